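"""Synthetic annotation + expression datasets with ground truth.

The generator emulates the statistical structure of a FACS/RNA-seq study
of mosquito spermatogenesis: four germline populations (premeiotic I,
meiotic II and III, postmeiotic IV) x three replicates; autosomes 2 and 3
with many genes, a gene-poor X and a handful of Y contig genes; log-normal
baseline expression with a very-low-expression ("dropout") gene fraction;
stage-peaked autosomal expression programs; a hemizygous male X at half
dosage, optionally compensated in the premeiotic stage and silenced from
the meiotic stage onward (MSCI), with a small fraction of X-linked
escapees that instead peak meiotically.

Every dataset ships with a per-gene truth table so each pipeline stage can
be tested for parameter recovery without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import POPULATIONS, ExpressionMatrix

#: Ten stage-program archetypes (FPKM multipliers over populations I-IV),
#: covering single-stage peaks, two-stage plateaus, monotone ramps and an
#: ends-high program. Each is normalised to mean 1 before use so the
#: baseline distribution keeps its scale.
DEFAULT_ARCHETYPES: tuple[tuple[float, float, float, float], ...] = (
    (8, 1, 1, 1),  # premeiotic peak
    (8, 8, 1, 1),  # premeiotic/early-meiotic plateau
    (1, 8, 1, 1),  # early-meiotic peak
    (1, 8, 8, 1),  # meiotic plateau
    (1, 1, 8, 1),  # late-meiotic peak
    (1, 1, 8, 8),  # late-meiotic/postmeiotic plateau
    (1, 1, 1, 8),  # postmeiotic peak
    (8, 4, 2, 1),  # decreasing ramp
    (1, 2, 4, 8),  # increasing ramp
    (8, 1, 1, 8),  # ends-high
)

#: Meiotic-peaked program assigned to MSCI escapees, so they rise in III
#: relative to I as escapees do in real data.
ESCAPEE_ARCHETYPE: tuple[float, float, float, float] = (1, 2, 8, 4)


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one synthetic spermatogenesis dataset.

    Defaults describe the study-like scenario: hemizygous X (x_dosage 0.5)
    with no premeiotic compensation, strong meiotic silencing (3/4 of
    expression lost at stage II, 9/10 at III and IV), ~1% of X genes
    escaping silencing, ten stage archetypes and a 20% very-low-expression
    gene fraction.
    """

    n_genes_by_chromosome: Mapping[str, int] = field(
        default_factory=lambda: {"2": 1000, "3": 1000, "X": 350, "Y": 10}
    )
    baseline_mu: float = 2.5  # log-normal baseline location (ln scale)
    baseline_sigma: float = 1.2  # log-normal baseline spread; drives the heavy tail
    x_dosage: float = 0.5  # hemizygous male X
    compensation: float = 1.0  # multiplies X in population I only
    silencing: Mapping[str, float] = field(
        default_factory=lambda: {"II": 0.25, "III": 0.1, "IV": 0.1}
    )
    escapee_fraction: float = 0.01
    stage_archetypes: Sequence[Sequence[float]] = DEFAULT_ARCHETYPES
    archetype_proportions: Sequence[float] | None = None  # uniform when None
    replicate_cv: float = 0.2
    n_replicates: int = 3
    library_size: float = 30_000_000.0  # fragments per sample
    dropout: float = 0.2  # fraction of genes at near-zero expression
    dropout_factor: float = 1e-3
    overdispersion: float | None = None  # NB dispersion; Poisson when None
    seed: int = 17

    def __post_init__(self) -> None:
        problems = []
        if not 0 < self.x_dosage <= 1:
            problems.append("x_dosage must be in (0, 1]")
        if self.compensation < 1:
            problems.append("compensation must be >= 1")
        for pop, s in self.silencing.items():
            if pop not in ("II", "III", "IV"):
                problems.append(f"silencing schedule names unknown population {pop!r}")
            elif not 0 <= s <= 1:
                problems.append(f"silencing[{pop}] must be in [0, 1]")
        if not 0 <= self.escapee_fraction <= 1:
            problems.append("escapee_fraction must be in [0, 1]")
        if not 0 <= self.dropout < 1:
            problems.append("dropout must be in [0, 1)")
        if self.replicate_cv < 0:
            problems.append("replicate_cv must be >= 0")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if self.library_size <= 0:
            problems.append("library_size must be > 0")
        if any(n < 0 for n in self.n_genes_by_chromosome.values()):
            problems.append("gene counts must be >= 0")
        arch = np.asarray(self.stage_archetypes, dtype=float)
        if arch.ndim != 2 or arch.shape[1] != len(POPULATIONS) or (arch <= 0).any():
            problems.append("stage_archetypes must be positive 4-vectors")
        if self.archetype_proportions is not None:
            props = np.asarray(self.archetype_proportions, dtype=float)
            if props.shape != (arch.shape[0],) or (props < 0).any() or not np.isclose(props.sum(), 1):
                problems.append("archetype_proportions must be non-negative and sum to 1")
        if problems:
            raise SimConfigError("; ".join(problems))

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        return cls(**dict(data))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_genes_by_chromosome"] = dict(self.n_genes_by_chromosome)
        d["silencing"] = dict(self.silencing)
        d["stage_archetypes"] = [list(a) for a in self.stage_archetypes]
        return d

    # ---- Named scenarios -------------------------------------------------

    @classmethod
    def null_dosage(cls, seed: int = 17, **overrides) -> "SimConfig":
        """Hemizygous X, no compensation, no silencing, no stage structure.

        All chromosomes share one log-normal FPKM distribution; the X is
        simply at half dosage, so the premeiotic X:A median ratio is 0.5 by
        construction and 2:3 is 1.
        """
        base = dict(
            silencing={"II": 1.0, "III": 1.0, "IV": 1.0},
            escapee_fraction=0.0,
            stage_archetypes=((1.0, 1.0, 1.0, 1.0),),
            dropout=0.0,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def msci(cls, seed: int = 17, silencing_factor: float = 0.1, **overrides) -> "SimConfig":
        """Hemizygous X with uniform meiotic silencing from stage II onward."""
        base = dict(
            silencing={p: silencing_factor for p in ("II", "III", "IV")},
            escapee_fraction=0.0,
            stage_archetypes=((1.0, 1.0, 1.0, 1.0),),
            dropout=0.0,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


def _x_factor_matrix(cfg: SimConfig) -> np.ndarray:
    """Per-population multipliers applied to non-escapee sex-linked genes."""
    factors = np.ones(len(POPULATIONS))
    factors[0] = cfg.x_dosage * cfg.compensation
    for i, pop in enumerate(POPULATIONS[1:], start=1):
        factors[i] = cfg.x_dosage * cfg.silencing.get(pop, 1.0)
    return factors


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Generate (annotation, counts, FPKM, truth) for one dataset.

    Per gene, the population-level mean FPKM is a log-normal baseline draw
    times its stage-archetype profile, times the sex-chromosome factors
    when the gene is X- or Y-linked (dosage x compensation in population I;
    dosage x silencing in II-IV, unless the gene is an escapee, which keeps
    full hemizygous dosage and a meiotic-peaked program). Replicate FPKM
    adds multiplicative log-normal noise at the configured CV; fragment
    counts are Poisson (optionally negative-binomial) around the expected
    fragments given gene length and library size, so FPKM reconstruction
    from counts inverts the generative FPKM in expectation.

    Outputs are bit-reproducible for a fixed config (the seed is part of
    the config).
    """
    rng = np.random.default_rng(cfg.seed)
    chroms: list[str] = []
    gene_ids: list[str] = []
    for chrom in ("2", "3", "X", "Y"):
        n = int(cfg.n_genes_by_chromosome.get(chrom, 0))
        chroms.extend([chrom] * n)
        gene_ids.extend(f"SG{chrom}_{i:05d}" for i in range(n))
    n_genes = len(gene_ids)
    if n_genes == 0:
        raise SimConfigError("no genes requested")
    chrom_arr = np.asarray(chroms, dtype=object)

    # Annotation: log-normal lengths, genes laid out along each chromosome.
    lengths = np.clip(rng.lognormal(np.log(2000), 0.6, n_genes), 200, 50_000).astype(int)
    starts = np.empty(n_genes, dtype=int)
    for chrom in ("2", "3", "X", "Y"):
        mask = chrom_arr == chrom
        if mask.sum() == 0:
            continue
        gaps = rng.integers(500, 20_000, size=mask.sum())
        spans = lengths[mask] + gaps
        starts[mask] = 1 + np.concatenate([[0], np.cumsum(spans[:-1])])
    annotation = pd.DataFrame(
        {
            "chromosome": chrom_arr,
            "start": starts,
            "end": starts + lengths - 1,
            "length": lengths,
            "strand": rng.choice(["+", "-"], size=n_genes),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # Baseline expression and dropout spike.
    baseline = rng.lognormal(cfg.baseline_mu, cfg.baseline_sigma, n_genes)
    dropped = rng.random(n_genes) < cfg.dropout
    baseline[dropped] *= cfg.dropout_factor

    # Stage archetypes, normalised to mean 1 across populations.
    arch = np.asarray(cfg.stage_archetypes, dtype=float)
    arch = arch / arch.mean(axis=1, keepdims=True)
    props = (
        np.asarray(cfg.archetype_proportions, dtype=float)
        if cfg.archetype_proportions is not None
        else np.full(arch.shape[0], 1.0 / arch.shape[0])
    )
    archetype_id = rng.choice(arch.shape[0], size=n_genes, p=props)

    # Escapees: X-linked only, exempt from silencing, meiotic-peaked program.
    sex_linked = np.isin(chrom_arr, ("X", "Y"))
    is_escapee = (chrom_arr == "X") & (rng.random(n_genes) < cfg.escapee_fraction)
    escapee_profile = np.asarray(ESCAPEE_ARCHETYPE, dtype=float)
    escapee_profile = escapee_profile / escapee_profile.mean()

    mean_fpkm = baseline[:, None] * arch[archetype_id]
    mean_fpkm[is_escapee] = baseline[is_escapee, None] * escapee_profile[None, :]
    x_factors = _x_factor_matrix(cfg)
    mean_fpkm[sex_linked & ~is_escapee] *= x_factors[None, :]
    mean_fpkm[is_escapee] *= cfg.x_dosage  # hemizygous but unsilenced

    any_silencing = any(s < 1 for s in cfg.silencing.values())
    is_silenced = sex_linked & ~is_escapee & any_silencing

    # Normalise each population so the FPKM identity holds:
    # sum_g FPKM[g] * length_kb[g] = 1e6. This makes the emitted FPKM
    # internally consistent with the fragment counts drawn below, so
    # counts_to_fpkm inverts the generator in expectation. All ratio,
    # tau and clustering analyses are invariant to this common factor.
    length_kb = lengths / 1000.0
    mean_fpkm *= 1e6 / (mean_fpkm * length_kb[:, None]).sum(axis=0)

    # Replicate-level FPKM with multiplicative log-normal noise (mean 1).
    sample_ids = [f"{pop}_r{r}" for pop in POPULATIONS for r in range(1, cfg.n_replicates + 1)]
    design = pd.DataFrame(
        {
            "population": [s.split("_")[0] for s in sample_ids],
            "replicate": [int(s.split("_r")[1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    pop_index = np.asarray([POPULATIONS.index(p) for p in design["population"]])
    sigma_r = np.sqrt(np.log1p(cfg.replicate_cv**2))
    noise = rng.lognormal(-sigma_r**2 / 2, sigma_r, size=(n_genes, len(sample_ids)))
    fpkm_rep = mean_fpkm[:, pop_index] * noise
    fpkm = ExpressionMatrix(
        values=pd.DataFrame(fpkm_rep, index=annotation.index, columns=sample_ids),
        design=design,
        unit="FPKM",
    )

    # Fragment counts: expected fragments from FPKM, length and library size.
    lam = fpkm_rep * length_kb[:, None] * (cfg.library_size / 1e6)
    if cfg.overdispersion is not None and cfg.overdispersion > 0:
        shape = 1.0 / cfg.overdispersion
        lam = rng.gamma(shape, lam / shape)
    count_values = rng.poisson(lam).astype(np.int64)
    counts = ExpressionMatrix(
        values=pd.DataFrame(count_values, index=annotation.index, columns=sample_ids),
        design=design.copy(),
        unit="counts",
    )

    truth = pd.DataFrame(
        {
            "chromosome": chrom_arr,
            "is_silenced": is_silenced,
            "is_escapee": is_escapee,
            "archetype_id": np.where(is_escapee, -1, archetype_id),
            "is_dropout": dropped,
            **{f"mu_{pop}": mean_fpkm[:, i] for i, pop in enumerate(POPULATIONS)},
        },
        index=annotation.index,
    )
    return annotation, counts, fpkm, truth


def simulate_tissue_panel(
    n_genes: int = 1000,
    tissues: Sequence[str] = ("testis", "ovary", "midgut", "head", "salivary_gland", "carcass"),
    specific_fraction: float = 0.05,
    base_mu: float = 2.0,
    base_sigma: float = 1.0,
    tissue_noise_sigma: float = 0.4,
    off_tissue_factor: float = 0.02,
    seed: int = 17,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-tissue expression panel with planted tissue-specific genes.

    Background genes are broadly expressed (a per-gene log-normal base
    value with mild per-tissue log-normal variation, so tau stays well
    below the 0.8 enrichment cut-off); a *specific_fraction* of genes are
    planted as single-tissue genes, expressed in one tissue (chosen
    uniformly) and at *off_tissue_factor* of their base level elsewhere.
    Returns the genes x tissues panel and a truth table whose
    ``tissue_specific_to`` column is the planted tissue or ``none``.
    """
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    for required in ("testis", "ovary"):
        if required not in tissues:
            raise ValueError(f"tissue panel must include {required!r}")
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"TP_{i:05d}" for i in range(n_genes)], name="gene_id")
    base = rng.lognormal(base_mu, base_sigma, n_genes)
    values = base[:, None] * rng.lognormal(
        0.0, tissue_noise_sigma, size=(n_genes, len(tissues))
    )
    planted = rng.random(n_genes) < specific_fraction
    target = rng.integers(0, len(tissues), size=n_genes)
    for i in np.flatnonzero(planted):
        off = values[i] * off_tissue_factor
        on_value = base[i] * rng.lognormal(1.0, 0.3)
        values[i] = off
        values[i, target[i]] = on_value
    panel = pd.DataFrame(values, index=gene_ids, columns=list(tissues))
    truth = pd.DataFrame(
        {
            "tissue_specific_to": np.where(
                planted, np.asarray(list(tissues), dtype=object)[target], "none"
            )
        },
        index=gene_ids,
    )
    return panel, truth
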
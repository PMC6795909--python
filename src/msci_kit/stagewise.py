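"""Stage-resolved expression analysis.

Covers the downstream, per-gene view of the four germline populations:
Z-scored log2(FPKM+1) profiles and their k-means clustering into stage
programs; a pluggable differential-expression stage (a one-way F-test on
log-scale replicate values, replaceable verbatim by an external per-gene
p-value table from a count-model tool); Benjamini-Hochberg adjustment;
the population-enrichment filter (fold change > 2 against each other
population, adjusted p < 0.05, 1 FPKM floor); and the meiotic (III) vs
premeiotic (I) fold-change map ordered along each chromosome, where
silenced X-linked genes appear as a run of negative bars and escapees as
isolated positive ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .expression_io import CHROMOSOMES, POPULATIONS, ExpressionMatrix

#: Pseudocount (FPKM) added to fold-change denominators.
DEFAULT_EPS = 0.01


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score of log2(FPKM + 1) across the four populations, per gene.

    The standard deviation uses the population-count denominator (ddof=0),
    so non-constant profiles have mean 0 and sd exactly 1; constant
    profiles map to the zero vector.
    """
    t = np.log2(profiles[list(POPULATIONS)].to_numpy(dtype=float) + 1.0)
    mean = t.mean(axis=1, keepdims=True)
    sd = t.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (t - mean) / sd
    z[np.squeeze(sd, axis=1) == 0] = 0.0
    out = pd.DataFrame(z, index=profiles.index, columns=list(POPULATIONS))
    out.index.name = "gene_id"
    return out


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # gene_id -> cluster id in 1..k
    centroids: np.ndarray  # k x 4, ordered canonically
    inertia: float
    seed: int


def kmeans_clusters(
    zprofiles: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterResult:
    """k-means clustering of Z-profiles into stage programs.

    Standard Lloyd iterations from k-means++ starts, best of *n_init* by
    inertia. Cluster ids are canonicalised after fitting: clusters are
    numbered 1..k by the population index of their centroid peak (earliest
    peak first), ties broken by higher centroid value at population I, so
    labels are comparable across runs.
    """
    if len(zprofiles) < k:
        raise ValueError(f"need >= {k} genes to fit {k} clusters, got {len(zprofiles)}")
    data = zprofiles[list(POPULATIONS)].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
    raw = km.fit_predict(data)
    order = sorted(
        range(k),
        key=lambda j: (int(np.argmax(km.cluster_centers_[j])), -km.cluster_centers_[j, 0]),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignments = pd.Series(
        [relabel[c] for c in raw], index=zprofiles.index, name="cluster"
    )
    centroids = km.cluster_centers_[order]
    return ClusterResult(
        k=k,
        assignments=assignments,
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries (e.g. zero-variance genes from the F-test surrogate)
    propagate as NaN and do not enter the adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan)
    if mask.sum():
        adjusted[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adjusted


def de_surrogate(m: ExpressionMatrix) -> pd.Series:
    """Per-gene raw p-values for differential expression across populations.

    A one-way F-test on log2(FPKM + 1) replicate values over the four
    populations. Genes with zero variance across all samples are flagged
    missing (NaN). An externally computed p-value table (for instance from
    a negative-binomial count model) can replace this stage verbatim
    downstream.
    """
    if m.unit != "FPKM":
        raise ValueError("de_surrogate expects an FPKM matrix")
    groups = []
    for pop in POPULATIONS:
        samples = m.samples_of(pop)
        if len(samples) < 2:
            raise ValueError(
                f"population {pop} has {len(samples)} replicate(s); the F-test needs >= 2 "
                "— supply an external per-gene p-value table instead"
            )
        groups.append(np.log2(m.values[samples].to_numpy(dtype=float) + 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.f_oneway(*groups, axis=1)
    p = np.asarray(result.pvalue, dtype=float)
    flat = np.concatenate(groups, axis=1)
    p[flat.std(axis=1) == 0] = np.nan
    return pd.Series(p, index=m.genes, name="p_raw")


def enriched_transcripts(
    profiles: pd.DataFrame,
    p_adj: pd.Series,
    fc: float = 2.0,
    alpha: float = 0.05,
    floor: float = 1.0,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Population-enrichment calls.

    A transcript is enriched in population p iff FPKM_p / (FPKM_q + eps)
    > *fc* for every other population q, its adjusted p-value is < *alpha*,
    and its maximal FPKM exceeds *floor*. With fc > 1 at most one
    population can win, so ``enriched_population`` is single-valued
    (``none`` otherwise).
    """
    if fc <= 1:
        raise ValueError("fold-change cut-off must exceed 1 for exclusive calls")
    common = profiles.index.intersection(p_adj.index)
    if len(common) != len(profiles):
        missing = profiles.index.difference(p_adj.index)
        raise ValueError(f"p_adj missing for {len(missing)} transcripts: {list(missing[:5])}")
    values = profiles.loc[:, list(POPULATIONS)].to_numpy(dtype=float)
    padj = p_adj.loc[profiles.index].to_numpy(dtype=float)
    significant = padj < alpha  # NaN compares False
    above_floor = values.max(axis=1) > floor
    enriched_pop = np.full(len(profiles), "none", dtype=object)
    for i, pop in enumerate(POPULATIONS):
        others = [j for j in range(len(POPULATIONS)) if j != i]
        wins = np.all(
            values[:, [i]] / (values[:, others] + eps) > fc, axis=1
        )
        enriched_pop[wins & significant & above_floor] = pop
    out = profiles.loc[:, list(POPULATIONS)].copy()
    out["p_adj"] = padj
    out["enriched_population"] = enriched_pop
    out.index.name = "transcript_id"
    return out


def fold_change_map(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    p_adj: pd.Series,
    pop_a: str = "III",
    pop_b: str = "I",
    floor: float = 1.0,
    alpha: float = 0.05,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """log2 fold-change map between two populations along the genome.

    log2fc = log2((FPKM_a + eps) / (FPKM_b + eps)), default meiotic III vs
    premeiotic I. Entries are masked (the "gaps" of the genome-wide bar
    map) when maximal FPKM across populations is below *floor*
    (``low_expression``) or adjusted p > *alpha* (``not_significant``);
    transcripts without annotation are emitted masked with reason
    ``missing_annotation`` and sorted last. Output is ordered by
    chromosome (2, 3, X, Y, other) then start position.
    """
    values = profiles[list(POPULATIONS)]
    padj = p_adj.reindex(profiles.index).to_numpy(dtype=float)
    log2fc = np.log2(
        (values[pop_a].to_numpy(dtype=float) + eps)
        / (values[pop_b].to_numpy(dtype=float) + eps)
    )
    low = values.max(axis=1).to_numpy() < floor
    not_sig = ~(padj <= alpha)  # masks NaN as not significant
    have_annot = profiles.index.isin(annotation.index)

    reason = np.full(len(profiles), "", dtype=object)
    reason[not_sig] = "not_significant"
    reason[low] = "low_expression"  # low expression takes precedence
    reason[~have_annot] = "missing_annotation"

    chrom = annotation["chromosome"].reindex(profiles.index)
    start = annotation["start"].reindex(profiles.index)
    out = pd.DataFrame(
        {
            "chromosome": pd.Categorical(chrom, categories=list(CHROMOSOMES), ordered=True),
            "start": start,
            "log2fc": log2fc,
            "masked": reason != "",
            "mask_reason": reason,
        },
        index=profiles.index,
    )
    out.index.name = "transcript_id"
    return out.sort_values(["chromosome", "start"], na_position="last", kind="mergesort")
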
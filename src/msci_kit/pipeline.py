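"""End-to-end orchestration: simulate -> filter -> ratios -> tau -> stagewise.

A single :class:`RunConfig` (usually read from YAML) drives the whole
analysis; every stage writes a TSV with a commented metadata header, and a
``manifest.json`` records the config hash, per-stage outputs and summary
counts. Reruns with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .chromstats import (
    DEFAULT_THRESHOLDS,
    chromosome_summary,
    rank_test_consecutive,
    rank_test_frame,
    ratio_frame,
    ratio_sweep,
    summary_frame,
)
from .expression_io import (
    POPULATIONS,
    ExpressionMatrix,
    counts_to_fpkm,
    population_profiles,
    read_annotation,
    read_expression,
    write_annotation,
    write_expression,
)
from .filtering import apply_global_filter, presence_calls, venn_counts, venn_frame
from .specificity import tau_report
from .stagewise import (
    bh_adjust,
    de_surrogate,
    enriched_transcripts,
    fold_change_map,
    kmeans_clusters,
    zscore_profiles,
)
from .synthetic import SimConfig, simulate_dataset, simulate_tissue_panel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; partial outputs are retained."""


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one input source must be given: a simulation config (``sim``)
    or paths to annotation + expression matrix + design (``annotation_path``
    etc., FPKM or counts). All analysis constants default to the study
    values: 10 FPKM global cut-off, ratio thresholds 0-40, 10,000
    bootstraps, k = 10 clusters, fold change 2, alpha 0.05, tau >= 0.8,
    1 FPKM floor.
    """

    outdir: str | Path = "msci_run"
    seed: int = 17
    sim: SimConfig | None = None
    annotation_path: str | None = None
    annotation_dialect: str = "tsv"
    expression_path: str | None = None
    design_path: str | None = None
    expression_unit: str = "FPKM"
    external_pvalues_path: str | None = None
    tissue_panel_path: str | None = None
    simulate_tissue_panel: bool = True
    global_threshold: float = 10.0
    ratio_thresholds: Sequence[float] = tuple(DEFAULT_THRESHOLDS)
    n_boot: int = 10_000
    k: int = 10
    fc: float = 2.0
    alpha: float = 0.05
    tau_cutoff: float = 0.8
    floor: float = 1.0

    def __post_init__(self) -> None:
        has_paths = self.expression_path is not None
        if (self.sim is None) == (not has_paths):
            raise ValueError("exactly one of a simulation config or input paths is required")
        if has_paths and (self.annotation_path is None or self.design_path is None):
            raise ValueError("path input needs annotation_path, expression_path and design_path")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "sim" in data and data["sim"] is not None:
            data["sim"] = SimConfig.from_dict(data["sim"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = {
            k: (v.to_dict() if isinstance(v, SimConfig) else v)
            for k, v in self.__dict__.items()
        }
        d["outdir"] = str(self.outdir)
        d["ratio_thresholds"] = [float(t) for t in self.ratio_thresholds]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path, meta: Mapping[str, object], index: bool = True) -> None:
    with open(path, "w") as handle:
        for key, value in meta.items():
            handle.write(f"# {key}: {value}\n")
        frame.to_csv(handle, sep="\t", index=index)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    meta = {"msci_kit_version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "outputs": {},
        "summary": {},
    }

    def register(name: str, path: Path) -> Path:
        manifest["outputs"][name] = str(path)
        return path

    try:
        # --- inputs -------------------------------------------------------
        if cfg.sim is not None:
            annotation, counts, fpkm, truth = simulate_dataset(cfg.sim)
            write_annotation(annotation, register("annotation", outdir / "annotation.tsv"))
            write_expression(
                counts,
                register("counts", outdir / "counts.tsv"),
                outdir / "design.tsv",
            )
            manifest["outputs"]["design"] = str(outdir / "design.tsv")
            write_expression(fpkm, register("fpkm", outdir / "fpkm.tsv"), outdir / "design.tsv")
            truth.to_csv(register("truth", outdir / "truth.tsv"), sep="\t")
        else:
            annotation = read_annotation(cfg.annotation_path, cfg.annotation_dialect)
            matrix = read_expression(cfg.expression_path, cfg.design_path, cfg.expression_unit)
            fpkm = counts_to_fpkm(matrix, annotation) if matrix.unit == "counts" else matrix

        profiles = population_profiles(fpkm)
        _write_tsv(profiles, register("profiles", outdir / "profiles.tsv"), meta)
        manifest["summary"]["n_genes"] = int(len(profiles))

        # --- presence / Venn ---------------------------------------------
        filtered = apply_global_filter(profiles, cfg.global_threshold)
        presence = presence_calls(profiles, cfg.global_threshold)
        _write_tsv(presence, register("presence", outdir / "presence.tsv"), meta)
        venn = venn_counts(presence)
        _write_tsv(venn_frame(venn), register("venn", outdir / "venn.tsv"), meta)
        manifest["summary"]["n_filtered_genes"] = int(len(filtered))
        manifest["summary"]["expressed_per_population"] = {
            pop: int(presence[pop].sum()) for pop in POPULATIONS
        }

        # --- chromosome statistics ---------------------------------------
        summaries = [
            chromosome_summary(profiles, annotation, pop, chrom, cfg.global_threshold)
            for chrom in ("2", "3", "X")
            for pop in POPULATIONS
        ]
        _write_tsv(
            summary_frame(summaries), register("chrom_summary", outdir / "chrom_summary.tsv"),
            meta, index=False,
        )
        tests = [
            r
            for chrom in ("2", "3", "X")
            for r in rank_test_consecutive(profiles, annotation, chrom, cfg.global_threshold)
        ]
        _write_tsv(
            rank_test_frame(tests), register("rank_tests", outdir / "rank_tests.tsv"),
            meta, index=False,
        )

        results, skipped = ratio_sweep(
            profiles, annotation, cfg.ratio_thresholds, n_boot=cfg.n_boot, seed=cfg.seed
        )
        _write_tsv(
            ratio_frame(results), register("ratio_sweep", outdir / "ratio_sweep.tsv"),
            meta, index=False,
        )
        manifest["summary"]["ratio_combinations"] = len(results)
        manifest["summary"]["ratio_skipped"] = skipped
        xa0 = {
            r.population: r.observed_ratio
            for r in results
            if r.numerator == "X" and r.threshold == 0
        }
        manifest["summary"]["xa_ratio_threshold0"] = xa0

        # --- tissue specificity ------------------------------------------
        panel = None
        if cfg.tissue_panel_path is not None:
            panel = pd.read_csv(cfg.tissue_panel_path, sep="\t", index_col="gene_id", comment="#")
        elif cfg.simulate_tissue_panel:
            panel, _panel_truth = simulate_tissue_panel(seed=cfg.seed)
        if panel is not None:
            report = tau_report(panel, cutoff=cfg.tau_cutoff)
            _write_tsv(report, register("tau", outdir / "tau.tsv"), meta)
            manifest["summary"]["n_testis_enriched"] = int(report["enriched_testis"].sum())
            manifest["summary"]["n_ovary_enriched"] = int(report["enriched_ovary"].sum())

        # --- stagewise ----------------------------------------------------
        zp = zscore_profiles(filtered)
        _write_tsv(zp, register("zprofiles", outdir / "zprofiles.tsv"), meta)
        clusters = kmeans_clusters(zp, k=cfg.k, seed=cfg.seed)
        _write_tsv(
            clusters.assignments.to_frame(),
            register("clusters", outdir / "clusters.tsv"), meta,
        )
        centroids = pd.DataFrame(
            clusters.centroids, columns=list(POPULATIONS),
            index=pd.Index(range(1, cfg.k + 1), name="cluster"),
        )
        _write_tsv(centroids, register("centroids", outdir / "centroids.tsv"), meta)
        manifest["summary"]["cluster_sizes"] = (
            clusters.assignments.value_counts().sort_index().astype(int).to_dict()
        )

        if cfg.external_pvalues_path is not None:
            ext = pd.read_csv(cfg.external_pvalues_path, sep="\t", comment="#")
            p_raw = ext.set_index(ext.columns[0]).iloc[:, 0].reindex(profiles.index)
        else:
            p_raw = de_surrogate(fpkm)
        p_adj = pd.Series(bh_adjust(p_raw.to_numpy()), index=p_raw.index, name="p_adj")

        enriched = enriched_transcripts(
            profiles, p_adj, fc=cfg.fc, alpha=cfg.alpha, floor=cfg.floor
        )
        _write_tsv(enriched, register("enriched", outdir / "enriched.tsv"), meta)
        manifest["summary"]["enriched_per_population"] = {
            pop: int((enriched["enriched_population"] == pop).sum()) for pop in POPULATIONS
        }

        fc_map = fold_change_map(
            profiles, annotation, p_adj, floor=cfg.floor, alpha=cfg.alpha
        )
        _write_tsv(fc_map, register("fc_map", outdir / "fc_map.tsv"), meta)
        manifest["summary"]["fc_map_unmasked"] = int((~fc_map["masked"]).sum())
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(f"pipeline stage failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
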
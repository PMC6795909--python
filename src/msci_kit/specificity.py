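"""Tau tissue-specificity index and germline-enrichment classification.

tau for an expression vector x over N tissues is

    tau = sum_i (1 - x_i / max(x)) / (N - 1)

and lies in [0, 1]: 0 for a gene expressed uniformly across tissues, 1 for
a gene expressed in exactly one tissue. A gene is called germline-enriched
when tau >= 0.8 (inclusive) and its maximal expression is in the queried
germline tissue (testis for males, ovary for females).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_TAU_CUTOFF = 0.8


def tau(x) -> float:
    """Tissue-specificity index of one non-negative expression vector.

    Returns NaN (flagged missing) when the vector is all zero; such genes
    can never be called enriched.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D vector over at least 2 tissues")
    if np.any(x < 0) or not np.isfinite(x).all():
        raise ValueError("tau requires finite non-negative expression values")
    top = x.max()
    if top <= 0:
        return float("nan")
    return float(np.sum(1.0 - x / top) / (x.size - 1))


def tau_table(panel: pd.DataFrame) -> pd.Series:
    """tau for every gene of a genes x tissues panel (vectorised)."""
    if panel.shape[1] < 2:
        raise ValueError("tissue panel needs at least 2 tissues")
    values = panel.to_numpy(dtype=float)
    if (values < 0).any() or not np.isfinite(values).all():
        raise ValueError("tissue panel requires finite non-negative values")
    top = values.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = values / top[:, None]
    taus = np.sum(1.0 - scaled, axis=1) / (values.shape[1] - 1)
    taus[top <= 0] = np.nan
    return pd.Series(taus, index=panel.index, name="tau")


def classify_enriched(
    panel: pd.DataFrame,
    target_tissue: str,
    cutoff: float = DEFAULT_TAU_CUTOFF,
) -> pd.DataFrame:
    """Call genes enriched in *target_tissue* by the tau >= cutoff rule.

    A gene is enriched iff tau >= cutoff and its (unique) maximal
    expression is in the target tissue; ties at the maximum are treated as
    an ambiguous maximum and never called enriched. Returns a DataFrame
    with columns ``tau``, ``max_tissue`` and ``enriched``.
    """
    if target_tissue not in panel.columns:
        raise ValueError(f"unknown tissue label {target_tissue!r}; panel has {list(panel.columns)}")
    taus = tau_table(panel)
    values = panel.to_numpy(dtype=float)
    top = values.max(axis=1)
    argmax = np.asarray(panel.columns)[values.argmax(axis=1)]
    ambiguous = (values == top[:, None]).sum(axis=1) > 1
    all_zero = top <= 0
    max_tissue = pd.Series(argmax, index=panel.index, name="max_tissue", dtype=object)
    max_tissue[all_zero] = None
    enriched = (
        (taus >= cutoff).fillna(False)
        & (max_tissue == target_tissue)
        & ~ambiguous
        & ~all_zero
    )
    return pd.DataFrame(
        {"tau": taus, "max_tissue": max_tissue, "enriched": enriched},
        index=panel.index,
    )


def tau_report(
    panel: pd.DataFrame,
    testis_label: str = "testis",
    ovary_label: str = "ovary",
    cutoff: float = DEFAULT_TAU_CUTOFF,
) -> pd.DataFrame:
    """Per-gene tau with male (testis) and female (ovary) enrichment calls."""
    male = classify_enriched(panel, testis_label, cutoff)
    female = classify_enriched(panel, ovary_label, cutoff)
    report = male.rename(columns={"enriched": "enriched_testis"})
    report["enriched_ovary"] = female["enriched"]
    report.index.name = "gene_id"
    return report
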
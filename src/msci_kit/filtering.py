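"""Expression thresholds, presence calls and Venn-region counts.

A gene is "expressed" in a population when its mean FPKM there strictly
exceeds the threshold (default 10 FPKM). The global filter keeps genes
expressed in at least one of the four populations; presence calls break
that down per population, and the Venn counts partition the surviving
genes over the 15 non-empty population subsets.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping

import pandas as pd

from .expression_io import POPULATIONS

logger = logging.getLogger(__name__)

#: Global expression cut-off (FPKM) used to reduce noise after assembly.
DEFAULT_THRESHOLD = 10.0


def apply_global_filter(profiles: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Keep genes with FPKM strictly above *threshold* in >= 1 population."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    keep = (profiles[list(POPULATIONS)] > threshold).any(axis=1)
    filtered = profiles.loc[keep].copy()
    logger.info(
        "global filter (> %g FPKM in >= 1 population): %d of %d genes retained",
        threshold, len(filtered), len(profiles),
    )
    return filtered


def presence_calls(profiles: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-population expressed/not-expressed calls.

    Returns a boolean DataFrame (columns I-IV) plus ``passes_global_filter``,
    true iff the gene is expressed in at least one population.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    calls = (profiles[list(POPULATIONS)] > threshold).copy()
    calls["passes_global_filter"] = calls[list(POPULATIONS)].any(axis=1)
    calls.index.name = "gene_id"
    return calls


def venn_regions() -> list[tuple[str, ...]]:
    """The 15 non-empty subsets of {I, II, III, IV}, smallest first."""
    regions = []
    for r in range(1, len(POPULATIONS) + 1):
        regions.extend(itertools.combinations(POPULATIONS, r))
    return regions


def region_key(subset: tuple[str, ...]) -> str:
    return "+".join(subset)


def venn_counts(presence: pd.DataFrame) -> Mapping[str, int]:
    """Count genes in each exclusive Venn region of the four populations.

    Only genes passing the global filter contribute; the 15 region counts
    sum to the number of such genes.
    """
    if presence.empty:
        raise ValueError("presence table is empty")
    expressed = presence.loc[presence["passes_global_filter"], list(POPULATIONS)]
    counts: dict[str, int] = {}
    for subset in venn_regions():
        inside = expressed[list(subset)].all(axis=1)
        outside = ~expressed[[p for p in POPULATIONS if p not in subset]].any(axis=1) \
            if len(subset) < len(POPULATIONS) else pd.Series(True, index=expressed.index)
        counts[region_key(subset)] = int((inside & outside).sum())
    return counts


def venn_frame(counts: Mapping[str, int]) -> pd.DataFrame:
    frame = pd.DataFrame({"region": list(counts), "count": list(counts.values())})
    return frame.set_index("region")
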
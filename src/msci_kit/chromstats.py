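"""Chromosome-level expression statistics and the MSCI / dosage-compensation core.

Three analyses live here:

* per-chromosome, per-population summaries (median, mean, quartiles, SD)
  of FPKM values of globally filtered genes;
* Wilcoxon rank-sum tests between consecutive germline populations on a
  chromosome's per-gene FPKM values;
* the bootstrap chromosome-wide median expression ratio: X:A (median of
  X-linked genes over median of all autosomal genes) and 2:3 (chromosome 2
  over chromosome 3), with 95% confidence intervals from resampling the
  numerator gene set, swept over FPKM inclusion thresholds.

In a male with a single X and no dosage compensation the premeiotic X:A
ratio is expected near 0.5; meiotic sex chromosome inactivation pushes the
meiotic and postmeiotic ratios below that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import AUTOSOMES, POPULATIONS

#: FPKM inclusion thresholds for the ratio sweep.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0, 1, 2, 3, 4, 10, 20, 30, 40)

#: Numerator chromosome -> denominator chromosome set.
RATIO_DESIGNS: dict[str, tuple[str, ...]] = {"X": AUTOSOMES, "2": ("3",)}

CONSECUTIVE_PAIRS: tuple[tuple[str, str], ...] = (("I", "II"), ("II", "III"), ("III", "IV"))


class DegenerateRatioError(ValueError):
    """Raised when a ratio cannot be formed (empty side or zero denominator)."""


@dataclass(frozen=True)
class ChromosomeSummary:
    population: str
    chromosome: str
    n_genes: int
    median: float
    mean: float
    q25: float
    q75: float
    sd: float

    @property
    def empty(self) -> bool:
        return self.n_genes == 0


@dataclass(frozen=True)
class RankTestResult:
    chromosome: str
    population_pair: tuple[str, str]
    statistic: float
    p_value: float


@dataclass(frozen=True)
class RatioResult:
    population: str
    numerator: str
    denominator: str
    threshold: float
    observed_ratio: float
    ci_low: float
    ci_high: float
    n_numerator_genes: int
    n_denominator_genes: int
    n_boot: int
    seed: int | None


def _chromosome_values(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    chromosomes: Sequence[str],
    population: str,
) -> pd.Series:
    genes = annotation.index[annotation["chromosome"].isin(chromosomes)]
    genes = genes.intersection(profiles.index)
    return profiles.loc[genes, population]


def chromosome_summary(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    population: str,
    chromosome: str,
    min_fpkm: float = 10.0,
) -> ChromosomeSummary:
    """Summary statistics of one chromosome's expression in one population.

    The global filter (> *min_fpkm* FPKM in at least one population) is
    applied first; statistics are then taken over that population's FPKM
    values of the chromosome's surviving genes. An empty chromosome yields
    a flagged-empty summary (NaN statistics) rather than an exception.
    """
    from .filtering import apply_global_filter

    filtered = apply_global_filter(profiles, min_fpkm)
    values = _chromosome_values(filtered, annotation, [chromosome], population).to_numpy()
    if values.size == 0:
        return ChromosomeSummary(population, chromosome, 0, *(float("nan"),) * 5)
    return ChromosomeSummary(
        population=population,
        chromosome=chromosome,
        n_genes=int(values.size),
        median=float(np.median(values)),
        mean=float(np.mean(values)),
        q25=float(np.percentile(values, 25)),
        q75=float(np.percentile(values, 75)),
        sd=float(np.std(values, ddof=1)) if values.size > 1 else float("nan"),
    )


def summary_frame(summaries: Sequence[ChromosomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def rank_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between two samples.

    Exact null distribution when both samples are small (n <= 25) and free
    of ties; tie-corrected normal approximation otherwise. Returns
    (U statistic of the first sample, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("rank test needs >= 2 observations per sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def rank_test_consecutive(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    chromosome: str,
    min_fpkm: float = 10.0,
) -> list[RankTestResult]:
    """Rank-sum tests between consecutive populations (I-II, II-III, III-IV).

    The two populations' per-gene FPKM vectors are treated as independent
    samples, matching the cited rank-sum test.
    """
    from .filtering import apply_global_filter

    filtered = apply_global_filter(profiles, min_fpkm)
    results = []
    for pop_a, pop_b in CONSECUTIVE_PAIRS:
        a = _chromosome_values(filtered, annotation, [chromosome], pop_a).to_numpy()
        b = _chromosome_values(filtered, annotation, [chromosome], pop_b).to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"chromosome {chromosome}: fewer than 2 genes for pair {pop_a}-{pop_b}"
            )
        statistic, p = rank_test(a, b)
        results.append(RankTestResult(chromosome, (pop_a, pop_b), statistic, p))
    return results


def rank_test_frame(results: Sequence[RankTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [r.chromosome for r in results],
            "population_a": [r.population_pair[0] for r in results],
            "population_b": [r.population_pair[1] for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
        }
    )


def median_ratio(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    population: str,
    numerator: str = "X",
    threshold: float = 0.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Observed median expression ratio and the two thresholded value sets.

    Genes enter each side iff their FPKM in *population* strictly exceeds
    *threshold* (threshold 0 therefore means "all expressed genes").
    """
    if numerator not in RATIO_DESIGNS:
        raise ValueError(f"numerator must be one of {sorted(RATIO_DESIGNS)}")
    denom_chroms = RATIO_DESIGNS[numerator]
    num_all = _chromosome_values(profiles, annotation, [numerator], population)
    den_all = _chromosome_values(profiles, annotation, denom_chroms, population)
    num = num_all[num_all > threshold].to_numpy(dtype=float)
    den = den_all[den_all > threshold].to_numpy(dtype=float)
    if num.size == 0:
        raise DegenerateRatioError(
            f"empty numerator: no chromosome-{numerator} genes above {threshold} FPKM "
            f"in population {population}"
        )
    if den.size == 0:
        raise DegenerateRatioError(
            f"empty denominator: no {'/'.join(denom_chroms)} genes above {threshold} FPKM "
            f"in population {population}"
        )
    den_med = float(np.median(den))
    if den_med == 0:
        raise DegenerateRatioError("degenerate denominator: median is zero")
    return float(np.median(num)) / den_med, num, den


def bootstrap_ratio(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    population: str,
    numerator: str = "X",
    threshold: float = 0.0,
    n_boot: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    resample_denominator: bool = False,
) -> RatioResult:
    """Bootstrap chromosome-wide median expression ratio with a 95% CI.

    The numerator gene set is resampled with replacement at its own size
    *n_boot* times; each bootstrap median is divided by the fixed observed
    denominator median (optionally the denominator is resampled too). The
    CI is the 2.5th/97.5th percentile of the bootstrap ratios.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    observed, num, den = median_ratio(profiles, annotation, population, numerator, threshold)
    den_med = float(np.median(den))
    idx = rng.integers(0, num.size, size=(n_boot, num.size))
    boot_num = np.median(num[idx], axis=1)
    if resample_denominator:
        didx = rng.integers(0, den.size, size=(n_boot, den.size))
        boot_den = np.median(den[didx], axis=1)
        if np.any(boot_den == 0):
            raise DegenerateRatioError("degenerate denominator in bootstrap resample")
        ratios = boot_num / boot_den
    else:
        ratios = boot_num / den_med
    ci_low, ci_high = np.percentile(ratios, [2.5, 97.5])
    return RatioResult(
        population=population,
        numerator=numerator,
        denominator="autosomes" if numerator == "X" else "3",
        threshold=float(threshold),
        observed_ratio=observed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_numerator_genes=int(num.size),
        n_denominator_genes=int(den.size),
        n_boot=int(n_boot),
        seed=seed,
    )


def ratio_sweep(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_boot: int = 10_000,
    seed: int = 0,
    resample_denominator: bool = False,
) -> tuple[list[RatioResult], list[dict]]:
    """X:A and 2:3 bootstrap ratios for every population x threshold.

    Sub-seeds are derived deterministically per (population, numerator,
    threshold) combination, so results do not depend on sweep order.
    Combinations with an empty or degenerate side are skipped and reported
    in the second return value rather than aborting the sweep.
    """
    results: list[RatioResult] = []
    skipped: list[dict] = []
    for numerator in RATIO_DESIGNS:
        for pop in POPULATIONS:
            for threshold in thresholds:
                key = [
                    int(seed),
                    POPULATIONS.index(pop),
                    0 if numerator == "X" else 1,
                    int(round(float(threshold) * 1000)),
                ]
                rng = np.random.default_rng(np.random.SeedSequence(key))
                try:
                    res = bootstrap_ratio(
                        profiles,
                        annotation,
                        population=pop,
                        numerator=numerator,
                        threshold=threshold,
                        n_boot=n_boot,
                        rng=rng,
                        resample_denominator=resample_denominator,
                    )
                except DegenerateRatioError as exc:
                    skipped.append(
                        {
                            "population": pop,
                            "numerator": numerator,
                            "threshold": float(threshold),
                            "reason": str(exc),
                        }
                    )
                    continue
                results.append(
                    RatioResult(**{**res.__dict__, "seed": int(seed)})
                )
    return results, skipped


def ratio_frame(results: Sequence[RatioResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
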
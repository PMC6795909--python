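"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the rank-sum oracle
enumerates every rank split, the BH oracle applies the step-up definition
literally, and the Venn oracle works on Python sets.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def rank_sum_p_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p-value by full enumeration of rank splits.

    Uses midranks for ties; the permutation distribution of U is symmetric
    about n1*n2/2, so the two-sided p is the fraction of splits at least as
    far from the centre as the observed U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    combos = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2
    return float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-9))


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg step-up applied literally to a p-value vector."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def venn_by_sets(presence_bools) -> dict[str, int]:
    """Venn region counts computed with plain Python set algebra.

    *presence_bools* is a DataFrame of booleans with columns I-IV.
    """
    populations = ("I", "II", "III", "IV")
    expressed_in = {
        pop: set(presence_bools.index[presence_bools[pop]]) for pop in populations
    }
    union = set().union(*expressed_in.values())
    counts: dict[str, int] = {}
    for r in range(1, 5):
        for subset in itertools.combinations(populations, r):
            inside = set(union)
            for pop in subset:
                inside &= expressed_in[pop]
            for pop in populations:
                if pop not in subset:
                    inside -= expressed_in[pop]
            counts["+".join(subset)] = len(inside)
    return counts
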
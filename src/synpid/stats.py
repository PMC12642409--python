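"""Condition-level comparisons: permutation tests and Hedges' g.

Recording-level summaries (fitted lambda, lambda_eff, long-path
proportions) are compared between two conditions with a two-sided
label-permutation test on the difference of group means.  At typical
recording counts (5 vs 5 -> 252 partitions) all label partitions are
enumerated exactly; the attainable p-value floor (2 / #partitions for a
two-sided test) is surfaced alongside the result.  Larger designs fall
back to Monte-Carlo permutation with the add-one correction
p = (1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm).

Effect sizes use Hedges' g: the pooled-SD standardised mean difference
with the small-sample correction J = 1 - 3 / (4 (n_a + n_b) - 9).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = ["GroupComparison", "permutation_test", "hedges_g",
           "compare_conditions"]

EXHAUSTIVE_CAP = 20_000
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class GroupComparison:
    mean_difference: float
    p_value: float
    hedges_g: float
    n_a: int
    n_b: int
    method: str        # "exhaustive" or "monte_carlo"
    p_floor: float     # smallest attainable two-sided p for this design


def _stat(pooled, mask_a, welch: bool):
    a, b = pooled[mask_a], pooled[~mask_a]
    diff = a.mean() - b.mean()
    if not welch:
        return diff
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return diff / se if se > 0 else 0.0


def permutation_test(a, b, n_perm: int = 10_000, seed: int = 0,
                     statistic: str = "mean_diff") -> tuple[float, str]:
    """Two-sided label-permutation p-value for the group difference.

    Exhaustive over all label partitions when their number is at most
    20,000 (no add-one correction: exact counting includes the observed
    labelling), Monte-Carlo with the add-one correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    if statistic not in ("mean_diff", "welch_t"):
        raise ValueError("statistic must be 'mean_diff' or 'welch_t'")
    welch = statistic == "welch_t"
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    mask_obs = np.zeros(n, dtype=bool)
    mask_obs[:n_a] = True
    obs = abs(_stat(pooled, mask_obs, welch))
    total = comb(n, n_a)
    if total <= EXHAUSTIVE_CAP:
        hits = 0
        mask = np.zeros(n, dtype=bool)
        for idx in combinations(range(n), n_a):
            mask[:] = False
            mask[list(idx)] = True
            if abs(_stat(pooled, mask, welch)) >= obs - _TIE_TOL:
                hits += 1
        return hits / total, "exhaustive"
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_a]] = True
        if abs(_stat(pooled, mask, welch)) >= obs - _TIE_TOL:
            hits += 1
    return (1 + hits) / (1 + n_perm), "monte_carlo"


def hedges_g(a, b) -> float:
    """Hedges' g = (mean(a) - mean(b)) / pooled_sd * J.

    Pooled SD uses the (n_a + n_b - 2) denominator; J is the small-sample
    bias correction.  Zero pooled variance yields NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    n_a, n_b = a.size, b.size
    pooled_var = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (
        n_a + n_b - 2
    )
    if pooled_var <= 0:
        return float("nan")
    j = 1 - 3 / (4 * (n_a + n_b) - 9)
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var) * j)


def compare_conditions(summaries_a, summaries_b, n_perm: int = 10_000,
                       seed: int = 0,
                       statistic: str = "mean_diff") -> GroupComparison:
    """Bundle mean difference, permutation p, and Hedges' g for two groups."""
    a = np.asarray(summaries_a, dtype=float)
    b = np.asarray(summaries_b, dtype=float)
    p, method = permutation_test(a, b, n_perm=n_perm, seed=seed,
                                 statistic=statistic)
    total = comb(a.size + b.size, a.size)
    floor = 2 / total if method == "exhaustive" else 1 / (1 + n_perm)
    return GroupComparison(
        mean_difference=float(a.mean() - b.mean()),
        p_value=float(p),
        hedges_g=hedges_g(a, b),
        n_a=a.size, n_b=b.size, method=method, p_floor=floor,
    )
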
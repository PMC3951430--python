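"""Shared nonparametric statistics.

All group comparisons in the pipeline (band powers, cell densities, qPCR
fold changes) go through the Wilcoxon rank-sum test.  Study group sizes are
tiny (3-6 animals or hemispheres per group), which puts them squarely in
the regime where the normal approximation is unreliable, so the test is
evaluated by exact enumeration of the rank-sum null whenever the combined
sample is small and tie-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["RankSumResult", "wilcoxon_rank_sum", "bonferroni_alpha"]

#: Largest combined sample size for which the exact null is enumerated.
EXACT_MAX_TOTAL = 12


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of a two-sided Wilcoxon rank-sum test.

    ``statistic`` is the sum of ranks of the first sample in the pooled
    ranking; ``method`` records whether the exact null distribution or the
    tie-corrected normal approximation produced ``p_value``.
    """

    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approx"


@lru_cache(maxsize=64)
def _exact_ranksum_pmf(n_a: int, n_total: int) -> dict[int, int]:
    """Counts of each rank-sum value over all C(n_total, n_a) assignments."""
    counts: dict[int, int] = {}
    for combo in combinations(range(1, n_total + 1), n_a):
        w = sum(combo)
        counts[w] = counts.get(w, 0) + 1
    return counts


def wilcoxon_rank_sum(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For tie-free samples with ``len(a) + len(b) <= 12`` the p-value is
    computed by exact enumeration of all rank assignments; the two-sided p
    doubles the smaller tail and is capped at 1.  Larger or tied samples
    fall back to the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([a, b])
    n_a, n_total = a.size, pooled.size
    has_ties = np.unique(pooled).size < n_total
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n_a].sum())

    if n_total <= EXACT_MAX_TOTAL and not has_ties:
        pmf = _exact_ranksum_pmf(n_a, n_total)
        total = sum(pmf.values())
        lower = sum(c for v, c in pmf.items() if v <= w)
        upper = sum(c for v, c in pmf.items() if v >= w)
        p = min(1.0, 2.0 * min(lower, upper) / total)
        return RankSumResult(statistic=w, p_value=p, method="exact")

    # Tie-corrected normal approximation on the rank sum.
    n_b = n_total - n_a
    mu = n_a * (n_total + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = (n_a * n_b / 12.0) * (n_total + 1 - tie_term / (n_total * (n_total - 1)))
    if var == 0:  # all observations identical
        return RankSumResult(statistic=w, p_value=1.0, method="normal-approx")
    z = (w - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return RankSumResult(statistic=w, p_value=p, method="normal-approx")


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison threshold ``family_alpha / m`` (Bonferroni)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m
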
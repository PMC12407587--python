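"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["rank_sum_test"]


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact null enumeration when both groups have <= 12 observations and
    the pooled data is tie-free; otherwise the normal approximation with tie
    and continuity corrections.

    Returns ``(statistic, pvalue)`` where the statistic is the Mann-Whitney U
    of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size <= 12 and y.size <= 12 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
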
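"""Small shared hypothesis-test helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def significance_stars(p: float) -> str:
    """Figure-label stars: ***<0.001, **<0.01, *<0.05, else empty."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) for independent groups.

    Exact enumeration when both groups have <= 25 observations and no ties;
    otherwise the normal approximation with tie correction.  Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
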
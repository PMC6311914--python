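"""Rank correlation and two-sample comparisons shared across the analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    note: str = "Spearman, mid-ranks for ties"


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    t_statistic: float
    p_value: float
    significant: bool
    n_a: int
    n_b: int


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Requires n >= 3 and non-constant inputs (a constant vector has no rank
    ordering, so the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("spearman needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman is undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), n=int(x.size), p_value=float(p))


def t_test(group_a, group_b, equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample Student's t-test (classical pooled-variance form
    by default; ``equal_var=False`` switches to Welch). Significance is the
    conventional p < 0.05."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        t_statistic=float(t), p_value=float(p),
        significant=bool(p < ALPHA), n_a=int(a.size), n_b=int(b.size),
    )
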
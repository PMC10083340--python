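"""Cohort statistics: variance homogeneity, location shift, correlation.

Thin, opinionated wrappers around the standard tests used to compare
fragmentation summaries between regions and between cohorts: Levene's test
for homogeneity of variance (mean-centered by default, median-centered —
Brown-Forsythe — by flag), the two-sided Wilcoxon/Mann-Whitney rank-sum
test (exact null for small samples without ties, tie-corrected normal
approximation otherwise), and the Pearson correlation with Fisher-z
confidence intervals on both r and R^2.  No multiple-testing correction is
applied by default (a Benjamini-Hochberg helper is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "TestResult",
    "CorrelationResult",
    "levene_test",
    "rank_sum_test",
    "pearson_with_ci",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    median: float
    sd: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method_name: str
    group_summaries: tuple[GroupSummary, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    r_ci: tuple[float, float]
    r_squared_ci: tuple[float, float]
    level: float
    n: int


def _summaries(groups: dict[str, np.ndarray]) -> tuple[GroupSummary, ...]:
    return tuple(
        GroupSummary(
            label=str(k),
            n=len(v),
            median=float(np.median(v)),
            sd=float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        )
        for k, v in groups.items()
    )


def levene_test(groups: dict[str, "np.ndarray"], center: str = "mean") -> TestResult:
    """Levene's test for homogeneity of variance across >= 2 groups.

    The classic form uses absolute deviations from the group *mean*;
    ``center="median"`` gives the Brown-Forsythe variant.  Degenerate case:
    when every group has zero spread the statistic is 0 and p = 1.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    devs = [
        np.abs(a - (np.mean(a) if center == "mean" else np.median(a))) for a in arrays
    ]
    if all(np.allclose(d, 0) for d in devs):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.levene(*arrays, center=center)
    return TestResult(
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        method_name=f"levene_{center}",
        group_summaries=_summaries({k: np.asarray(v, float) for k, v in groups.items()}),
    )


def rank_sum_test(a, b) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Uses the exact null distribution when both samples have n <= 8 and
    there are no ties; otherwise the tie-corrected normal approximation
    (without continuity correction, so identical samples give p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (a.size <= 8 and b.size <= 8) and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method_name="rank_sum_exact" if exact else "rank_sum_normal",
        group_summaries=_summaries({"a": a, "b": b}),
    )


def pearson_with_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson product-moment correlation with Fisher-z confidence intervals.

    The CI on r is the standard Fisher z-transform interval; the CI on R^2
    squares the r-interval endpoints, with the lower bound set to 0 when
    the r-interval spans 0 (R^2 cannot resolve the sign).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    ci = res.confidence_interval(confidence_level=level)
    r_lo, r_hi = float(ci.low), float(ci.high)
    if r_lo <= 0.0 <= r_hi:
        r2_lo = 0.0
        r2_hi = max(r_lo**2, r_hi**2)
    else:
        ends = sorted((r_lo**2, r_hi**2))
        r2_lo, r2_hi = ends
    return CorrelationResult(
        r=r,
        r_squared=r * r,
        p_value=float(res.pvalue),
        r_ci=(r_lo, r_hi),
        r_squared_ci=(r2_lo, r2_hi),
        level=level,
        n=int(x.size),
    )


def benjamini_hochberg(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg adjusted p-values (off by default in reports)."""
    reject, adjusted, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return reject, adjusted
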
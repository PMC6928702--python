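"""Walking-speed distribution descriptors and two-method comparison.

Summaries follow the usual descriptor table (mean, SD, median, min, max,
quartiles, skewness, kurtosis). Two speed distributions are compared with a
normality-gated test: Wilcoxon rank-sum when either sample departs from
normality (Shapiro-Wilk), otherwise an F-test on variances followed by a
pooled or Welch two-sample t-test. Empirical CDFs support the comparison
plots.

Conventions (documented because the tables' own rules are unknown):
quantiles use linear interpolation (type 7); kurtosis is raw, i.e. a normal
distribution sits near 3, not 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = [
    "DistributionSummary",
    "ComparisonResult",
    "summarize",
    "compare_distributions",
    "ecdf",
    "assign_bout_speeds",
]


@dataclass
class DistributionSummary:
    """Descriptors of a speed sample; skewness/kurtosis are ``None`` when
    undefined (n < 3 or zero spread)."""

    n: int
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float
    q1: float
    q3: float
    skewness: Optional[float]
    kurtosis: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "minimum": self.minimum,
            "maximum": self.maximum,
            "q1": self.q1,
            "q3": self.q3,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
        }


@dataclass
class ComparisonResult:
    """Outcome of the normality-gated two-sample comparison."""

    test_used: str  # {"wilcoxon_ranksum", "t_test"}
    p_value: float
    alpha: float = 0.05
    normality_p: tuple = ()
    variance_p: Optional[float] = None
    equal_var: Optional[bool] = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test_used": self.test_used,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "normality_p": list(self.normality_p),
            "variance_p": self.variance_p,
            "equal_var": self.equal_var,
        }


def _as_speeds(x, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise DataError(f"need at least {min_n} speed values, got {arr.size}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DataError("speeds must be positive and finite")
    return arr


def summarize(speeds) -> DistributionSummary:
    """Descriptor table for one speed sample (quantiles: linear/type 7)."""
    x = _as_speeds(speeds, min_n=1)
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    degenerate = x.size < 3 or sd == 0.0
    return DistributionSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        q1=float(np.quantile(x, 0.25)),
        q3=float(np.quantile(x, 0.75)),
        skewness=None if degenerate else float(stats.skew(x)),
        kurtosis=None if degenerate else float(stats.kurtosis(x, fisher=False)),
    )


def _f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = stats.f.cdf(f, a.size - 1, b.size - 1)
    return float(2 * min(p, 1 - p))


def compare_distributions(
    a,
    b,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> ComparisonResult:
    """Compare two speed distributions with a normality-gated test.

    Shapiro-Wilk assesses each sample; if either is non-normal the unpaired
    Wilcoxon rank-sum test is used. Otherwise an F-test decides between the
    pooled-variance and Welch t-test.
    """
    xa = _as_speeds(a, min_n=3)
    xb = _as_speeds(b, min_n=3)

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:  # shapiro is undefined for constant input
            return 0.0
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(xa), _shapiro_p(xb)
    if pa < normality_alpha or pb < normality_alpha:
        stat = stats.ranksums(xa, xb)
        return ComparisonResult(
            test_used="wilcoxon_ranksum",
            p_value=float(stat.pvalue),
            alpha=alpha,
            normality_p=(pa, pb),
        )
    var_p = _f_test(xa, xb)
    equal_var = var_p >= alpha
    stat = stats.ttest_ind(xa, xb, equal_var=equal_var)
    return ComparisonResult(
        test_used="t_test",
        p_value=float(stat.pvalue),
        alpha=alpha,
        normality_p=(pa, pb),
        variance_p=var_p,
        equal_var=equal_var,
    )


def ecdf(speeds) -> np.ndarray:
    """Right-continuous empirical CDF as an array of (value, fraction) rows.

    One row per distinct value; the last fraction is exactly 1.
    """
    x = _as_speeds(speeds, min_n=1)
    values, counts = np.unique(x, return_counts=True)
    frac = np.cumsum(counts) / x.size
    frac[-1] = 1.0
    return np.column_stack([values, frac])


def assign_bout_speeds(
    bouts,
    cycle_times: Sequence[float],
    cycle_speeds: Sequence[float],
    per: str = "bout",
) -> list[float]:
    """Map externally supplied per-cycle speeds onto detected bouts.

    Each cycle (time, speed) is attributed to the bout whose [start, end)
    span contains the cycle time. ``per="bout"`` returns one mean speed per
    bout that received at least one cycle; ``per="cycle"`` returns the raw
    matched speeds.
    """
    if per not in ("bout", "cycle"):
        raise DataError("per must be 'bout' or 'cycle'")
    ct = np.asarray(cycle_times, dtype=float)
    cs = np.asarray(cycle_speeds, dtype=float)
    if ct.shape != cs.shape:
        raise DataError("cycle_times and cycle_speeds must align")
    out: list[float] = []
    for b in bouts:
        sel = cs[(ct >= b.start) & (ct < b.end)]
        if sel.size == 0:
            continue
        if per == "bout":
            out.append(float(sel.mean()))
        else:
            out.extend(float(v) for v in sel)
    return out
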
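"""Group-comparison statistics for small-n animal studies.

The decision flow is the conventional one for 7–8 animals per group:

1. Shapiro–Wilk normality per group (α = 0.05); Dixon's Q screens each
   group for outliers (reported, never removed).
2. If both groups pass normality: an F-test compares variances and a
   two-tailed unpaired t-test is run, pooled when variances are equal and
   Welch-corrected otherwise.
3. Otherwise: Levene's test documents the variance comparison and the
   comparison itself is a Kruskal–Wallis test (with two groups this is the
   rank test equivalent to Mann–Whitney up to tie handling).

Matched 2 μm / 1 μm acquisitions of the same specimens are compared with a
paired t-test and summarised by the relative difference
100·(mean₂μm − mean₁μm)/mean₁μm.

Derived physiology quantities live here too: the insulin-resistance index
HOMA-IR = (fasting glucose [mg/dL] × fasting insulin [mU/L]) / 405, and
percent-difference / fold-change effect descriptors rounded to one decimal
(half away from zero) as conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ComparisonReport",
    "homa_ir",
    "percent_difference",
    "fold_change",
    "compare_groups",
    "dixon_q",
    "paired_resolution_compare",
    "pearson_r",
]

ALPHA = 0.05

# Two-sided Dixon r10 critical values at alpha = 0.05 (classical table).
_DIXON_Q95 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
    10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
    16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
    22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
    28: 0.305, 29: 0.301, 30: 0.298,
}


@dataclass
class GroupSample:
    """One experimental group's values for a single metric."""

    label: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a group needs at least 2 scalar values")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


@dataclass
class ComparisonReport:
    test_used: str
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    relative_difference_pct: float
    normal_a: bool | None = None
    normal_b: bool | None = None
    shapiro_p: tuple[float, float] | None = None
    variance_equal: bool | None = None
    variance_test: str | None = None
    variance_p: float | None = None
    outlier_flags: dict = field(default_factory=dict)
    note: str = ""


def _round_half_away(x: float, ndigits: int) -> float:
    f = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * f + 0.5), x) / f


def homa_ir(fbg_mg_dl: float, fpi_mU_L: float) -> float:
    """HOMA-IR = (fasting glucose × fasting insulin) / 405.

    Glucose in mg/dL, insulin in mU/L; 405 absorbs the units.
    """
    if fbg_mg_dl < 0 or fpi_mU_L < 0:
        raise ValueError("inputs must be non-negative")
    return fbg_mg_dl * fpi_mU_L / 405.0


def percent_difference(test_mean: float, ref_mean: float,
                       ndigits: int | None = 1) -> float:
    """100 × (test − ref)/ref, printed to one decimal by default."""
    if ref_mean == 0:
        raise ValueError("reference mean must be non-zero")
    val = 100.0 * (test_mean - ref_mean) / ref_mean
    return _round_half_away(val, ndigits) if ndigits is not None else val


def fold_change(test_mean: float, ref_mean: float,
                ndigits: int | None = 1) -> float:
    """test/ref, printed to one decimal by default."""
    if not (ref_mean > 0):
        raise ValueError("reference mean must be positive")
    val = test_mean / ref_mean
    return _round_half_away(val, ndigits) if ndigits is not None else val


def dixon_q(values, alpha: float = ALPHA) -> np.ndarray:
    """Dixon's two-sided Q (r10) outlier screen at the 0.05 level.

    Returns a boolean flag per value (original order); at most the extreme
    value on each side can be flagged.  Valid for 3 <= n <= 30.
    """
    if alpha != 0.05:
        raise ValueError("critical values tabulated for alpha = 0.05 only")
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    if not (3 <= n <= 30):
        raise ValueError("Dixon's test requires 3 <= n <= 30")
    flags = np.zeros(n, dtype=bool)
    rng_ = float(v.max() - v.min())
    if rng_ == 0:
        return flags
    order = np.argsort(v, kind="stable")
    s = v[order]
    crit = _DIXON_Q95[n]
    q_low = (s[1] - s[0]) / rng_
    q_high = (s[-1] - s[-2]) / rng_
    if q_low > crit:
        flags[order[0]] = True
    if q_high > crit:
        flags[order[-1]] = True
    return flags


def compare_groups(a: GroupSample, b: GroupSample,
                   alpha: float = ALPHA) -> ComparisonReport:
    """Two-group comparison following the normality-driven decision flow.

    ``b`` is the reference group for the relative difference.  The Dixon
    screen is reported but non-destructive.
    """
    if a.n < 3 or b.n < 3:
        raise ValueError("need n >= 3 per group for normality testing")
    sw_a = sps.shapiro(a.values).pvalue
    sw_b = sps.shapiro(b.values).pvalue
    normal_a, normal_b = sw_a > alpha, sw_b > alpha
    outliers = {}
    for g in (a, b):
        if 3 <= g.n <= 30:
            outliers[g.label] = dixon_q(g.values).tolist()

    if normal_a and normal_b:
        va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
        if vb == 0 and va == 0:
            var_p, equal = 1.0, True
        else:
            f = va / vb if vb > 0 else np.inf
            dfa, dfb = a.n - 1, b.n - 1
            cdf = sps.f.cdf(f, dfa, dfb)
            var_p = 2.0 * min(cdf, 1.0 - cdf)
            equal = var_p > alpha
        res = sps.ttest_ind(a.values, b.values, equal_var=equal)
        test_used = "t_equal_var" if equal else "t_unequal_var"
        var_test = "f_test"
    else:
        var_p = float(sps.levene(a.values, b.values, center="median").pvalue)
        equal = var_p > alpha
        res = sps.kruskal(a.values, b.values)
        test_used = "kruskal_wallis"
        var_test = "levene"

    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return ComparisonReport(
        test_used=test_used,
        p_value=p,
        mean_a=a.mean, sd_a=a.sd, mean_b=b.mean, sd_b=b.sd,
        relative_difference_pct=percent_difference(a.mean, b.mean, ndigits=None)
        if b.mean != 0 else float("nan"),
        normal_a=normal_a, normal_b=normal_b, shapiro_p=(float(sw_a), float(sw_b)),
        variance_equal=equal, variance_test=var_test, variance_p=float(var_p),
        outlier_flags=outliers,
    )


def paired_resolution_compare(m1, m2) -> ComparisonReport:
    """Paired t-test of matched per-specimen metrics at 1 μm (m1) vs 2 μm (m2).

    The relative difference is 100·(mean₂ − mean₁)/mean₁, i.e. the bias of
    the coarse acquisition relative to the fine one.
    """
    m1 = np.asarray(m1, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("matched metric vectors of equal length required")
    mean1, mean2 = float(m1.mean()), float(m2.mean())
    rel = 100.0 * (mean2 - mean1) / mean1 if mean1 != 0 else float("nan")
    note = ""
    if np.allclose(m1, m2):
        p = float("nan")
        note = "identical vectors: paired t-test undefined (zero differences)"
    else:
        p = float(sps.ttest_rel(m2, m1).pvalue)
    return ComparisonReport(
        test_used="paired_t", p_value=p,
        mean_a=mean2, sd_a=float(m2.std(ddof=1)),
        mean_b=mean1, sd_b=float(m1.std(ddof=1)),
        relative_difference_pct=rel, note=note,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)
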
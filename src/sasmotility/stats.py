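"""Statistical comparisons used throughout the analysis.

Nonparametric two-group comparison is the Mann–Whitney U test (exact by
enumeration for small tie-free samples, normal approximation with tie and
continuity correction otherwise); three or more groups use Kruskal–Wallis.
Displacement-vs-√time curves are compared by ordinary least squares with an
equality-of-slopes test (interaction term of the pooled regression).  A
single-outlier Grubbs screen is provided.  All p-values are reported raw
(no multiplicity correction), two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .metrics import DisplacementCurve


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    direction: int = 0     # sign of (location(a) − location(b)); 0 if tied

    def as_dict(self) -> dict:
        return {"test": self.test_name, "statistic": self.statistic,
                "p_value": self.p_value, "n": list(self.n_per_group),
                "direction": self.direction}


@dataclass
class SlopeComparison:
    slope_a: float
    se_a: float
    slope_b: float
    se_b: float
    statistic: float       # t statistic of the interaction term
    p_value: float

    @property
    def slope_difference(self) -> float:
        return self.slope_a - self.slope_b

    def as_dict(self) -> dict:
        return {"slope_a": self.slope_a, "se_a": self.se_a,
                "slope_b": self.slope_b, "se_b": self.se_b,
                "statistic": self.statistic, "p_value": self.p_value}


@dataclass
class GrubbsResult:
    outlier_index: int | None
    g_statistic: float
    critical_value: float
    alpha: float
    degenerate: bool = False    # zero-variance input


def _direction(a: np.ndarray, b: np.ndarray) -> int:
    d = float(np.median(a) - np.median(b))
    return 0 if d == 0 else (1 if d > 0 else -1)


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 mode: str = "auto") -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    ``mode`` is ``exact`` (full null distribution; requires tie-free data),
    ``approx`` (normal approximation with mid-rank ties, tie correction and
    continuity correction), or ``auto``: exact when both samples have ≤ 10
    observations and there are no ties, approximate otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if mode == "auto":
        method = "exact" if (max(len(a), len(b)) <= 10 and not ties) \
            else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return GroupComparison("mann_whitney", float(res.statistic),
                           float(min(res.pvalue, 1.0)), (len(a), len(b)),
                           _direction(a, b))


def kruskal_wallis(*groups: Sequence[float]) -> GroupComparison:
    """Kruskal–Wallis H test (tie-corrected, χ² p with k−1 df) for ≥3 groups."""
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis needs >= 3 groups; use mann_whitney "
                         "for two")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrs):
        raise ValueError("empty group")
    if all(np.array_equal(arrs[0], g) for g in arrs[1:]):
        # identical groups: H = 0, p = 1 (scipy raises on all-identical data)
        return GroupComparison("kruskal_wallis", 0.0, 1.0,
                               tuple(len(g) for g in arrs))
    res = sps.kruskal(*arrs)
    return GroupComparison("kruskal_wallis", float(res.statistic),
                           float(res.pvalue), tuple(len(g) for g in arrs))


def t_test_two_tailed(a: Sequence[float], b: Sequence[float],
                      welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t test, pooled variance by default
    (Welch by flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t test requires n >= 2 per group")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
    stat = 0.0 if math.isnan(res.statistic) else float(res.statistic)
    return GroupComparison("t_welch" if welch else "t_pooled", stat, p,
                           (len(a), len(b)),
                           int(np.sign(np.mean(a) - np.mean(b))))


# ---------------------------------------------------------------------------
# regression on √time
# ---------------------------------------------------------------------------

def sqrt_time_fit(curve: DisplacementCurve) -> tuple[float, float, float]:
    """OLS fit of mean displacement on √τ: returns (slope, intercept, R²).

    For a random walk the mean displacement grows linearly in √τ through
    the origin; for ballistic motion the relation is convex.
    """
    x = np.sqrt(curve.time_grid)
    y = curve.mean
    ok = ~np.isnan(y)
    res = sps.linregress(x[ok], y[ok])
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, its SE, and residual SS of a simple OLS fit."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate abscissa: all x values equal")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float((resid**2).sum())
    se = math.sqrt(rss / (n - 2) / sxx) if n > 2 else float("nan")
    return slope, se, rss


def fit_and_compare_slopes(
    x_a: Sequence[float], y_a: Sequence[float],
    x_b: Sequence[float], y_b: Sequence[float],
) -> SlopeComparison:
    """Per-group OLS slopes and the pooled-regression equality-of-slopes
    test (t on the group × abscissa interaction term).

    Exactly coincident noiseless lines give p = 1; distinct noiseless lines
    give p = 0.
    """
    x_a = np.asarray(x_a, float); y_a = np.asarray(y_a, float)
    x_b = np.asarray(x_b, float); y_b = np.asarray(y_b, float)
    if len(x_a) < 3 or len(x_b) < 3:
        raise ValueError("need >= 3 points per group")
    slope_a, se_a, _ = _ols_slope(x_a, y_a)
    slope_b, se_b, _ = _ols_slope(x_b, y_b)

    # pooled model: y = b0 + b1*x + b2*g + b3*(x*g)
    x = np.concatenate([x_a, x_b])
    y = np.concatenate([y_a, y_b])
    g = np.concatenate([np.zeros(len(x_a)), np.ones(len(x_b))])
    X = np.column_stack([np.ones(len(x)), x, g, x * g])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise ValueError("degenerate design in pooled slope regression")
    resid = y - X @ coef
    dof = len(y) - 4
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    se_int = math.sqrt(max(s2 * xtx_inv[3, 3], 0.0))
    diff = float(coef[3])
    y_scale = max(float(np.mean(y**2)), 1e-30)
    slope_scale = max(abs(slope_a), abs(slope_b), 1.0)
    if s2 <= 1e-18 * y_scale:
        # numerically perfect fit: equality decided by the coefficient
        exact_equal = abs(diff) <= 1e-8 * slope_scale
        t_stat = 0.0 if exact_equal else float("inf")
        p = 1.0 if exact_equal else 0.0
    else:
        t_stat = diff / se_int
        p = float(2.0 * sps.t.sf(abs(t_stat), dof))
    return SlopeComparison(slope_a, se_a, slope_b, se_b, t_stat, p)


def compare_displacement_slopes(
    curve_a: DisplacementCurve, curve_b: DisplacementCurve,
    sqrt_time: bool = True,
) -> SlopeComparison:
    """Equality-of-slopes test between two cohort displacement curves,
    regressing mean displacement on √τ (or on τ)."""
    def xy(c: DisplacementCurve):
        ok = ~np.isnan(c.mean)
        x = c.time_grid[ok]
        return (np.sqrt(x) if sqrt_time else x), c.mean[ok]

    xa, ya = xy(curve_a)
    xb, yb = xy(curve_b)
    return fit_and_compare_slopes(xa, ya, xb, yb)


# ---------------------------------------------------------------------------
# Grubbs outlier screen
# ---------------------------------------------------------------------------

def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value:
    ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) Student-t quantile
    at n−2 degrees of freedom."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(x: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Single-outlier two-sided Grubbs test.

    G = max|x_i − mean| / sd; the most extreme observation is flagged iff
    G exceeds the critical value.  Zero-variance input yields no outlier
    with the statistic flagged undefined.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    crit = grubbs_critical_value(n, alpha)
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return GrubbsResult(None, float("nan"), crit, alpha, degenerate=True)
    dev = np.abs(x - x.mean())
    i = int(dev.argmax())
    g = float(dev[i] / sd)
    return GrubbsResult(i if g > crit else None, g, crit, alpha)
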
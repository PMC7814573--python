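"""Cohort statistics: rank-sum comparison, Noether power, ln-linear regression.

Group differences in HOMA-IR, insulin and glucose between lean and
overweight cats are tested with the Wilcoxon rank-sum (Mann-Whitney) test;
its power is expressed through the stochastic-superiority proportion
p'' = P(X < Y) via Noether's large-sample approximation.  Associations
with body fat percentage use ordinary least squares on the natural-log
scale, with slopes interpreted as percent change per BF% unit.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

EXACT_MAX_N = 12


@dataclasses.dataclass
class GroupComparison:
    """Two-group descriptive block plus the rank-sum test."""

    n1: int
    n2: int
    median1: float
    median2: float
    q1_1: float
    q3_1: float
    q1_2: float
    q3_2: float
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    rank_sum_statistic: float
    p_two_sided: float
    method: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PowerSpec:
    """Noether power specification; exactly one of power / p_doubleprime unknown."""

    n1: int
    n2: int
    alpha: float = 0.05
    power: Optional[float] = None
    p_doubleprime: Optional[float] = None


@dataclasses.dataclass
class RegressionResult:
    """OLS of ln(response) on a predictor, with percent-change reading."""

    beta: float
    beta_se: float
    intercept: float
    r_squared: float
    p_value: float
    pct_change_per_10: float
    residual_skew: float
    residual_kurtosis: float
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _describe(x: np.ndarray) -> tuple[float, float, float, float, float]:
    # (median, Q1, Q3, mean, SD); quartiles by linear interpolation (type 7)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3), float(x.mean()), float(x.std(ddof=1))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], continuity: bool = True
) -> GroupComparison:
    """Wilcoxon rank-sum test with exact small-sample enumeration.

    The exact null distribution is used when min(n1, n2) <= 12 and the
    pooled data have no ties; otherwise the normal approximation with
    midranks, tie-corrected variance and (by default) continuity
    correction.  Two identical constant samples give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    med1, q11, q31, m1, s1 = _describe(x)
    med2, q12, q32, m2, s2 = _describe(y)

    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and min(x.size, y.size) <= EXACT_MAX_N
    if np.ptp(pooled) == 0.0:
        warnings.warn("all values identical in both groups; p set to 1")
        u1 = x.size * y.size / 2.0
        p = 1.0
        method = "degenerate"
    elif exact:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        u1, p = float(res.statistic), float(res.pvalue)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=continuity,
        )
        u1, p = float(res.statistic), float(res.pvalue)
        method = "normal_approx_tie_corrected"
    w = u1 + x.size * (x.size + 1) / 2.0  # rank sum of the first sample
    return GroupComparison(
        n1=int(x.size), n2=int(y.size),
        median1=med1, median2=med2,
        q1_1=q11, q3_1=q31, q1_2=q12, q3_2=q32,
        mean1=m1, mean2=m2, sd1=s1, sd2=s2,
        rank_sum_statistic=w,
        p_two_sided=min(p, 1.0),
        method=method,
    )


def noether(spec: PowerSpec) -> PowerSpec:
    """Complete a :class:`PowerSpec` via Noether's approximation.

    N = (z_{1-alpha/2} + z_power)^2 / (12 c (1-c) (p'' - 1/2)^2) with
    N = n1 + n2 and c = n1/N.  Solves for whichever of power or p'' is
    missing; p'' must exceed 1/2 (the first group is stochastically
    smaller).  Power counts both rejection tails, so it tends to alpha as
    p'' approaches 1/2.
    """
    if spec.n1 < 2 or spec.n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if not 0 < spec.alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if (spec.power is None) == (spec.p_doubleprime is None):
        raise ValueError("exactly one of power / p_doubleprime must be given")
    n = spec.n1 + spec.n2
    c = spec.n1 / n
    za = stats.norm.ppf(1 - spec.alpha / 2)
    rootk = np.sqrt(12.0 * c * (1 - c) * n)

    def power_at(p2: float) -> float:
        d = rootk * (p2 - 0.5)
        return float(stats.norm.cdf(d - za) + stats.norm.cdf(-d - za))

    if spec.p_doubleprime is None:
        if not spec.alpha < spec.power < 1:
            raise ValueError("power must lie in (alpha, 1)")
        from scipy.optimize import brentq

        p2 = brentq(lambda q: power_at(q) - spec.power, 0.5, 0.5 + 0.5 - 1e-12)
        return dataclasses.replace(spec, p_doubleprime=float(p2))
    if spec.p_doubleprime <= 0.5:
        raise ValueError("p'' must exceed 0.5")
    return dataclasses.replace(spec, power=power_at(spec.p_doubleprime))


def ln_regression(
    response: Sequence[float],
    predictor: Sequence[float],
    extra_predictor: Sequence[float] | None = None,
) -> RegressionResult:
    """OLS of ln(response) on the predictor (e.g. BF%).

    The slope is per predictor unit on the ln scale; ``pct_change_per_10``
    restates it as the percent change of the raw response per 10-unit
    increase.  Residual skewness and excess kurtosis are reported as
    normality diagnostics.  ``extra_predictor`` adds one covariate (e.g. a
    locomotor-signs flag) to the same model; the reported slope and p-value
    stay those of the primary predictor.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.size != x.size:
        raise ValueError("response and predictor lengths differ")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(y <= 0):
        raise ValueError("response must be strictly positive for the ln transform")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor has zero variance")
    cols = [x]
    if extra_predictor is not None:
        cols.append(np.asarray(extra_predictor, dtype=float))
    design = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(np.log(y), design).fit()
    resid = fit.resid
    return RegressionResult(
        beta=float(fit.params[1]),
        beta_se=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        pct_change_per_10=pct_change_per_delta(float(fit.params[1]), 10.0),
        residual_skew=float(stats.skew(resid)),
        residual_kurtosis=float(stats.kurtosis(resid)),
        n=int(y.size),
    )


def pct_change_per_delta(beta: float, delta: float) -> float:
    """Percent change of the raw response per ``delta`` predictor units."""
    return 100.0 * (np.exp(beta * delta) - 1.0)
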
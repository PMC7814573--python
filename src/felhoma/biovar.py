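"""Biological-variation indices from repeated-measures analyte series.

A two-level nested Gaussian random-effects model is fitted on the natural-
log scale to values from cats sampled on several occasions with duplicate
analyses:

    ln y_cor = mu + g_c + w_co + e_cor

with independent effects g_c ~ N(0, sd2_G) (between cats), w_co ~ N(0,
sd2_I) (within cat, between occasions) and e_cor ~ N(0, sd2_A) (between
duplicates, i.e. analytical).  Estimation is unbounded restricted maximum
likelihood (REML): point estimates may be negative as long as every
stratum variance (duplicate, occasion, cat level) stays positive.  For
balanced complete designs the REML solution coincides with the classical
nested-ANOVA mean-square estimators.

Variance components on the ln scale are converted to coefficients of
variation with Cole's equation CV = sqrt(exp(SD^2(ln x)) - 1), combined
into the index of individuality II = CV_G / sqrt(CV_I^2 + CV_A^2), and
into the asymmetric ln-scale reference change value

    RCV(%) = 100 exp{ +/- z sqrt(2 (SD_I^2(ln x) + SD_A^2(ln x))) }.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

logger = logging.getLogger("felhoma")

_LN2PI = math.log(2.0 * math.pi)


class DesignError(ValueError):
    """The repeated-measures design cannot support the nested model."""


# ---------------------------------------------------------------------------
# series container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BioVarSeries:
    """Long-format repeated measures: one row per (cat, occasion, replicate)."""

    cat_id: np.ndarray
    occasion: np.ndarray
    replicate: np.ndarray
    value: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.cat_id = np.asarray(self.cat_id)
        self.occasion = np.asarray(self.occasion, dtype=int)
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        n = self.value.size
        if not (self.cat_id.size == self.occasion.size == self.replicate.size == n):
            raise ValueError("all columns must have equal length")
        if n == 0:
            raise DesignError("empty series")
        if np.any(self.value <= 0):
            raise ValueError("values must be strictly positive (ln scale)")
        if len(np.unique(self.cat_id)) < 2:
            raise DesignError("need at least 2 cats")
        occ_per_cat = (
            pd.DataFrame({"c": self.cat_id, "o": self.occasion})
            .groupby("c")["o"]
            .nunique()
        )
        if occ_per_cat.min() < 2:
            raise DesignError("every cat needs at least 2 sampling occasions")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, units: str = "") -> "BioVarSeries":
        return cls(
            cat_id=df["cat_id"].to_numpy(),
            occasion=df["occasion"].to_numpy(),
            replicate=df["replicate"].to_numpy(),
            value=df["value"].to_numpy(),
            units=units,
        )

    @classmethod
    def from_csv(cls, path, units: str = "") -> "BioVarSeries":
        return cls.from_dataframe(pd.read_csv(path), units=units)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cat_id": self.cat_id,
                "occasion": self.occasion,
                "replicate": self.replicate,
                "value": self.value,
            }
        )

    @property
    def n_cats(self) -> int:
        return len(np.unique(self.cat_id))

    @property
    def max_replicates(self) -> int:
        df = self.to_dataframe()
        return int(df.groupby(["cat_id", "occasion"]).size().max())


# ---------------------------------------------------------------------------
# REML fit
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class VarianceComponents:
    """ln-scale variance components and fit diagnostics."""

    sd2_G: float
    sd2_I: float
    sd2_A: float
    converged: bool
    log_restricted_likelihood: float
    se: Optional[tuple[float, float, float]] = None
    n_obs: int = 0
    n_cats: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.sd2_G, self.sd2_I, self.sd2_A])


def _balanced_suffstats(df: pd.DataFrame):
    """Sufficient statistics for a balanced complete C x O x R design.

    Returns None when the design is not balanced complete.
    """
    sizes = df.groupby(["cat_id", "occasion"]).size()
    R = sizes.iloc[0]
    if sizes.nunique() != 1:
        return None
    occ = df.groupby("cat_id")["occasion"].nunique()
    O = occ.iloc[0]
    if occ.nunique() != 1:
        return None
    C = df["cat_id"].nunique()
    y = df["lny"].to_numpy()
    cell = df.groupby(["cat_id", "occasion"])["lny"].mean()
    catm = df.groupby("cat_id")["lny"].mean()
    grand = y.mean()
    ss_a = float(((y - df.groupby(["cat_id", "occasion"])["lny"].transform("mean")) ** 2).sum())
    ss_i = float(R * ((cell - cell.index.get_level_values(0).map(catm)) ** 2).sum())
    ss_g = float(O * R * ((catm - grand) ** 2).sum())
    return C, O, int(R), ss_a, ss_i, ss_g


def _neg2_reml_balanced(theta, C, O, R, ss_a, ss_i, ss_g):
    sG, sI, sA = theta
    lamA = sA
    lamI = sA + R * sI
    lamG = sA + R * sI + O * R * sG
    if lamA <= 0 or lamI <= 0 or lamG <= 0:
        return np.inf
    n = C * O * R
    df_a = C * O * (R - 1)
    df_i = C * (O - 1)
    val = (
        df_a * math.log(lamA)
        + df_i * math.log(lamI)
        + (C - 1) * math.log(lamG)
        + ss_a / lamA
        + ss_i / lamI
        + ss_g / lamG
        + math.log(n)
        + (n - 1) * _LN2PI
    )
    return val


def _cat_blocks(df: pd.DataFrame):
    """Per-cat observation vectors and occasion labels (dense path)."""
    blocks = []
    for _, g in df.groupby("cat_id", sort=False):
        occ = g["occasion"].to_numpy()
        # occasion indicator matrix Z (m x n_occ)
        _, inv = np.unique(occ, return_inverse=True)
        m = len(g)
        z = np.zeros((m, inv.max() + 1))
        z[np.arange(m), inv] = 1.0
        blocks.append((g["lny"].to_numpy(), z))
    return blocks


def _neg2_reml_dense(theta, blocks):
    sG, sI, sA = theta
    logdet = 0.0
    xtvx = 0.0
    xtvy = 0.0
    ytvy = 0.0
    n = 0
    for y, z in blocks:
        m = len(y)
        n += m
        v = sA * np.eye(m) + sI * (z @ z.T) + sG
        try:
            c, low = linalg.cho_factor(v, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        if np.any(np.diag(c) <= 0):
            return np.inf
        logdet += 2.0 * np.log(np.diag(c)).sum()
        ones = np.ones(m)
        vi_y = linalg.cho_solve((c, low), y, check_finite=False)
        vi_1 = linalg.cho_solve((c, low), ones, check_finite=False)
        xtvx += ones @ vi_1
        xtvy += ones @ vi_y
        ytvy += y @ vi_y
    if xtvx <= 0:
        return np.inf
    quad = ytvy - xtvy**2 / xtvx
    return logdet + math.log(xtvx) + quad + (n - 1) * _LN2PI


def _anova_start(df: pd.DataFrame) -> np.ndarray:
    """Moment-based starting values (exact ANOVA estimators when balanced)."""
    g = df.groupby(["cat_id", "occasion"])["lny"]
    within = g.transform("mean")
    sizes = g.size()
    df_a = int((sizes - 1).sum())
    sA = float(((df["lny"] - within) ** 2).sum() / df_a) if df_a > 0 else 0.0
    cell = g.mean()
    rbar = float(sizes.mean())
    catm = cell.groupby(level=0).mean()
    occ_per_cat = cell.groupby(level=0).size()
    dev = cell - cell.index.get_level_values(0).map(catm)
    df_i = int((occ_per_cat - 1).sum())
    ms_i = float((dev**2).sum() / df_i) if df_i > 0 else 0.0
    sI = max(ms_i - sA / rbar, 0.0)
    grand = float(catm.mean())
    obar = float(occ_per_cat.mean())
    c = len(catm)
    ms_g = float(((catm - grand) ** 2).sum() / (c - 1)) if c > 1 else 0.0
    sG = max(ms_g - sI / obar - sA / (obar * rbar), 0.0)
    return np.array([sG, sI, sA])


def fit_nested_reml(
    series: BioVarSeries, compute_se: bool = True
) -> VarianceComponents:
    """Unbounded REML for the two-level nested model on ln values.

    Maximizes the restricted log-likelihood over (sd2_G, sd2_I, sd2_A)
    without non-negativity constraints (the marginal covariance must stay
    positive definite).  Balanced complete designs use a closed-form
    likelihood in the nested-ANOVA sufficient statistics; unbalanced
    designs use per-cat dense covariance blocks.  Standard errors come
    from the curvature (observed information) at the optimum.
    """
    df = series.to_dataframe()
    if series.max_replicates < 2:
        raise DesignError("duplicates (R >= 2) required somewhere to identify sd2_A")
    df["lny"] = np.log(df["value"].to_numpy())
    n = len(df)
    ncats = series.n_cats

    if np.ptp(df["lny"].to_numpy()) == 0.0:
        return VarianceComponents(0.0, 0.0, 0.0, True, math.nan, None, n, ncats)

    suff = _balanced_suffstats(df)
    if suff is not None:
        obj = lambda th: _neg2_reml_balanced(th, *suff)  # noqa: E731
    else:
        blocks = _cat_blocks(df)
        obj = lambda th: _neg2_reml_dense(th, blocks)  # noqa: E731

    x0 = _anova_start(df)
    scale = max(x0.sum(), 1e-8)
    res = optimize.minimize(
        obj,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 1e-12 * scale,
            "fatol": 1e-12,
            "maxiter": 4000,
            "initial_simplex": x0 + scale * 0.1 * np.vstack([np.zeros(3), np.eye(3)]),
        },
    )
    theta = res.x
    loglik = -0.5 * obj(theta)
    se = _wald_se(obj, theta, scale) if compute_se else None
    fit = VarianceComponents(
        sd2_G=float(theta[0]),
        sd2_I=float(theta[1]),
        sd2_A=float(theta[2]),
        converged=bool(res.success and np.isfinite(loglik)),
        log_restricted_likelihood=float(loglik),
        se=se,
        n_obs=n,
        n_cats=ncats,
    )
    if not fit.converged:
        logger.warning("REML did not converge: %s", res.message)
    return fit


def _wald_se(obj, theta, scale) -> Optional[tuple[float, float, float]]:
    """SEs of the variance components from a finite-difference Hessian."""
    h = 1e-4 * np.maximum(np.abs(theta), 0.05 * scale)
    k = len(theta)
    hess = np.empty((k, k))
    f0 = obj(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fp = obj(theta + ei)
                fm = obj(theta - ei)
                hess[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                fpp = obj(theta + ei + ej)
                fpm = obj(theta + ei - ej)
                fmp = obj(theta - ei + ej)
                fmm = obj(theta - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(hess)):
        return None
    info = 0.5 * hess  # obj is -2 log restricted likelihood
    try:
        cov = linalg.inv(info)
    except linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d <= 0):
        return None
    se = np.sqrt(d)
    return (float(se[0]), float(se[1]), float(se[2]))


# ---------------------------------------------------------------------------
# CV conversion, II, RCV
# ---------------------------------------------------------------------------


def cv_from_sdln(sd_ln: float) -> float:
    """Cole's equation: CV(%) = 100 sqrt(exp(sd_ln^2) - 1).

    Negative inputs (possible from unbounded estimation upstream) are
    floored to zero with a warning, since the equation is undefined there.
    """
    if sd_ln < 0:
        warnings.warn("negative SD(ln x) floored to 0 before CV conversion")
        sd_ln = 0.0
    return 100.0 * math.sqrt(math.expm1(sd_ln**2))


def sdln_from_cv(cv_percent: float) -> float:
    """Inverse of Cole's equation: SD(ln x) = sqrt(ln(1 + (CV/100)^2))."""
    if cv_percent < 0:
        raise ValueError("CV must be >= 0")
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


def _var_to_cv(v: float) -> float:
    return cv_from_sdln(math.sqrt(v)) if v > 0 else 0.0


def wald_ci_components(
    fit: VarianceComponents, z: float = 1.96
) -> dict[str, tuple[float, float, float]]:
    """Wald CIs on the variance scale, expressed as CVs.

    For each component the interval estimate +/- z*SE is computed on the
    ln-scale variance, each endpoint is mapped through Cole's equation, and
    negative lower endpoints are set to zero.  Returns
    ``{component: (cv_point, cv_lower, cv_upper)}``.
    """
    if fit.se is None:
        raise ValueError("standard errors unavailable (singular information matrix)")
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, v, s in zip(
            ("G", "I", "A"), (fit.sd2_G, fit.sd2_I, fit.sd2_A), fit.se
        ):
            out[name] = (
                _var_to_cv(v),
                _var_to_cv(v - z * s),
                _var_to_cv(v + z * s),
            )
    return out


def index_of_individuality(cv_G: float, cv_I: float, cv_A: float) -> float:
    """II = CV_G / sqrt(CV_I^2 + CV_A^2).

    II < 0.7 indicates low individuality (population reference intervals
    useful); II > 1.7 high individuality (monitor with reference change
    values instead).
    """
    denom = math.hypot(cv_I, cv_A)
    if denom == 0:
        raise ValueError("CV_I and CV_A are both zero; II undefined")
    return cv_G / denom


def rcv(sd2_I_ln: float, sd2_A_ln: float, z: float = 1.96) -> tuple[float, float]:
    """Asymmetric ln-scale reference change value, as percentages.

    Returns (increase, decrease) with increase = 100 exp(+z d) and
    decrease = 100 exp(-z d), d = sqrt(2 (sd2_I + sd2_A)); a follow-up
    result above ``increase``% or below ``decrease``% of baseline is a
    significant change.  increase x decrease = 100^2 exactly.
    """
    if sd2_I_ln < 0 or sd2_A_ln < 0:
        raise ValueError("variance components must be >= 0 (floor upstream)")
    d = math.sqrt(2.0 * (sd2_I_ln + sd2_A_ln))
    return 100.0 * math.exp(z * d), 100.0 * math.exp(-z * d)


def rcv_from_cvs(cv_I: float, cv_A: float, z: float = 1.96) -> tuple[float, float]:
    """RCV from CVs in percent, via the inverse of Cole's equation."""
    return rcv(sdln_from_cv(cv_I) ** 2, sdln_from_cv(cv_A) ** 2, z)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BioVarIndices:
    """CVs with 95% CIs, index of individuality and RCV for one analyte."""

    cv_G: float
    cv_I: float
    cv_A: float
    ci_G: tuple[float, float]
    ci_I: tuple[float, float]
    ci_A: tuple[float, float]
    ii: float
    rcv_increase_pct: float
    rcv_decrease_pct: float
    z: float
    n_cats: int
    n_occasions: int

    def to_dict(self) -> dict:
        """Table-style report (CVs 1 dp, II 2 dp, RCV whole percent)."""
        return {
            "CV_G": round(self.cv_G, 1),
            "CV_G_95CI": [round(v, 1) for v in self.ci_G],
            "CV_I": round(self.cv_I, 1),
            "CV_I_95CI": [round(v, 1) for v in self.ci_I],
            "CV_A": round(self.cv_A, 1),
            "CV_A_95CI": [round(v, 1) for v in self.ci_A],
            "II": round(self.ii, 2),
            "RCV_increase_pct": round(self.rcv_increase_pct),
            "RCV_decrease_pct": round(self.rcv_decrease_pct),
            "z": self.z,
            "n_cats": self.n_cats,
            "n_occasions": self.n_occasions,
        }


def biovar_indices(series: BioVarSeries, z: float = 1.96) -> BioVarIndices:
    """Full biological-variation analysis of one analyte series."""
    fit = fit_nested_reml(series)
    cis = (
        wald_ci_components(fit, z)
        if fit.se is not None
        else {k: (math.nan, math.nan, math.nan) for k in "GIA"}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv_g = _var_to_cv(fit.sd2_G)
        cv_i = _var_to_cv(fit.sd2_I)
        cv_a = _var_to_cv(fit.sd2_A)
    inc, dec = rcv(max(fit.sd2_I, 0.0), max(fit.sd2_A, 0.0), z)
    df = series.to_dataframe()
    return BioVarIndices(
        cv_G=cv_g,
        cv_I=cv_i,
        cv_A=cv_a,
        ci_G=cis["G"][1:],
        ci_I=cis["I"][1:],
        ci_A=cis["A"][1:],
        ii=index_of_individuality(cv_g, cv_i, cv_a),
        rcv_increase_pct=inc,
        rcv_decrease_pct=dec,
        z=z,
        n_cats=series.n_cats,
        n_occasions=int(df.groupby("cat_id")["occasion"].nunique().max()),
    )


def rcv_threshold(baseline: float, indices: BioVarIndices) -> tuple[float, float]:
    """Per-individual significant-change bounds for a given baseline.

    Returns (decrease bound, increase bound) in the analyte's units: a
    follow-up value below the first or above the second is a significant
    change from ``baseline``.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return (
        baseline * indices.rcv_decrease_pct / 100.0,
        baseline * indices.rcv_increase_pct / 100.0,
    )


def rcv_threshold_from_cvs(
    baseline: float, cv_I: float, cv_A: float, z: float = 1.96
) -> tuple[float, float]:
    """Significant-change bounds straight from published CVs (percent)."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    inc, dec = rcv_from_cvs(cv_I, cv_A, z)
    return baseline * dec / 100.0, baseline * inc / 100.0


def tukey_duplicate_screen(
    series: BioVarSeries, k: float = 1.5
) -> tuple[BioVarSeries, list[tuple]]:
    """Optional pre-fit outlier screen on ln duplicate differences.

    Flags (cat, occasion) cells whose ln-scale duplicate spread lies beyond
    the Tukey fences of all duplicate spreads, removes those cells, and
    returns the screened series with the flagged cells.  OFF by default in
    the pipeline; every removal is logged.
    """
    df = series.to_dataframe()
    df["lny"] = np.log(df["value"])
    spread = df.groupby(["cat_id", "occasion"])["lny"].agg(lambda v: v.max() - v.min())
    dup = spread[spread > 0]
    if len(dup) < 4:
        return series, []
    q1, q3 = np.percentile(dup.to_numpy(), [25, 75])
    hi = q3 + k * (q3 - q1)
    flagged = [idx for idx, s in dup.items() if s > hi]
    if not flagged:
        return series, []
    keep = ~pd.MultiIndex.from_arrays([df["cat_id"], df["occasion"]]).isin(flagged)
    logger.warning("duplicate-outlier screen removed cells: %s", flagged)
    out = BioVarSeries.from_dataframe(df.loc[keep], units=series.units)
    return out, flagged
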
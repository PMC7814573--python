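"""Nested REML variance components, Cole CVs, II and RCV."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import felhoma as fh
from felhoma.biovar import (
    BioVarSeries,
    DesignError,
    VarianceComponents,
    tukey_duplicate_screen,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def nested_anova_oracle(series: BioVarSeries):
    """Closed-form nested-ANOVA estimators for a balanced C x O x R design."""
    df = series.to_dataframe()
    df["lny"] = np.log(df["value"])
    g = df.groupby(["cat_id", "occasion"])["lny"]
    sizes = g.size()
    R = int(sizes.iloc[0])
    assert sizes.nunique() == 1
    O = int(df.groupby("cat_id")["occasion"].nunique().iloc[0])
    C = df["cat_id"].nunique()
    cell = g.mean()
    catm = df.groupby("cat_id")["lny"].mean()
    ms_a = ((df["lny"] - g.transform("mean")) ** 2).sum() / (C * O * (R - 1))
    ms_i = R * ((cell - cell.index.get_level_values(0).map(catm)) ** 2).sum() / (
        C * (O - 1)
    )
    ms_g = O * R * ((catm - catm.mean()) ** 2).sum() / (C - 1)
    return (ms_g - ms_i) / (O * R), (ms_i - ms_a) / R, ms_a


def restricted_neg2_loglik_oracle(series: BioVarSeries, theta):
    """Brute-force -2 restricted log-likelihood via dense whole-sample matrices."""
    df = series.to_dataframe()
    y = np.log(df["value"].to_numpy())
    n = y.size
    cats = pd.factorize(df["cat_id"])[0]
    cells = df.groupby(["cat_id", "occasion"]).ngroup().to_numpy()
    zg = (cats[:, None] == np.arange(cats.max() + 1)).astype(float)
    zi = (cells[:, None] == np.arange(cells.max() + 1)).astype(float)
    sG, sI, sA = theta
    v = sA * np.eye(n) + sG * zg @ zg.T + sI * zi @ zi.T
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0:
        return np.inf
    vi = np.linalg.inv(v)
    ones = np.ones(n)
    xtvx = ones @ vi @ ones
    mu = (ones @ vi @ y) / xtvx
    r = y - mu
    return logdet + math.log(xtvx) + r @ vi @ r + (n - 1) * math.log(2 * math.pi)


# ---------------------------------------------------------------------------
# REML fit
# ---------------------------------------------------------------------------


def test_all_identical_observations_give_zero_components():
    df = pd.DataFrame(
        {
            "cat_id": np.repeat(["a", "b"], 4),
            "occasion": [1, 1, 2, 2] * 2,
            "replicate": [1, 2, 1, 2] * 2,
            "value": 3.3,
        }
    )
    fit = fh.fit_nested_reml(BioVarSeries.from_dataframe(df))
    assert (fit.sd2_G, fit.sd2_I, fit.sd2_A) == (0.0, 0.0, 0.0)
    assert fit.converged


@pytest.mark.parametrize("seed", [3, 11, 27])
def test_balanced_reml_equals_nested_anova_oracle(seed):
    series = fh.generate_biovar_series(
        fh.BioVarGenParams(n_cats=4, n_occasions=3, n_replicates=2, seed=seed)
    )
    fit = fh.fit_nested_reml(series)
    oracle = nested_anova_oracle(series)
    for est, exp in zip(fit.as_array(), oracle):
        assert est == pytest.approx(exp, rel=1e-6)


def test_unbalanced_reml_at_least_as_likely_as_anova_start():
    """With one replicate missing, the REML optimum must beat the moment start."""
    series = fh.generate_biovar_series(fh.BioVarGenParams(drop_one_replicate=True, seed=5))
    fit = fh.fit_nested_reml(series)
    at_opt = restricted_neg2_loglik_oracle(series, fit.as_array())
    # moment start from the complete-data closed form applied naively
    complete = fh.generate_biovar_series(fh.BioVarGenParams(seed=5))
    start = nested_anova_oracle(complete)
    assert at_opt <= restricted_neg2_loglik_oracle(series, start) + 1e-9
    # and the reported likelihood matches the independent dense computation
    assert -2.0 * fit.log_restricted_likelihood == pytest.approx(at_opt, rel=1e-8)


def test_reml_profile_grid_confirms_optimum():
    """No grid point around the optimum has higher restricted likelihood."""
    series = fh.generate_biovar_series(fh.BioVarGenParams(drop_one_replicate=True, seed=8))
    fit = fh.fit_nested_reml(series)
    best = restricted_neg2_loglik_oracle(series, fit.as_array())
    for scale in (0.8, 0.9, 1.1, 1.25):
        for axis in range(3):
            theta = fit.as_array()
            theta[axis] *= scale
            assert restricted_neg2_loglik_oracle(series, theta) >= best - 1e-9


def test_design_errors():
    one_cat = pd.DataFrame(
        {"cat_id": ["a"] * 4, "occasion": [1, 1, 2, 2], "replicate": [1, 2, 1, 2], "value": [1.0, 1.1, 1.2, 1.3]}
    )
    with pytest.raises(DesignError):
        BioVarSeries.from_dataframe(one_cat)
    no_dup = pd.DataFrame(
        {
            "cat_id": np.repeat(["a", "b"], 2),
            "occasion": [1, 2, 1, 2],
            "replicate": 1,
            "value": [1.0, 1.1, 1.2, 1.3],
        }
    )
    with pytest.raises(DesignError):
        fh.fit_nested_reml(BioVarSeries.from_dataframe(no_dup))
    with pytest.raises(ValueError):
        BioVarSeries.from_dataframe(no_dup.assign(value=[1.0, -1.0, 1.0, 1.0]))


# ---------------------------------------------------------------------------
# Cole conversion, Wald CIs
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sd_ln,cv",
    [(0.0, 0.0), (0.48086, 51.0), (0.0739, 7.4)],
)
def test_cv_from_sdln(sd_ln, cv):
    assert fh.cv_from_sdln(sd_ln) == pytest.approx(cv, abs=0.05)


@given(sd=st.floats(min_value=1e-6, max_value=0.05))
@settings(max_examples=50, derandomize=True)
def test_cv_small_sd_limit_and_monotonicity(sd):
    cv = fh.cv_from_sdln(sd)
    assert abs(cv - 100 * sd) / cv < 0.002
    assert fh.cv_from_sdln(sd * 1.5) > cv


def test_sdln_cv_roundtrip():
    for cv in (7.4, 38.0, 52.3):
        assert fh.cv_from_sdln(fh.sdln_from_cv(cv)) == pytest.approx(cv, rel=1e-12)


def test_wald_ci_degenerate_and_flooring():
    fit = VarianceComponents(
        sd2_G=0.04, sd2_I=0.02, sd2_A=0.001, converged=True,
        log_restricted_likelihood=0.0, se=(0.0, 0.05, 0.0),
    )
    cis = fh.wald_ci_components(fit)
    point_g = fh.cv_from_sdln(math.sqrt(0.04))
    assert cis["G"] == (point_g, point_g, point_g)  # SE=0 -> degenerate CI
    assert cis["I"][1] == 0.0  # negative lower variance endpoint -> CV floor 0


def test_wald_ci_coverage_for_dominant_component():
    """~95% of variance-scale Wald CIs cover the dominant CV (400 replicates)."""
    truth = (30.0, 40.0, 5.0)
    cover = 0
    n_rep = 400
    for i in range(n_rep):
        series = fh.generate_biovar_series(
            fh.BioVarGenParams(
                n_cats=20, n_occasions=4, n_replicates=2,
                cv_G=truth[0], cv_I=truth[1], cv_A=truth[2], seed=30_000 + i,
            )
        )
        lo, hi = fh.wald_ci_components(fh.fit_nested_reml(series))["I"][1:]
        cover += lo <= truth[1] <= hi
    assert cover / n_rep == pytest.approx(0.95, abs=0.04)


# ---------------------------------------------------------------------------
# II and RCV
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cvs,expected",
    [((52.3, 51.0, 7.4), 1.01), ((52.1, 38.0, 6.6), 1.35), ((0.0, 30.0, 5.0), 0.0)],
)
def test_index_of_individuality(cvs, expected):
    assert fh.index_of_individuality(*cvs) == pytest.approx(expected, abs=0.005)


def test_index_of_individuality_zero_denominator():
    with pytest.raises(ValueError):
        fh.index_of_individuality(10.0, 0.0, 0.0)


@given(k=st.floats(min_value=0.01, max_value=100))
@settings(max_examples=50, derandomize=True)
def test_ii_scale_invariance(k):
    base = fh.index_of_individuality(52.3, 51.0, 7.4)
    assert fh.index_of_individuality(52.3 * k, 51.0 * k, 7.4 * k) == pytest.approx(base)


def test_rcv_zero_variance():
    assert fh.rcv(0.0, 0.0) == (100.0, 100.0)


@given(
    si=st.floats(min_value=0, max_value=1),
    sa=st.floats(min_value=0, max_value=0.2),
    z=st.floats(min_value=0.5, max_value=3.5),
)
@settings(max_examples=100, derandomize=True)
def test_rcv_multiplicative_symmetry(si, sa, z):
    inc, dec = fh.rcv(si, sa, z)
    assert inc * dec == pytest.approx(100.0**2, rel=1e-9)
    assert inc >= 100.0 >= dec


def test_rcv_threshold_trivial_and_baseline_scaling():
    idx = fh.biovar_indices(
        fh.generate_biovar_series(fh.BioVarGenParams(seed=0))
    )
    lo, hi = fh.rcv_threshold(2.0, idx)
    assert lo == pytest.approx(2.0 * idx.rcv_decrease_pct / 100)
    assert hi == pytest.approx(2.0 * idx.rcv_increase_pct / 100)
    inc, dec = fh.rcv(0.0, 0.0)
    assert (1 * dec / 100, 1 * inc / 100) == (1.0, 1.0)


def test_duplicate_outlier_screen_flags_planted_cell():
    series = fh.generate_biovar_series(fh.BioVarGenParams(seed=1))
    df = series.to_dataframe()
    sel = (df["cat_id"] == "cat2") & (df["occasion"] == 3) & (df["replicate"] == 2)
    df.loc[sel, "value"] *= 25.0  # gross duplicate discrepancy
    screened, flagged = tukey_duplicate_screen(BioVarSeries.from_dataframe(df))
    assert ("cat2", 3) in flagged
    assert len(screened.value) == len(df) - 2 * len(flagged)
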
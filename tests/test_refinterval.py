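"""Tukey screening, Box-Cox fitting, robust limits and bootstrap CIs."""

import numpy as np
import pytest
from scipy import special

import felhoma as fh
from felhoma.refinterval import (
    DegenerateSample,
    _best_lambda,
    bootstrap_limit_ci,
    robust_limits,
    tukey_outliers,
)


# ---------------------------------------------------------------------------
# Tukey outliers
# ---------------------------------------------------------------------------


def test_tukey_flags_point_beyond_fence():
    values = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 7.0]  # Q1=1, Q3=3, fence=6
    kept, flagged = tukey_outliers(values)
    assert list(flagged) == [7.0]
    assert len(kept) == 6


def test_tukey_flags_nothing_on_regular_sample():
    x = np.linspace(-2, 2, 41)
    kept, flagged = tukey_outliers(x)
    assert flagged.size == 0 and kept.size == 41


def test_tukey_planted_extreme_among_61(lean_homa_base_60):
    values = np.append(lean_homa_base_60, 8.0)
    kept, flagged = tukey_outliers(values)
    assert flagged.size == 1 and flagged[0] == 8.0
    assert kept.size == 60


def test_tukey_needs_four_values():
    with pytest.raises(ValueError):
        tukey_outliers([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


def test_boxcox_lambda_near_one_for_normal_data():
    x = np.random.default_rng(0).normal(10, 2, 500)
    lam, _ = fh.boxcox_fit(np.abs(x))
    assert abs(lam - 1) < 0.3


def test_boxcox_lambda_near_zero_for_lognormal_data():
    x = np.random.default_rng(0).lognormal(0, 0.5, 500)
    lam, _ = fh.boxcox_fit(x)
    assert abs(lam) < 0.2


@pytest.mark.parametrize("lam", [-1.0, 0.0, 0.5, 1.0])
def test_boxcox_transform_inverts(lam):
    x = np.array([0.2, 0.8, 1.0, 3.7])
    assert special.inv_boxcox(special.boxcox(x, lam), lam) == pytest.approx(x)


def test_boxcox_rejects_nonpositive():
    with pytest.raises(ValueError):
        fh.boxcox_fit([1.0, 0.0, 2.0])


# ---------------------------------------------------------------------------
# robust limits
# ---------------------------------------------------------------------------


def test_robust_limits_match_parametric_on_gaussian():
    x = np.random.default_rng(1).normal(0, 1, 10_000)
    lo, hi = robust_limits(x)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_robust_limits_resist_contamination():
    rng = np.random.default_rng(12)
    clean = rng.normal(0, 1, 2000)
    contaminated = clean.copy()
    contaminated[:40] = 10.0  # 2% gross contamination
    _, hi_clean = robust_limits(clean)
    _, hi_cont = robust_limits(contaminated)
    parametric_shift = (
        contaminated.mean() + 1.96 * contaminated.std(ddof=1)
    ) - (clean.mean() + 1.96 * clean.std(ddof=1))
    assert hi_cont - hi_clean < 0.25 * parametric_shift


def test_robust_limits_degenerate_on_constant_sample():
    with pytest.raises(DegenerateSample):
        robust_limits(np.full(50, 2.5))


def test_robust_limits_affine_equivariant():
    x = np.random.default_rng(3).normal(0, 1, 2000)
    lo, hi = robust_limits(x)
    a, b = 2.5, -7.0
    lo2, hi2 = robust_limits(a * x + b)
    assert lo2 == pytest.approx(a * lo + b, abs=1e-6)
    assert hi2 == pytest.approx(a * hi + b, abs=1e-6)


# ---------------------------------------------------------------------------
# bootstrap CIs
# ---------------------------------------------------------------------------


def test_bootstrap_deterministic_and_covers_gaussian_limits():
    x = np.random.default_rng(0).normal(0, 1, 500)
    first = bootstrap_limit_ci(x, B=1000, seed=11, transform="none")
    second = bootstrap_limit_ci(x, B=1000, seed=11, transform="none")
    assert first == second
    ci_lower, ci_upper, _ = first
    assert ci_lower[0] <= -1.96 <= ci_lower[1]
    assert ci_upper[0] <= 1.96 <= ci_upper[1]


def test_bootstrap_requires_seed_and_minimum_B():
    x = np.random.default_rng(0).normal(0, 1, 100)
    with pytest.raises(ValueError):
        bootstrap_limit_ci(x, B=1000, seed=None)
    with pytest.raises(ValueError):
        bootstrap_limit_ci(x, B=100, seed=1)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def test_reference_interval_gaussian_fixture():
    x = np.random.default_rng(1).normal(0, 1, 10_000)
    ri = fh.reference_interval(x, B=500, seed=2, transform="none",
                               nonnegative_analyte=False)
    assert ri.lower == pytest.approx(-1.96, abs=0.06)
    assert ri.upper == pytest.approx(1.96, abs=0.06)
    assert ri.boxcox_lambda is None


def test_reference_interval_lognormal_lower_limit_near_true_quantile():
    sigma = 0.6
    x = np.random.default_rng(5).lognormal(np.log(0.8), sigma, 400)
    ri = fh.reference_interval(x, B=500, seed=6)
    true_lower = 0.8 * np.exp(-1.96 * sigma)
    assert ri.lower == pytest.approx(true_lower, rel=0.10)
    assert abs(ri.boxcox_lambda) < 0.4  # near the ln transform


def test_reference_interval_skewed_n60_flags_wide_cis():
    """Small skewed samples give bootstrap CIs wider than the CLSI 0.2 rule."""
    x = np.random.default_rng(3).lognormal(np.log(0.8), 0.55, 61)
    ri = fh.reference_interval(x, B=500, seed=4)
    assert not ri.ci_width_adequate


def test_reference_interval_removes_planted_outlier(lean_homa_base_60):
    values = np.append(lean_homa_base_60, 8.0)
    ri = fh.reference_interval(values, B=500, seed=7)
    assert ri.outliers_removed == [8.0]
    assert ri.n_used == 60
    # interval contains the post-screen sample median
    med = float(np.median(lean_homa_base_60))
    assert ri.lower <= med <= ri.upper


def test_bootstrap_ci_shrinks_with_sample_size():
    widths = []
    for n, seed in [(60, 7), (240, 8)]:
        rep = []
        for k in range(3):
            x = np.random.default_rng(seed + 10 * k).lognormal(np.log(0.8), 0.5, n)
            ri = fh.reference_interval(x, B=500, seed=9)
            rep.append(
                (ri.ci_lower[1] - ri.ci_lower[0]) + (ri.ci_upper[1] - ri.ci_upper[0])
            )
        widths.append(np.median(rep))
    assert widths[1] < widths[0]
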
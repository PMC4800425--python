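"""Power-law regression: estimates, uncertainty, and oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from flysleep.exceptions import InsufficientDataError, UnidentifiableModelError
from flysleep.powerlaw import (
    PowerLawFit,
    PowerLawRegressor,
    confidence_band,
    dependency,
    fit_powerlaw,
    r_squared,
    weighted_fit_1_over_y2,
)

from conftest import oracle_powerlaw

# 3-point derived example: expected values frozen from the grid-search
# oracle in conftest (a(b) closed form + Brent refinement).
X3 = np.array([1.0, 2.0, 4.0])
Y3 = np.array([10.0, 6.0, 3.0])
ORACLE_A3, ORACLE_B3, ORACLE_SS3 = 10.0793680, -0.8172420, 0.14525273
ORACLE_R2_3 = 0.99411138  # 1 - 0.14525273 / 24.6666667
ORACLE_WA3, ORACLE_WB3 = 10.2807209, -0.8684828  # weights 1/y^2


def test_exact_power_law_recovered():
    """Points on y = 100 x^-1 give a = 100, b = -1, R² = 1, SSres = 0."""
    fit = fit_powerlaw([1, 2, 4], [100, 50, 25])
    assert fit.a == pytest.approx(100, abs=1e-8)
    assert fit.b == pytest.approx(-1, abs=1e-10)
    assert fit.ss_res == pytest.approx(0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1, abs=1e-12)
    assert fit.converged


def test_three_point_example_matches_grid_oracle():
    fit = fit_powerlaw(X3, Y3)
    assert fit.a == pytest.approx(ORACLE_A3, rel=1e-4)
    assert fit.b == pytest.approx(ORACLE_B3, rel=1e-4)
    assert fit.ss_res == pytest.approx(ORACLE_SS3, rel=1e-6)
    assert fit.r_squared == pytest.approx(ORACLE_R2_3, rel=1e-6)


def test_weighted_three_point_example_matches_weighted_oracle():
    fit = weighted_fit_1_over_y2(X3, Y3)
    assert fit.a == pytest.approx(ORACLE_WA3, rel=1e-4)
    assert fit.b == pytest.approx(ORACLE_WB3, rel=1e-4)


def test_scale_equivariance():
    """Scaling y by c scales a by c; b and R² are unchanged."""
    base = fit_powerlaw(X3, Y3)
    scaled = fit_powerlaw(X3, 7.5 * Y3)
    assert scaled.a == pytest.approx(7.5 * base.a, rel=1e-8)
    assert scaled.b == pytest.approx(base.b, rel=1e-8)
    assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-10)


def test_constant_weights_match_unweighted():
    base = fit_powerlaw(X3, Y3)
    w = fit_powerlaw(X3, Y3, weights=np.full(3, 3.7))
    assert (w.a, w.b) == pytest.approx((base.a, base.b), rel=1e-8)


def test_exact_points_same_fit_under_any_weights():
    unw = fit_powerlaw([1, 2, 4], [100, 50, 25])
    wgt = weighted_fit_1_over_y2([1, 2, 4], [100, 50, 25])
    assert (wgt.a, wgt.b) == pytest.approx((unw.a, unw.b), abs=1e-7)


@settings(max_examples=40, deadline=None)
@given(
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    n=st.integers(min_value=4, max_value=12),
    weighted=st.booleans(),
)
def test_oracle_equivalence_on_small_inputs(seed, n, weighted):
    """SSres of the fit matches the grid-search oracle within 1e-3 relative."""
    rng = np.random.default_rng(seed)
    x = rng.integers(1, 30, n).astype(float)
    if len(np.unique(x)) < 2:
        x[0] += 1
    a0, b0 = rng.uniform(50, 700), rng.uniform(-1.5, -0.5)
    y = a0 * x**b0 * np.exp(rng.normal(0, 0.2, n))
    w = 1 / y**2 if weighted else None
    fit = fit_powerlaw(x, y, weights=w)
    _, _, ss_oracle = oracle_powerlaw(x, y, w)
    ss_fit = float(np.sum((np.ones(n) if w is None else w) * (y - fit.predict(x)) ** 2))
    assert ss_fit <= ss_oracle * (1 + 1e-3) + 1e-12


def test_r_squared_definition_and_sentinels():
    fit = fit_powerlaw(X3, Y3)
    # independent evaluation of 1 - SSres/SStot
    ss_res = np.sum((Y3 - fit.a * X3**fit.b) ** 2)
    ss_tot = np.sum((Y3 - Y3.mean()) ** 2)
    assert r_squared(X3, Y3, fit) == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
    # a fit forced to the horizontal mean line has R² = 0 by construction
    mean_fit = PowerLawFit(
        a=float(Y3.mean()), b=0.0, covariance=np.zeros((2, 2)), r_squared=0.0,
        ss_res=ss_tot, ss_tot=ss_tot, ci_a=(0, 0), ci_b=(0, 0),
        dependency=0.0, n=3, dof=1, converged=True)
    assert r_squared(X3, Y3, mean_fit) == pytest.approx(0.0, abs=1e-12)
    # all y equal: SStot = 0, undefined
    assert np.isnan(r_squared([1, 2, 4], [5, 5, 5], mean_fit))


def test_error_conditions():
    with pytest.raises(InsufficientDataError):
        fit_powerlaw([1, 2], [3, 4])
    with pytest.raises(UnidentifiableModelError):
        fit_powerlaw([3, 3, 3], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_powerlaw([1, 2, 3], [1, -2, 3])
    with pytest.raises(ValueError):
        fit_powerlaw([0, 2, 3], [1, 2, 3])


def test_dependency_arithmetic_and_bounds():
    fit = fit_powerlaw(X3, Y3)
    fit.covariance = np.array([[4.0, 2.0], [2.0, 4.0]])
    assert dependency(fit) == pytest.approx(0.25)
    fit.covariance = np.diag([1.0, 2.0])
    assert dependency(fit) == 0.0
    fit.covariance = np.zeros((2, 2))
    assert np.isnan(dependency(fit))


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_dependency_in_unit_interval_on_random_fits(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(1, 40, 20).astype(float)
    x[0], x[1] = 1, 2
    y = 500 * x**-1.0 * np.exp(rng.normal(0, 0.3, 20))
    fit = fit_powerlaw(x, y)
    assert 0.0 <= fit.dependency <= 1.0


def test_band_zero_width_for_perfect_fit():
    fit = fit_powerlaw([1, 2, 4, 8], [100, 50, 25, 12.5])
    band = confidence_band(fit, [1, 2, 4])
    assert np.allclose(band.upper - band.lower, 0, atol=1e-6)
    assert np.allclose(band.fit, [100, 50, 25], atol=1e-6)


def test_band_matches_delta_method_arithmetic():
    """Band half-widths equal t * sqrt(g' C g) computed by hand."""
    fit = fit_powerlaw(X3, Y3)
    band = confidence_band(fit, X3)
    tcrit = stats.t.ppf(0.975, fit.dof)
    for i, xv in enumerate(X3):
        g = np.array([xv**fit.b, fit.a * xv**fit.b * np.log(xv)])
        half = tcrit * np.sqrt(g @ fit.covariance @ g)
        assert band.upper[i] - band.fit[i] == pytest.approx(half, rel=1e-10)
        assert band.fit[i] - band.lower[i] == pytest.approx(half, rel=1e-10)
    # at x = 1 the gradient is (1, 0): width depends only on var(a)
    band1 = confidence_band(fit, [1.0])
    assert band1.upper[0] - band1.fit[0] == pytest.approx(
        tcrit * np.sqrt(fit.covariance[0, 0]), rel=1e-10)
    # the band always contains the fitted curve
    assert (band.lower <= band.fit).all() and (band.fit <= band.upper).all()


def test_band_rejects_nonpositive_x():
    fit = fit_powerlaw(X3, Y3)
    with pytest.raises(ValueError):
        confidence_band(fit, [0.0, 1.0])


def test_fixed_exponent_closed_form():
    """With b fixed at -1 the scale equals sum(y/x) / sum(1/x²)."""
    rng = np.random.default_rng(3)
    x = rng.integers(1, 20, 30).astype(float)
    y = 600 / x * np.exp(rng.normal(0, 0.1, 30))
    est = PowerLawRegressor(fix_b=-1.0).fit(x, y)
    closed = np.sum(y / x) / np.sum(1.0 / x**2)
    assert est.a_ == pytest.approx(closed, rel=1e-12)
    assert est.b_ == -1.0
    assert est.ci_b_ == (-1.0, -1.0)


def test_ci_coverage_of_parameter_recovery():
    """95% CIs for (a, b) cover the truth ~95% of the time (500 sims).

    The generative noise is multiplicative (constant relative error), so
    the variance-matched 1/y² weighted fit is used: its covariance model
    agrees with the data-generating process, making coverage meaningful.
    """
    rng = np.random.default_rng(42)
    a0, b0, n = 600.0, -1.0, 40
    hits_a = hits_b = 0
    reps = 500
    for _ in range(reps):
        x = rng.integers(1, 25, n).astype(float)
        x[:2] = [1, 2]
        y = a0 * x**b0 * (1 + rng.normal(0, 0.05, n))
        fit = fit_powerlaw(x, y, weighting="inverse_y2")
        hits_a += fit.ci_a[0] <= a0 <= fit.ci_a[1]
        hits_b += fit.ci_b[0] <= b0 <= fit.ci_b[1]
    assert 0.90 <= hits_a / reps <= 0.99
    assert 0.90 <= hits_b / reps <= 0.99


def test_sklearn_estimator_contract():
    """get_params/set_params/clone/predict behave like sklearn estimators."""
    from sklearn.base import clone

    est = PowerLawRegressor(weighting="inverse_y2", ci_level=0.9)
    params = est.get_params()
    assert params["weighting"] == "inverse_y2" and params["ci_level"] == 0.9
    cloned = clone(est)
    cloned.fit(X3.reshape(-1, 1), Y3)
    assert cloned.predict([[1.0]])[0] == pytest.approx(cloned.a_)
    assert cloned.score(X3.reshape(-1, 1), Y3) <= 1.0


def test_weighted_r2_flag():
    """Default R² of a weighted fit uses unweighted sums of squares."""
    rng = np.random.default_rng(5)
    x = rng.integers(1, 15, 40).astype(float)
    y = 300 * x**-0.9 * np.exp(rng.normal(0, 0.3, 40))
    plain = weighted_fit_1_over_y2(x, y)
    ss_res = np.sum((y - plain.predict(x)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert plain.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)
    wr2 = fit_powerlaw(x, y, weighting="inverse_y2", weighted_r2=True)
    assert wr2.r_squared != pytest.approx(plain.r_squared)
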
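"""Laplace-transform calculus: closed forms, oracles and shape properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frailtysim.families import (
    FrailtyFamily,
    GammaFrailty,
    InverseGaussianFrailty,
    LogNormalFrailty,
    PositiveStableFrailty,
    get_family,
    laplace,
    laplace_derivative,
    marginal_hazard_ratio,
    median_concordance,
    posterior_expectation,
)

MEAN_ONE_FAMILIES = [GammaFrailty, InverseGaussianFrailty, LogNormalFrailty]
ALL_FAMILIES = MEAN_ONE_FAMILIES + [PositiveStableFrailty]


# ---------------------------------------------------------------------------
# Laplace transform values
# ---------------------------------------------------------------------------

def test_gamma_closed_form_values():
    fam = GammaFrailty(1.0)
    assert laplace(fam, 1.0) == pytest.approx(0.5, abs=1e-12)
    assert laplace_derivative(fam, 1, 1.0) == pytest.approx(-0.25, abs=1e-12)


@pytest.mark.parametrize("cls", ALL_FAMILIES)
def test_laplace_at_zero_is_one(cls):
    assert laplace(cls(2.0), 0.0) == pytest.approx(1.0, abs=1e-8)


def test_positive_stable_degenerate_limit():
    # theta = 0 gives b = 1: Z degenerate at 1, L(c) = exp(-c)
    fam = PositiveStableFrailty(0.0)
    assert laplace(fam, 1.0) == pytest.approx(np.exp(-1.0), rel=1e-12)


def test_negative_argument_rejected():
    with pytest.raises(ValueError):
        laplace(GammaFrailty(1.0), -0.5)


@pytest.mark.parametrize("cls", [GammaFrailty, InverseGaussianFrailty])
def test_nonpositive_theta_rejected(cls):
    with pytest.raises(ValueError):
        cls(0.0)


@pytest.mark.parametrize("cls", ALL_FAMILIES)
def test_zeroth_derivative_equals_laplace(cls):
    fam = cls(1.5)
    for c in (0.2, 1.0, 4.0):
        assert laplace_derivative(fam, 0, c) == pytest.approx(
            laplace(fam, c), rel=1e-10
        )


@pytest.mark.parametrize(
    "cls,kmax", [(GammaFrailty, 10), (InverseGaussianFrailty, 10),
                 (PositiveStableFrailty, 10), (LogNormalFrailty, 6)]
)
@pytest.mark.parametrize("theta", [0.5, 2.0, 8.0])
def test_complete_monotonicity_sign_alternation(cls, kmax, theta):
    fam = cls(theta)
    cs = np.array([0.05, 0.5, 2.0, 7.5, 20.0])
    for k in range(kmax + 1):
        vals = np.array([laplace_derivative(fam, k, c) for c in cs])
        assert np.all((-1.0) ** k * vals > 0)


def test_inverse_gaussian_derivative_matches_finite_differences():
    # high-order central finite difference of L as an independent oracle
    fam = InverseGaussianFrailty(2.0)
    c, h = 0.7, 5e-3
    # 7-point O(h^4) stencil for the third derivative
    weights = np.array([1 / 8, -1.0, 13 / 8, 0.0, -13 / 8, 1.0, -1 / 8])
    offsets = np.arange(-3, 4)
    fd = sum(w * laplace(fam, c + o * h) for w, o in zip(weights, offsets)) / h**3
    assert laplace_derivative(fam, 3, c) == pytest.approx(fd, rel=1e-6)


@pytest.mark.parametrize("cls", MEAN_ONE_FAMILIES)
@pytest.mark.parametrize("theta", [1.0, 4.0])
def test_mean_one_variance_inverse_theta(cls, theta):
    # E[Z] = -L'(0), Var[Z] = L''(0) - 1, via finite differences at 0
    fam = cls(theta)
    h = 1e-4
    l0, l1, l2 = (laplace(fam, i * h) for i in range(3))
    mean = -(l1 - l0) / h + h / 2 * (l2 - 2 * l1 + l0) / h**2  # O(h^2)
    var = (l2 - 2 * l1 + l0) / h**2 - 1.0
    assert mean == pytest.approx(1.0, abs=5e-4)
    assert var == pytest.approx(1.0 / theta, abs=5e-3)


def test_lognormal_high_order_raises():
    with pytest.raises(NotImplementedError):
        laplace_derivative(LogNormalFrailty(2.0), 11, 1.0)


def test_positive_stable_order_cap_raises():
    with pytest.raises(NotImplementedError):
        laplace_derivative(PositiveStableFrailty(1.0), 31, 1.0)


# ---------------------------------------------------------------------------
# posterior expectation
# ---------------------------------------------------------------------------

def test_posterior_prior_mean_is_one():
    for cls in MEAN_ONE_FAMILIES:
        assert posterior_expectation(cls(2.0), 0, 0.0) == pytest.approx(
            1.0, abs=1e-6
        )


def test_gamma_posterior_closed_form_examples():
    assert posterior_expectation(GammaFrailty(2.0), 1, 1.0) == pytest.approx(1.0)
    assert posterior_expectation(GammaFrailty(1.0), 0, 1.0) == pytest.approx(0.5)


def test_gamma_generic_route_matches_closed_form():
    # Laplace-derivative ratio vs (theta+n)/(theta+c) on a grid
    for theta in (0.3, 1.0, 5.0):
        fam = GammaFrailty(theta)
        for n in range(6):
            for c in (0.0, 0.4, 2.0, 9.0):
                generic = FrailtyFamily.posterior_expectation(fam, n, c)
                assert generic == pytest.approx(
                    (theta + n) / (theta + c), rel=1e-10
                )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    theta=st.floats(0.2, 20.0),
    c1=st.floats(0.01, 10.0),
    dc=st.floats(0.01, 10.0),
    n=st.integers(0, 8),
)
@pytest.mark.parametrize("cls", [GammaFrailty, InverseGaussianFrailty,
                                 PositiveStableFrailty])
def test_posterior_monotone_in_history(cls, theta, c1, dc, n):
    """Survivor selection: nonincreasing in hazard, nondecreasing in events."""
    fam = cls(theta)
    lo = posterior_expectation(fam, n, c1)
    hi = posterior_expectation(fam, n, c1 + dc)
    assert hi <= lo + 1e-12
    more_events = posterior_expectation(fam, n + 1, c1)
    assert more_events >= lo - 1e-12


# ---------------------------------------------------------------------------
# marginal hazard ratio (conditional hazard ratio 5)
# ---------------------------------------------------------------------------

LOG5 = float(np.log(5.0))


def test_marginal_hr_starts_at_conditional_ratio():
    for cls in MEAN_ONE_FAMILIES:
        assert marginal_hazard_ratio(cls(2.0), LOG5, 0.0) == pytest.approx(
            5.0, rel=1e-6
        )


def test_marginal_hr_gamma_closed_form():
    # 5 (theta + c) / (theta + 5 c) at theta=4, c=1
    assert marginal_hazard_ratio(GammaFrailty(4.0), LOG5, 1.0) == pytest.approx(
        25.0 / 9.0, rel=1e-12
    )


def test_marginal_hr_gamma_attenuates_to_one():
    fam = GammaFrailty(2.0)
    grid = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 20.0, 200.0])
    hr = marginal_hazard_ratio(fam, LOG5, grid)
    assert np.all(np.diff(hr) < 0)
    assert hr[0] == pytest.approx(5.0)
    assert hr[-1] == pytest.approx(1.0, abs=0.1)


def test_marginal_hr_positive_stable_is_time_constant():
    fam = PositiveStableFrailty(1.0)
    grid = np.array([0.1, 1.0, 10.0, 100.0])
    hr = marginal_hazard_ratio(fam, LOG5, grid)
    assert np.allclose(hr, 5.0 ** fam.b, rtol=1e-12)


# ---------------------------------------------------------------------------
# median concordance
# ---------------------------------------------------------------------------

def test_median_concordance_examples():
    assert median_concordance(PositiveStableFrailty(0.0)) == pytest.approx(0.0, abs=1e-12)
    assert median_concordance(GammaFrailty(1.0)) == pytest.approx(1.0 / 3.0, rel=1e-10)
    assert abs(median_concordance(GammaFrailty(1e6))) < 1e-5
    with pytest.raises(NotImplementedError):
        median_concordance(LogNormalFrailty(4.0))


def test_median_concordance_closed_form_matches_root_search():
    # generic bracketed inversion against the family-specific closed forms
    for fam in (GammaFrailty(1.7), InverseGaussianFrailty(0.8),
                PositiveStableFrailty(0.6)):
        c_root = FrailtyFamily.inverse_laplace(fam, 0.5)
        assert fam.laplace(c_root) == pytest.approx(0.5, abs=1e-9)
        generic = 4.0 * fam.laplace(2.0 * c_root) - 1.0
        assert median_concordance(fam) == pytest.approx(generic, abs=1e-8)


def _sample_frailty(fam, n, rng):
    if isinstance(fam, GammaFrailty):
        return rng.gamma(fam.theta, 1.0 / fam.theta, n)
    if isinstance(fam, InverseGaussianFrailty):
        return rng.wald(1.0, fam.theta, n)
    # positive stable via Chambers-Mallows-Stuck (totally skewed, index b)
    b = fam.b
    u = rng.uniform(0.0, np.pi, n)
    e = rng.exponential(1.0, n)
    return (np.sin(b * u) / np.sin(u) ** (1.0 / b)) * (
        np.sin((1.0 - b) * u) / e
    ) ** ((1.0 - b) / b)


@pytest.mark.parametrize(
    "fam", [GammaFrailty(1.0), InverseGaussianFrailty(2.0),
            PositiveStableFrailty(0.5)],
    ids=["gamma", "inverse_gaussian", "positive_stable"],
)
def test_median_concordance_monte_carlo_oracle(fam):
    """Pairs with shared frailty and unit-exponential conditional hazards."""
    rng = np.random.default_rng(2024)
    n = 1_000_000
    z = _sample_frailty(fam, n, rng)
    # sampler sanity: the empirical Laplace transform must match the family
    for c in (0.5, 2.0):
        emp = np.exp(-c * z).mean()
        assert emp == pytest.approx(fam.laplace(c), abs=4.0 / np.sqrt(n))
    t1 = rng.exponential(1.0, n) / z
    t2 = rng.exponential(1.0, n) / z
    m = fam.inverse_laplace(0.5)  # marginal median: S(t) = L(t) for unit hazard
    kappa_mc = np.mean(np.sign((t1 - m) * (t2 - m)))
    se = np.sqrt((1.0 - kappa_mc**2) / n)
    assert median_concordance(fam) == pytest.approx(kappa_mc, abs=3.0 * se)


def test_get_family_dispatch():
    assert isinstance(get_family("gamma", 1.0), GammaFrailty)
    with pytest.raises(ValueError):
        get_family("weibull", 1.0)
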
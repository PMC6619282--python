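"""Scenario resolution, censoring calibration and generator distributions."""

import numpy as np
import pytest
from scipy import stats

from frailtysim.simulate import (
    ScenarioConfig,
    beta1_for_level,
    calibrate_censoring,
    resolve_scenario,
    simulate_dataset,
)

LOG5 = float(np.log(5.0))


# ---------------------------------------------------------------------------
# derived constants
# ---------------------------------------------------------------------------

def test_weibull_scale_constraint():
    r = resolve_scenario(ScenarioConfig(weibull_shape=1.0), calibrate=False)
    assert r.weibull_scale == pytest.approx(0.016, rel=1e-12)
    for alpha in (0.8, 1.0, 2.0):
        r = resolve_scenario(
            ScenarioConfig(weibull_shape=alpha), calibrate=False
        )
        assert r.weibull_scale * 50.0**alpha == pytest.approx(0.8, rel=1e-12)
    rj = resolve_scenario(
        ScenarioConfig(structure="recurrent", group_size=5, total_size=300),
        calibrate=False,
    )
    assert rj.weibull_scale * 50.0 == pytest.approx(0.8 * 5, rel=1e-12)


def test_beta1_levels():
    # level 2 makes the effect cross zero at the horizon; level 1 is half
    full = beta1_for_level(2, LOG5, 50.0)
    assert LOG5 + full * np.log(50.0) == pytest.approx(0.0, abs=1e-12)
    assert round(full, 2) == -0.41
    assert round(beta1_for_level(1, LOG5, 50.0), 2) == -0.21
    assert beta1_for_level(0, LOG5, 50.0) == 0.0


def test_lognormal_moment_equations():
    r = resolve_scenario(
        ScenarioConfig(frailty_variance=0.25), calibrate=False
    )
    assert r.lognormal_s2 == pytest.approx(np.log(1.25), rel=1e-12)
    assert r.lognormal_mu == pytest.approx(-np.log(1.25) / 2, rel=1e-12)
    assert np.exp(r.lognormal_mu + r.lognormal_s2 / 2) == pytest.approx(1.0)


def test_shape_positivity_enforced():
    with pytest.raises(ValueError, match="shape"):
        resolve_scenario(
            ScenarioConfig(weibull_shape=0.4, beta1_level=2), calibrate=False
        )


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ScenarioConfig(group_size=7, total_size=300)
    with pytest.raises(ValueError):
        ScenarioConfig(structure="frail")
    with pytest.raises(ValueError):
        ScenarioConfig(frailty_law="weibull")


# ---------------------------------------------------------------------------
# censoring calibration
# ---------------------------------------------------------------------------

def test_calibration_exponential_special_case():
    # x forced to 0, alpha=1, no frailty: event times ~ Exp(gamma), so the
    # 0.7 quantile is -log(0.3)/gamma
    r = resolve_scenario(ScenarioConfig(covariate_p=0.0), calibrate=False)
    ct = calibrate_censoring(r, calib_subjects=100_000, seed=5)
    assert ct == pytest.approx(-np.log(0.3) / 0.016, rel=0.01)


def test_calibration_matches_brute_force_mixture_quantile():
    # x ~ Bernoulli(0.5): a 50/50 mixture of Exp(gamma) and Exp(5 gamma)
    r = resolve_scenario(ScenarioConfig(), calibrate=False)
    rng = np.random.default_rng(12)
    n = 1_000_000
    x = rng.random(n) < 0.5
    rate = 0.016 * np.where(x, 5.0, 1.0)
    oracle = np.quantile(rng.exponential(1.0 / rate), 0.7)
    ct = calibrate_censoring(r, calib_subjects=1_000_000, seed=6)
    assert ct == pytest.approx(oracle, rel=0.005)


@pytest.mark.parametrize(
    "cfg",
    [
        ScenarioConfig(group_size=2, total_size=100_000),
        ScenarioConfig(group_size=5, total_size=100_000, weibull_shape=0.8,
                       beta1_level=2, frailty_variance=0.25),
        ScenarioConfig(structure="recurrent", group_size=2,
                       total_size=100_000),
    ],
    ids=["null", "frailty-np", "recurrent"],
)
def test_censoring_rate_is_thirty_percent(cfg):
    resolved = resolve_scenario(cfg, calib_subjects=100_000, calib_seed=21)
    data = simulate_dataset(resolved, 99)
    if cfg.structure == "recurrent":
        # follow-up ends at the j-th event, so a single censored row can
        # stand in for several unobserved events: the 30% applies to the
        # generated events (the population whose 0.7 quantile was taken)
        n_subjects = cfg.total_size // cfg.group_size
        censored = 1.0 - data.status.sum() / (n_subjects * cfg.group_size)
    else:
        censored = 1.0 - data.status.mean()
    assert censored == pytest.approx(0.30, abs=0.01)


# ---------------------------------------------------------------------------
# generator distributions
# ---------------------------------------------------------------------------

def test_event_times_exponential_when_null():
    # sigma2=0, beta1=0, x=0, alpha=1: times are Exp(gamma)
    r = resolve_scenario(
        ScenarioConfig(covariate_p=0.0, total_size=10_000), calibrate=False
    ).with_censor_time(np.inf)
    data = simulate_dataset(r, 4)
    assert data.status.all()
    ks = stats.kstest(data.stop, "expon", args=(0.0, 1.0 / 0.016))
    assert ks.pvalue > 0.01


def test_weibull_shape_with_time_dependent_effect():
    # x=1, alpha=0.8, beta1 level 2: conditional shape is 0.8 - 0.41 = 0.39
    r = resolve_scenario(
        ScenarioConfig(weibull_shape=0.8, beta1_level=2, covariate_p=1.0,
                       total_size=20_000),
        calibrate=False,
    ).with_censor_time(np.inf)
    shape = 0.8 + r.beta1
    assert shape == pytest.approx(0.39, abs=0.005)
    data = simulate_dataset(r, 8)
    t = np.sort(data.stop)
    # empirical cumulative hazard H(t) = -log(1 - F_n); slope on log-log
    n = len(t)
    keep = slice(n // 100, -n // 100)
    H = -np.log1p(-(np.arange(1, n + 1) - 0.5) / n)
    slope = np.polyfit(np.log(t[keep]), np.log(H[keep]), 1)[0]
    assert slope == pytest.approx(shape, abs=0.02)


@pytest.mark.parametrize("law", ["lognormal", "gamma"])
def test_frailty_moments(law):
    cfg = ScenarioConfig(group_size=1, total_size=100_000,
                         frailty_variance=0.25, frailty_law=law)
    r = resolve_scenario(cfg, calibrate=False).with_censor_time(np.inf)
    z = simulate_dataset(r, 3).true_frailty
    se_mean = z.std() / np.sqrt(len(z))
    assert z.mean() == pytest.approx(1.0, abs=3 * se_mean)
    assert z.var() == pytest.approx(0.25, abs=0.02)


def test_clustered_common_covariate_constant_within_cluster():
    r = resolve_scenario(
        ScenarioConfig(structure="clustered_common", group_size=5,
                       total_size=500),
        calib_seed=31,
    )
    data = simulate_dataset(r, 17)
    df = data.to_frame()
    assert (df.groupby("cluster_id")["x"].nunique() == 1).all()
    # while in the plain clustered design x varies within clusters
    r2 = resolve_scenario(
        ScenarioConfig(group_size=5, total_size=500), calib_seed=31
    )
    df2 = simulate_dataset(r2, 17).to_frame()
    assert (df2.groupby("cluster_id")["x"].nunique() > 1).any()


def test_same_seed_reproduces_dataset_exactly():
    r = resolve_scenario(
        ScenarioConfig(structure="recurrent", group_size=3, total_size=300),
        calib_seed=41,
    )
    d1 = simulate_dataset(r, 123).to_frame()
    d2 = simulate_dataset(r, 123).to_frame()
    assert d1.equals(d2)
    assert not d1.equals(simulate_dataset(r, 124).to_frame())


def test_seed_is_required():
    r = resolve_scenario(ScenarioConfig(), calib_seed=51)
    with pytest.raises(ValueError, match="seed"):
        simulate_dataset(r, None)


def test_recurrent_event_count_oracle():
    """Events observed by the horizon follow min(Poisson(0.8 j), j), x = 0.

    Each subject is followed to their j-th event; with a unit frailty and
    x = 0 the process is Poisson with cumulative intensity 0.8 j at t = 50.
    """
    j = 3
    cfg = ScenarioConfig(structure="recurrent", group_size=j,
                         total_size=30_000, covariate_p=0.0)
    r = resolve_scenario(cfg, calibrate=False).with_censor_time(50.0)
    data = simulate_dataset(r, 77)
    counts = data.to_frame().groupby("subject_id")["status"].sum()
    lam = 0.8 * j
    k = np.arange(0, 200)
    pmf = stats.poisson.pmf(k, lam)
    expected = np.sum(np.minimum(k, j) * pmf)
    se = np.sqrt(np.sum((np.minimum(k, j) - expected) ** 2 * pmf) / len(counts))
    assert counts.mean() == pytest.approx(expected, abs=3 * se)


def test_proportional_hazards_effect_recovered_when_null():
    from frailtysim.cox import fit_cox

    r = resolve_scenario(
        ScenarioConfig(group_size=2, total_size=10_000), calib_seed=61
    )
    data = simulate_dataset(r, 5)
    fit = fit_cox(data)
    assert abs(fit.beta[0] - LOG5) < 0.05
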
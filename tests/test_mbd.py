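import math

import numpy as np
import pytest
from scipy import stats

from palaeodiv.bd_engine import RateProfile, bd_loglik_piecewise
from palaeodiv.covariates import EnvCurve
from palaeodiv.io_model import Lifespan, ShiftGrid
from palaeodiv.mbd import (
    MBDParams,
    MbdTrace,
    default_mbd_settings,
    horseshoe_shrinkage_weight,
    mbd_loglik,
    mbd_rate,
    mcmc_mbd,
    summarize_mbd,
)
from palaeodiv.experiments import simulate_mbd_dataset


def _const_curve(origin=10.0, value=5.0, name="c"):
    return EnvCurve(name, np.array([0.0, origin]), np.array([value, value]))


# ---------------------------------------------------------------------------
# rate link and likelihood
# ---------------------------------------------------------------------------


def test_mbd_rate_closed_forms():
    c = _const_curve(value=20.0)
    assert mbd_rate(3.0, 0.1, [0.0], [c]) == pytest.approx(0.1)
    assert mbd_rate(3.0, 0.1, [0.05], [c]) == pytest.approx(0.1 * math.e)
    two = [_const_curve(value=5.0, name="a"), _const_curve(value=5.0, name="b")]
    assert mbd_rate(3.0, 0.1, [0.1, -0.1], two) == pytest.approx(0.1)
    with pytest.raises(ValueError, match="coefficients"):
        mbd_rate(3.0, 0.1, [0.1], two)


def test_mbd_loglik_reduces_to_single_bin_bdcs(toy_lifespans):
    params = MBDParams(0.12, 0.07, np.zeros(1), np.zeros(1))
    v = mbd_loglik(toy_lifespans, params, [_const_curve()], integration_step=0.1)
    ref = bd_loglik_piecewise(
        toy_lifespans, RateProfile(ShiftGrid((10.0, 0.0)), np.array([0.12]), np.array([0.07]))
    )
    assert v == pytest.approx(ref, abs=1e-6)


def test_mbd_loglik_quadrature_converges(toy_lifespans):
    t = np.linspace(0.0, 10.0, 41)
    curve = EnvCurve("s", t, np.sin(t / 3.0))
    params = MBDParams(0.1, 0.05, np.array([0.3]), np.array([-0.2]))
    v1 = mbd_loglik(toy_lifespans, params, [curve], integration_step=0.1)
    v2 = mbd_loglik(toy_lifespans, params, [curve], integration_step=0.05)
    assert abs(v1 - v2) < 1e-4


def test_mbd_loglik_empty_and_coverage():
    assert mbd_loglik([], MBDParams(0.1, 0.1, np.zeros(1), np.zeros(1)), [_const_curve()]) == 0.0
    short = EnvCurve("c", np.array([0.0, 4.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="cover"):
        mbd_loglik([Lifespan("a", 8.0, 0.0)], MBDParams(0.1, 0.1, np.zeros(1), np.zeros(1)), [short])


# ---------------------------------------------------------------------------
# horseshoe
# ---------------------------------------------------------------------------


def test_shrinkage_weight_definition_and_limits():
    assert horseshoe_shrinkage_weight(1.0, 1.0) == pytest.approx(0.5)
    assert horseshoe_shrinkage_weight(2.0, 0.5) == pytest.approx(0.5)
    assert horseshoe_shrinkage_weight(1e-6, 1e-6) < 1e-9
    assert horseshoe_shrinkage_weight(1e6, 1.0) > 1.0 - 1e-9
    with pytest.raises(ValueError):
        horseshoe_shrinkage_weight(0.0, 1.0)
    with pytest.raises(ValueError):
        horseshoe_shrinkage_weight(1.0, -1.0)


def test_prior_sampling_reproduces_half_cauchy_tau():
    """With an information-free dataset the sampler must draw (tau, eps)
    from the horseshoe prior: the tau marginal is half-Cauchy(0, 1)."""
    lifespans = [Lifespan("a", 1.0, 0.0)]
    curve = _const_curve(origin=1.0)
    settings = default_mbd_settings(seed=0, n_replicates=1, n_iterations=400_000, sampling_freq=100)
    tr = mcmc_mbd(lifespans, [curve], settings)[0]
    tau = tr.post_burnin(tr.tau)
    expected = [math.tan(math.pi * q / 2.0) for q in (0.25, 0.5, 0.75)]
    got = np.quantile(tau, [0.25, 0.5, 0.75])
    for g, e in zip(got, expected):
        assert abs(g - e) / e < 0.30


def test_trace_length_and_omega_shape():
    lifespans, curves = simulate_mbd_dataset(0, n_min=50, n_max=2000)
    settings = default_mbd_settings(seed=0, n_replicates=2, n_iterations=2_000, sampling_freq=100)
    traces = mcmc_mbd(lifespans, curves, settings)
    assert len(traces) == 2
    assert len(traces[0]) == 2_000 // 100 + 1
    assert traces[0].omega.shape == (21, 4)
    assert np.all((traces[0].omega > 0) & (traces[0].omega < 1))


def test_rmdd_flag_appends_self_diversity_covariate():
    lifespans, curves = simulate_mbd_dataset(1, n_min=50, n_max=2000)
    settings = default_mbd_settings(seed=0, n_replicates=1, n_iterations=1_000, sampling_freq=100)
    with_dd = mcmc_mbd(lifespans, curves, settings, rm_dd=False)
    without = mcmc_mbd(lifespans, curves, settings, rm_dd=True)
    assert with_dd[0].covariate_names == ("driver", "noise", "self-diversity")
    assert without[0].covariate_names == ("driver", "noise")


def test_permuted_covariate_is_shrunk_harder():
    """Shuffling a driving covariate's values destroys its temporal signal;
    its shrinkage weight must drop below the intact copy's."""
    lifespans, curves = simulate_mbd_dataset(8)
    driver = curves[0]
    rng = np.random.default_rng(0)
    permuted = EnvCurve("permuted", driver.ages, rng.permutation(driver.values))
    settings = default_mbd_settings(seed=3, n_replicates=1, n_iterations=100_000, sampling_freq=200)
    traces = mcmc_mbd(lifespans, [driver, permuted], settings)
    summary, _ = summarize_mbd(traces)
    lam = summary[summary.rate == "lambda"].set_index("covariate")
    assert lam.loc["driver", "omega_mean"] > lam.loc["permuted", "omega_mean"]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def _trace_with(g_samples, eps_val, tau_val, names=("x",)):
    n = len(g_samples)
    ncov = len(names)
    g = np.tile(np.asarray(g_samples)[:, None], (1, ncov))
    return MbdTrace(
        covariate_names=names,
        lambda0=np.full(n, 0.1), mu0=np.full(n, 0.05),
        g_lambda=g, g_mu=np.zeros((n, ncov)),
        eps=np.full((n, 2 * ncov), eps_val), tau=np.full(n, tau_val),
        loglik=np.zeros(n), acceptance={}, burnin_fraction=0.0,
    )


def test_double_condition_significance_rule():
    rng = np.random.default_rng(0)
    pos = rng.uniform(0.02, 0.05, 500)  # HPD excludes 0
    spanning = rng.uniform(-0.02, 0.05, 500)  # HPD includes 0
    # omega 0.75 (released) vs 0.2 (shrunk): tau * eps = sqrt(3) vs 0.5
    released, _ = summarize_mbd([_trace_with(pos, math.sqrt(3.0), 1.0)])
    assert bool(released.iloc[0]["significant"]) is True
    weak_support, _ = summarize_mbd([_trace_with(pos, 0.5, 1.0)])
    assert bool(weak_support.iloc[0]["significant"]) is False  # omega < 0.5
    small_effect, _ = summarize_mbd([_trace_with(spanning, math.sqrt(3.0), 1.0)])
    assert bool(small_effect.iloc[0]["significant"]) is False  # HPD spans 0


def test_summarize_mbd_rate_envelopes():
    rng = np.random.default_rng(1)
    tr = _trace_with(rng.normal(0.0, 0.01, 400), 1.0, 1.0)
    curve = _const_curve(origin=20.0)
    summary, rates = summarize_mbd([tr], curves=[curve], rate_grid_step=5.0)
    assert rates is not None and len(rates) == 5
    assert np.all(rates["lambda_hpd_low"] <= rates["lambda_mean"])
    assert np.all(rates["lambda_mean"] <= rates["lambda_hpd_high"])
    assert rates["net_mean"].iloc[0] == pytest.approx(
        rates["lambda_mean"].iloc[0] - rates["mu_mean"].iloc[0], abs=1e-12
    )


def test_summarize_mbd_empty_error():
    with pytest.raises(ValueError):
        summarize_mbd([])


def test_mbd_params_validation():
    with pytest.raises(ValueError):
        MBDParams(0.0, 0.1, np.zeros(1), np.zeros(1))
    with pytest.raises(ValueError):
        MBDParams(0.1, 0.1, np.zeros(2), np.zeros(1))
    p = MBDParams(0.1, 0.1, np.zeros(1), np.zeros(1), eps=np.array([1.0, 1.0]), tau=1.0)
    assert np.allclose(p.omega, 0.5)
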
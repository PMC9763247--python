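import math

import numpy as np
import pytest
from scipy import stats

from palaeodiv.bd_engine import (
    BdTrace,
    McmcSettings,
    PreservationModel,
    RateProfile,
    bd_loglik_piecewise,
    discrete_gamma_means,
    mcmc_bdcs_lifespans,
    mcmc_bdcs_occurrences,
    preservation_loglik,
    resample_occurrence_ages,
    rtt_summary,
    tste_estimates,
)
from palaeodiv.experiments import bruteforce_bd_loglik, _random_small_dataset
from palaeodiv.io_model import FossilOccurrence, Lifespan, ShiftGrid, hpd_interval
from palaeodiv.synthetic_data import SimScenario, simulate_bd_process


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def test_bd_loglik_hand_computed_values():
    g = ShiftGrid((10.0, 0.0))
    one_extant = [Lifespan("A", 10.0, 0.0)]
    assert bd_loglik_piecewise(one_extant, RateProfile(g, np.array([0.1]), np.array([0.0]))) == pytest.approx(-1.0)
    two = [Lifespan("A", 10.0, 0.0), Lifespan("B", 5.0, 2.0)]
    expected = math.log(0.1) + math.log(0.05) - 0.15 * 13.0
    assert bd_loglik_piecewise(two, RateProfile(g, np.array([0.1]), np.array([0.05]))) == pytest.approx(expected)
    one_extinct = [Lifespan("A", 4.0, 1.0)]
    expected = math.log(0.1) - 0.3 * 3.0
    assert bd_loglik_piecewise(one_extinct, RateProfile(g, np.array([0.2]), np.array([0.1]))) == pytest.approx(expected)


def test_bd_loglik_zero_rate_with_events_is_minus_inf():
    g = ShiftGrid((10.0, 0.0))
    two = [Lifespan("A", 10.0, 0.0), Lifespan("B", 5.0, 2.0)]
    assert bd_loglik_piecewise(two, RateProfile(g, np.array([0.0]), np.array([0.1]))) == -np.inf
    assert bd_loglik_piecewise(two, RateProfile(g, np.array([0.1]), np.array([0.0]))) == -np.inf


def test_bd_loglik_rejects_lifespan_beyond_origin():
    g = ShiftGrid((10.0, 0.0))
    with pytest.raises(ValueError, match="origin"):
        bd_loglik_piecewise([Lifespan("A", 12.0, 0.0)], RateProfile(g, np.array([0.1]), np.array([0.1])))


def test_bd_loglik_matches_bruteforce_quadrature_on_random_data():
    rng = np.random.default_rng(7)
    for _ in range(20):
        lifespans, rates = _random_small_dataset(rng)
        assert bd_loglik_piecewise(lifespans, rates) == pytest.approx(
            bruteforce_bd_loglik(lifespans, rates), abs=1e-8
        )


def test_bd_loglik_invariant_under_bin_refinement():
    """Splitting a bin (same rates on both halves) leaves the likelihood
    unchanged."""
    lifespans = [Lifespan("A", 18.0, 0.0), Lifespan("B", 12.0, 4.0), Lifespan("C", 7.0, 1.0)]
    coarse = RateProfile(ShiftGrid((20.0, 10.0, 0.0)), np.array([0.2, 0.1]), np.array([0.05, 0.08]))
    fine = RateProfile(
        ShiftGrid((20.0, 15.0, 10.0, 5.0, 0.0)),
        np.array([0.2, 0.2, 0.1, 0.1]),
        np.array([0.05, 0.05, 0.08, 0.08]),
    )
    assert bd_loglik_piecewise(lifespans, coarse) == pytest.approx(
        bd_loglik_piecewise(lifespans, fine), abs=1e-10
    )


def test_preservation_loglik_hand_computed_values():
    pm = PreservationModel(ShiftGrid((10.0, 0.0)), np.array([0.5]), alpha=None)
    v = preservation_loglik({"A": [3.0, 4.0, 5.0]}, {"A": 8.0}, {"A": 2.0}, pm)
    assert v == pytest.approx(3 * math.log(0.5) - 3.0)
    pm2 = PreservationModel(ShiftGrid((10.0, 5.0, 0.0)), np.array([2.0, 1.0]), alpha=None)
    v2 = preservation_loglik({"A": [3.0, 6.0]}, {"A": 8.0}, {"A": 2.0}, pm2)
    assert v2 == pytest.approx(math.log(1.0) + math.log(2.0) - (1.0 * 3 + 2.0 * 3))


def test_preservation_gamma_discretization_limits():
    """K = 1 equals the alpha -> infinity limit; growing K converges to the
    exact (closed-form) gamma marginal."""
    pm_flat = PreservationModel(ShiftGrid((10.0, 0.0)), np.array([0.5]), alpha=None)
    pm_big_alpha = PreservationModel(ShiftGrid((10.0, 0.0)), np.array([0.5]), alpha=1e6, n_categories=4)
    args = ({"A": [3.0, 4.0, 5.0]}, {"A": 8.0}, {"A": 2.0})
    assert preservation_loglik(*args, pm_big_alpha) == pytest.approx(
        preservation_loglik(*args, pm_flat), abs=1e-3
    )
    # exact marginal: slogq + lgamma(a+n) - lgamma(a) + a ln a - (a+n) ln(a+L)
    alpha, n, lam_int, slogq = 1.3, 3, 0.5 * 6.0, 3 * math.log(0.5)
    exact = (
        slogq + math.lgamma(alpha + n) - math.lgamma(alpha)
        + alpha * math.log(alpha) - (alpha + n) * math.log(alpha + lam_int)
    )
    coarse = preservation_loglik(*args, PreservationModel(ShiftGrid((10.0, 0.0)), np.array([0.5]), alpha=alpha, n_categories=4))
    fine = preservation_loglik(*args, PreservationModel(ShiftGrid((10.0, 0.0)), np.array([0.5]), alpha=alpha, n_categories=512))
    assert abs(fine - exact) < abs(coarse - exact)
    assert fine == pytest.approx(exact, abs=5e-4)


def test_preservation_rejects_age_outside_lifespan():
    pm = PreservationModel(ShiftGrid((10.0, 0.0)), np.array([0.5]))
    with pytest.raises(ValueError, match="outside"):
        preservation_loglik({"A": [9.0]}, {"A": 8.0}, {"A": 2.0}, pm)


def test_discrete_gamma_means_average_to_one():
    for alpha in (0.3, 1.0, 4.2):
        m = discrete_gamma_means(alpha, 8)
        assert m.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(m) > 0)


# ---------------------------------------------------------------------------
# age resampling
# ---------------------------------------------------------------------------


def test_resample_occurrence_ages():
    occ = [FossilOccurrence("a", "extinct", 10.0, 10.0)]
    assert resample_occurrence_ages(occ, seed=0)[0] == 10.0
    occ = [FossilOccurrence("a", "extinct", 10.0, 20.0)] * 10_000
    ages = resample_occurrence_ages(occ, seed=1)
    assert abs(ages.mean() - 15.0) < 3 * ages.std() / 100.0
    assert np.array_equal(
        resample_occurrence_ages(occ, seed=2), resample_occurrence_ages(occ, seed=2)
    )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def test_trace_length_contract(small_fossil_dataset):
    d = small_fossil_dataset
    settings = McmcSettings(n_iterations=5_000, sampling_freq=250, seed=0, n_replicates=2)
    traces, tste = mcmc_bdcs_occurrences(d["occurrences"], d["grid"], d["grid"], settings)
    assert len(traces) == 2
    assert len(traces[0]) == 5_000 // 250 + 1
    assert set(tste.index) == set(d["truth"])


def test_tste_bounds_respect_occurrences(small_fossil_dataset):
    d = small_fossil_dataset
    settings = McmcSettings(n_iterations=50_000, sampling_freq=500, seed=3, n_replicates=2)
    traces, _ = mcmc_bdcs_occurrences(d["occurrences"], d["grid"], d["grid"], settings)
    for tr in traces:
        # bounds hold for every posterior sample, per replicate age draw
        ages = resample_occurrence_ages(d["occurrences"], seed=tr.seed)
        oldest: dict[str, float] = {}
        youngest: dict[str, float] = {}
        for occ, a in zip(d["occurrences"], ages):
            oldest[occ.species_id] = max(oldest.get(occ.species_id, 0.0), a)
            youngest[occ.species_id] = min(youngest.get(occ.species_id, np.inf), a)
        for j, sp in enumerate(tr.species_ids):
            assert tr.ts[:, j].min() >= oldest[sp] - 1e-9
            assert tr.te[:, j].max() <= youngest[sp] + 1e-9


def test_standing_diversity_augmentation(small_fossil_dataset):
    d = small_fossil_dataset
    settings = McmcSettings(
        n_iterations=5_000, sampling_freq=500, seed=0, n_replicates=1,
        extant_diversity=d["n_extant"] + 10,
    )
    traces, tste = mcmc_bdcs_occurrences(d["occurrences"], d["grid"], d["grid"], settings)
    latent = [s for s in traces[0].species_ids if s.startswith("_latent_")]
    n_extant_obs = len({o.species_id for o in d["occurrences"] if o.status == "extant"})
    assert len(latent) == d["n_extant"] + 10 - n_extant_obs
    assert not any(s.startswith("_latent_") for s in tste.index)
    bad = McmcSettings(n_iterations=5_000, sampling_freq=500, extant_diversity=1)
    with pytest.raises(ValueError, match="below"):
        mcmc_bdcs_occurrences(d["occurrences"], d["grid"], d["grid"], bad)


def test_lifespans_mode_ignores_preservation_settings(toy_lifespans):
    grid = ShiftGrid((10.0, 0.0))
    a = mcmc_bdcs_lifespans(toy_lifespans, grid, McmcSettings(n_iterations=10_000, sampling_freq=100, seed=1, n_replicates=1, p_preservation=0.2))
    b = mcmc_bdcs_lifespans(toy_lifespans, grid, McmcSettings(n_iterations=10_000, sampling_freq=100, seed=1, n_replicates=1, p_preservation=0.9))
    assert np.array_equal(a[0].lam, b[0].lam)
    assert np.array_equal(a[0].mu, b[0].mu)


def test_yule_posterior_matches_conjugate_gamma():
    """Extant-only data, rates-only sampling: the lambda marginal must match
    the analytic Gamma(1.1 + B, 1 + S) posterior implied by the prior."""
    rng = np.random.default_rng(0)
    lifespans = [Lifespan(f"s{i}", ts=float(rng.uniform(1, 29)), te=0.0) for i in range(40)]
    grid = ShiftGrid((30.0, 0.0))
    settings = McmcSettings(n_iterations=400_000, sampling_freq=200, seed=4, n_replicates=1)
    tr = mcmc_bdcs_lifespans(lifespans, grid, settings)[0]
    lam = tr.post_burnin(tr.lam)[:, 0][::4]  # thin the chain
    B = len(lifespans) - 1
    S = sum(l.ts for l in lifespans)
    ks = stats.kstest(lam, stats.gamma(a=1.1 + B, scale=1.0 / (1.0 + S)).cdf)
    assert ks.pvalue > 0.01


def test_two_bin_lambda_doubling_recovered():
    """lambda doubling at 30 Ma: posterior rate ratio lands near 2."""
    grid2 = ShiftGrid((60.0, 30.0, 0.0))
    ratios = []
    for seed in range(20):
        rates = RateProfile(grid2, np.array([0.1, 0.2]), np.array([0.05, 0.05]))
        pres_grid = ShiftGrid((60.0, 0.0))
        from palaeodiv.bd_engine import PreservationModel as PM

        sc = SimScenario(
            60.0, rates, PM(pres_grid, np.array([1.0])), ((0.0, 60.0),), seed=seed
        )
        lifespans, _ = simulate_bd_process(sc)
        if not 30 <= len(lifespans) <= 3000:
            continue
        settings = McmcSettings(n_iterations=100_000, sampling_freq=200, seed=seed, n_replicates=1)
        tr = mcmc_bdcs_lifespans(lifespans, grid2, settings)[0]
        lam = tr.post_burnin(tr.lam)
        ratios.append(lam[:, 1].mean() / lam[:, 0].mean())
    assert len(ratios) >= 15
    assert 1.5 <= np.median(ratios) <= 2.7


def test_ltt_of_estimated_lifespans_tracks_truth(small_fossil_dataset):
    from palaeodiv.bd_engine import replicate_lifespans
    from palaeodiv.phylo_combine import ltt_range_through

    d = small_fossil_dataset
    settings = McmcSettings(n_iterations=200_000, sampling_freq=500, seed=9, n_replicates=1)
    _, tste = mcmc_bdcs_occurrences(d["occurrences"], d["grid"], d["grid"], settings)
    extant = {o.species_id for o in d["occurrences"] if o.status == "extant"}
    est = replicate_lifespans(tste, extant_ids=extant)[0]
    true_sampled = [
        l for l in d["lifespans"] if l.species_id in d["truth"]
    ]
    t_grid = np.linspace(0.0, d["origin"], 50)
    ltt_e = ltt_range_through(est, step=0.5)
    ltt_t = ltt_range_through(true_sampled, step=0.5)
    rho = stats.spearmanr(
        [ltt_e.at(t) for t in t_grid], [ltt_t.at(t) for t in t_grid]
    ).statistic
    assert rho > 0.9


# ---------------------------------------------------------------------------
# rates-through-time summary
# ---------------------------------------------------------------------------


def _fake_trace(lam_cols, mu_cols, grid):
    lam = np.column_stack(lam_cols)
    mu = np.column_stack(mu_cols)
    n = lam.shape[0]
    return BdTrace(
        species_ids=("x",), grid=grid, q_grid=None,
        lam=lam, mu=mu, q=np.zeros((n, 1)), alpha=np.zeros(n),
        ts=np.zeros((n, 1)), te=np.zeros((n, 1)),
        loglik=np.zeros(n), logprior=np.zeros(n),
        acceptance={}, burnin_fraction=0.0,
    )


def test_adjacent_bin_significance_rule():
    """Adjacent bins are significantly different only when each mean lies
    outside the other's HPD (both directions)."""
    rng = np.random.default_rng(0)
    grid = ShiftGrid((20.0, 10.0, 0.0))
    sep = _fake_trace(
        [rng.uniform(0.15, 0.25, 4000), rng.uniform(0.30, 0.50, 4000)],
        [rng.uniform(0.01, 0.02, 4000), rng.uniform(0.01, 0.02, 4000)],
        grid,
    )
    df = rtt_summary([sep])
    assert bool(df["lambda_sig_next"][0]) is True
    assert bool(df["mu_sig_next"][0]) is False  # identical distributions
    wide = _fake_trace(
        [rng.uniform(0.10, 0.45, 4000), rng.uniform(0.30, 0.50, 4000)],
        [rng.uniform(0.01, 0.02, 4000), rng.uniform(0.01, 0.02, 4000)],
        grid,
    )
    df = rtt_summary([wide])
    assert bool(df["lambda_sig_next"][0]) is False  # bin-2 mean inside bin-1 HPD


def test_net_rate_is_per_sample_difference():
    rng = np.random.default_rng(1)
    grid = ShiftGrid((10.0, 0.0))
    tr = _fake_trace([rng.gamma(2, 0.1, 1000)], [rng.gamma(2, 0.05, 1000)], grid)
    df = rtt_summary([tr])
    assert df["net_mean"][0] == pytest.approx(df["lambda_mean"][0] - df["mu_mean"][0], abs=1e-12)


def test_rtt_summary_requires_traces():
    with pytest.raises(ValueError):
        rtt_summary([])
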
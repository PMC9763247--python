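import numpy as np
import pytest

from palaeodiv.io_model import Lifespan, TraitRecord
from palaeodiv.traits import (
    SizeClassConfig,
    assign_size_classes,
    fit_family_regressions,
    impute_crown_heights,
    partition_lifespans,
)


def _family(n, family, slope, intercept, noise, rng):
    out = []
    for i in range(n):
        x = float(rng.uniform(30, 300))
        y = intercept + slope * x + (float(rng.normal(0, noise)) if noise else 0.0)
        out.append(TraitRecord(f"{family}_{i}", family, body_length=x, crown_height=max(y, 0.01)))
    return out


def test_exact_line_recovered_to_machine_precision():
    rng = np.random.default_rng(0)
    fits, unfitted = fit_family_regressions(_family(5, "Fam", 0.1, 1.0, 0.0, rng))
    assert unfitted == []
    f = fits["Fam"]
    assert f.slope == pytest.approx(0.1, abs=1e-12)
    assert f.intercept == pytest.approx(1.0, abs=1e-9)
    assert f.r_squared == pytest.approx(1.0, abs=1e-12)


def test_small_family_reported_unfitted():
    rng = np.random.default_rng(1)
    records = _family(2, "Tiny", 0.1, 1.0, 0.2, rng) + _family(5, "Big", 0.05, 2.0, 0.2, rng)
    fits, unfitted = fit_family_regressions(records)
    assert unfitted == ["Tiny"] and set(fits) == {"Big"}


def test_zero_length_variance_is_an_error():
    records = [
        TraitRecord(f"s{i}", "Flat", body_length=100.0, crown_height=float(5 + i))
        for i in range(4)
    ]
    with pytest.raises(ValueError, match="variance"):
        fit_family_regressions(records)


def test_ols_confidence_interval_covers_true_slope():
    """95% CI of the slope covers the generating slope in >= 90% of seeds."""
    from scipy import stats

    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        x = rng.uniform(30, 300, 30)
        y = 1.0 + 0.05 * x + rng.normal(0, 1.0, 30)
        fit = stats.linregress(x, y)
        half = 2.048 * fit.stderr  # t(28, 0.975)
        hits += int(fit.slope - half <= 0.05 <= fit.slope + half)
    assert hits >= 0.9 * n_seeds


def test_imputation_uses_family_equation_and_keeps_measured_values():
    rng = np.random.default_rng(2)
    measured = _family(5, "Fam", 0.1, 1.0, 0.0, rng)
    missing = TraitRecord("gap", "Fam", body_length=100.0)
    fits, _ = fit_family_regressions(measured)
    done = impute_crown_heights(measured + [missing], fits)
    by_id = {t.species_id: t for t in done}
    assert by_id["gap"].crown_height == pytest.approx(11.0)
    assert by_id["gap"].imputed
    for t in measured:
        assert by_id[t.species_id].crown_height == t.crown_height
        assert not by_id[t.species_id].imputed


def test_imputation_errors_list_problem_species():
    fits, _ = fit_family_regressions(
        _family(5, "Fam", 0.1, 1.0, 0.0, np.random.default_rng(3))
    )
    orphan = TraitRecord("lost", "Unknown", body_length=50.0)
    with pytest.raises(ValueError, match="lost"):
        impute_crown_heights([orphan], fits)


def test_extant_bookkeeping_at_study_scale():
    """284 extant species, 220 measured: the remaining 64 are imputed and
    the measured share is 77.46%."""
    rng = np.random.default_rng(4)
    records = []
    for i in range(284):
        x = float(rng.uniform(30, 300))
        if i < 220:
            records.append(
                TraitRecord(f"sp{i}", "Fam", body_length=x, crown_height=1.0 + 0.1 * x)
            )
        else:
            records.append(TraitRecord(f"sp{i}", "Fam", body_length=x))
    fits, _ = fit_family_regressions(records)
    done = impute_crown_heights(records, fits)
    assert sum(t.imputed for t in done) == 64
    assert round(100 * sum(not t.imputed for t in done) / 284, 2) == 77.46


def test_size_class_boundaries_are_half_open():
    cfg = SizeClassConfig(5.0, 12.0)
    records = [
        TraitRecord("a", "F", crown_height=4.9),
        TraitRecord("b", "F", crown_height=5.0),
        TraitRecord("c", "F", crown_height=12.0),
    ]
    assert assign_size_classes(records, cfg) == {"a": "small", "b": "medium", "c": "large"}
    tiny = [TraitRecord(f"t{i}", "F", crown_height=0.5) for i in range(3)]
    assert set(assign_size_classes(tiny, cfg).values()) == {"small"}
    with pytest.raises(ValueError, match="crown height"):
        assign_size_classes([TraitRecord("x", "F", body_length=10.0)], cfg)
    with pytest.raises(ValueError):
        SizeClassConfig(12.0, 5.0)


def test_partition_is_disjoint_exhaustive_and_reports_unclassified():
    lifespans = [Lifespan(f"s{i}", 10.0 - i, 0.0) for i in range(5)]
    classes = {"s0": "small", "s1": "medium", "s2": "large", "s3": "small"}
    parts, unclassified = partition_lifespans(lifespans, classes)
    assert unclassified == ["s4"]
    ids = [l.species_id for p in parts.values() for l in p]
    assert sorted(ids) == ["s0", "s1", "s2", "s3"]
    assert len(set(ids)) == len(ids)
    for cls, subset in parts.items():
        for l in subset:
            assert l.size_class == cls


def test_partitioned_sets_are_valid_engine_input():
    from palaeodiv.bd_engine import McmcSettings, mcmc_bdcs_lifespans
    from palaeodiv.io_model import ShiftGrid

    lifespans = [Lifespan(f"s{i}", 20.0 - i, 0.0) for i in range(9)]
    classes = {f"s{i}": ("small", "medium", "large")[i % 3] for i in range(9)}
    parts, _ = partition_lifespans(lifespans, classes)
    grid = ShiftGrid((20.0, 0.0))
    settings = McmcSettings(n_iterations=1_000, sampling_freq=100, n_replicates=1)
    for subset in parts.values():
        traces = mcmc_bdcs_lifespans(subset, grid, settings)
        assert len(traces) == 1
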
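import numpy as np
import pytest

from palaeodiv.bd_engine import PreservationModel, RateProfile
from palaeodiv.io_model import Lifespan, ShiftGrid
from palaeodiv.synthetic_data import (
    SimScenario,
    discretize_occurrence_ages,
    simulate_bd_process,
    simulate_preservation,
)


@pytest.fixture(scope="session")
def small_fossil_dataset():
    """One constant-rate simulated clade with binned occurrences and truth,
    shared by the sampler tests (session-scoped: simulated once)."""
    origin = 40.0
    grid = ShiftGrid((origin, 0.0))
    rates = RateProfile(grid, np.array([0.2]), np.array([0.1]))
    pres = PreservationModel(grid, np.array([1.0]), alpha=None)
    edges = np.linspace(0.0, origin, 41)
    bins = tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))
    for k in range(200):
        sc = SimScenario(origin, rates, pres, bins, seed=(42, k))
        lifespans, parent = simulate_bd_process(sc)
        ages = simulate_preservation(lifespans, pres, seed=(42, k, 7))
        if 80 <= len(ages) <= 200:
            statuses = {
                l.species_id: ("extant" if l.extant else "extinct") for l in lifespans
            }
            occurrences = discretize_occurrence_ages(ages, bins, statuses)
            truth = {l.species_id: (l.ts, l.te) for l in lifespans if l.species_id in ages}
            return {
                "origin": origin,
                "grid": grid,
                "occurrences": occurrences,
                "truth": truth,
                "lifespans": lifespans,
                "parent": parent,
                "ages": ages,
                "n_extant": sum(1 for l in lifespans if l.extant),
            }
    raise RuntimeError("no suitable clade found")


@pytest.fixture()
def toy_lifespans():
    return [
        Lifespan("A", ts=10.0, te=0.0),
        Lifespan("B", ts=7.0, te=2.0),
        Lifespan("C", ts=5.0, te=0.0),
        Lifespan("D", ts=4.0, te=1.0),
    ]
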
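"""Shared fixtures: session-scoped sampled ensembles so the expensive
sampling runs happen once and are reused across test modules."""

import numpy as np
import pytest

from mcdock.engine import SamplingSchedule, learn_bias, run_mcmd
from mcdock.synthetic import (
    TraceSpec,
    default_planted_spec,
    generate_binding_trace,
    generate_planted_ensemble,
)
from mcdock.systems import make_double_well, make_gated_pocket, make_harmonic


@pytest.fixture(scope="session")
def harmonic_system():
    return make_harmonic()


@pytest.fixture(scope="session")
def harmonic_mcmd(harmonic_system):
    """Learned bias + multicanonical production for the 1D harmonic well.

    Ten trajectories of 10^6 steps each: trajectory means give an honest
    standard error for the reweighted averages.
    """
    schedule = SamplingSchedule(
        n_trajectories=10,
        prerun_steps=200_000,
        production_steps=1_000_000,
        bias_update_iterations=8,
        snapshot_stride=100,
        seed=11,
    )
    bias = learn_bias(harmonic_system, schedule)
    ensemble = run_mcmd(harmonic_system, bias, schedule)
    return harmonic_system, bias, ensemble, schedule


@pytest.fixture(scope="session")
def double_well_system():
    # the tilt makes the two well populations unequal, so free-energy
    # recovery against quadrature is a non-trivial check
    return make_double_well(barrier=3.0, well_sep=2.0, tilt=0.4)


@pytest.fixture(scope="session")
def double_well_mcmd(double_well_system):
    schedule = SamplingSchedule(
        n_trajectories=6,
        prerun_steps=200_000,
        production_steps=1_000_000,
        bias_update_iterations=8,
        snapshot_stride=50,
        seed=23,
    )
    bias = learn_bias(double_well_system, schedule)
    ensemble = run_mcmd(double_well_system, bias, schedule)
    return double_well_system, bias, ensemble, schedule


@pytest.fixture(scope="session")
def gated_system():
    return make_gated_pocket()


@pytest.fixture(scope="session")
def gated_mcmd(gated_system):
    schedule = SamplingSchedule(
        n_trajectories=4,
        prerun_steps=150_000,
        production_steps=400_000,
        bias_update_iterations=10,
        snapshot_stride=50,
        seed=37,
        step_width=0.35,
    )
    bias = learn_bias(gated_system, schedule)
    ensemble = run_mcmd(gated_system, bias, schedule)
    return gated_system, bias, ensemble, schedule


@pytest.fixture(scope="session")
def planted_large():
    return generate_planted_ensemble(default_planted_spec(n_snapshots=100_000, seed=5))


@pytest.fixture(scope="session")
def planted_small():
    return generate_planted_ensemble(default_planted_spec(n_snapshots=20_000, seed=7))


@pytest.fixture(scope="session")
def binding_trace():
    return generate_binding_trace(TraceSpec(seed=13))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
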
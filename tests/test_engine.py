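"""Sampler contracts: determinism, detailed balance, equipartition,
multicanonical limits, bias learning and restraint effects."""

import numpy as np
import pytest
from scipy import stats

from mcdock.constants import KB
from mcdock.engine import (
    BiasFunction,
    SamplingSchedule,
    Snapshot,
    check_snapshot_energy,
    energies_array,
    learn_bias,
    run_canonical,
    run_mcmd,
)
from mcdock.errors import InputError, IntegrationError
from mcdock.reweighting import flatness_ratio
from mcdock.systems import Restraint, make_double_well, make_gated_pocket, make_harmonic
from mcdock.utils import blocked_standard_error, count_round_trips

from helpers_oracles import double_well_quadrature


def _sched(**kw):
    base = dict(
        n_trajectories=1,
        prerun_steps=1,
        production_steps=50_000,
        bias_update_iterations=1,
        snapshot_stride=25,
        seed=3,
    )
    base.update(kw)
    return SamplingSchedule(**base)


def test_same_seed_bit_identical():
    sys_ = make_harmonic()
    sched = _sched()
    a = run_canonical(sys_, 300.0, sched)
    b = run_canonical(sys_, 300.0, sched)
    assert np.array_equal(energies_array(a), energies_array(b))
    assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))


def test_zero_bias_mcmd_equals_canonical():
    """With b ≡ 0 and T_ref = T the multicanonical sampler IS the canonical one."""
    sys_ = make_harmonic()
    sched = _sched()
    bias = BiasFunction.zero(T_ref=300.0, T_low=300.0, T_high=700.0)
    # the zero bias has zero tail slopes only when T_low == T_ref; force them
    bias = BiasFunction(bias.energy_knots, bias.bias_values,
                        T_low=300.0, T_high=300.0 + 1e-9, T_ref=300.0)
    a = run_mcmd(sys_, bias, sched)
    b = run_canonical(sys_, 300.0, sched)
    assert np.array_equal(energies_array(a), energies_array(b))


def test_canonical_equipartition_harmonic():
    """⟨E⟩ of the 1D harmonic at 300 K is ½kB·300 = 0.298 kcal/mol."""
    sys_ = make_harmonic()
    ens = run_canonical(sys_, 300.0, _sched(production_steps=400_000, seed=5))
    e = energies_array(ens)
    se = blocked_standard_error(e)
    assert abs(e.mean() - 0.5 * KB * 300.0) < 3.0 * se


def test_temperature_must_be_positive():
    with pytest.raises(InputError):
        run_canonical(make_harmonic(), 0.0, _sched())


def test_detailed_balance_position_marginal():
    """Metropolis at 300 K reproduces the Boltzmann position marginal
    (KS distance against the exact Gaussian shrinks with thinning)."""
    sys_ = make_harmonic(k=1.0)
    ens = run_canonical(sys_, 300.0, _sched(production_steps=400_000,
                                            snapshot_stride=200, seed=8))
    x = np.array([s.coords[0, 0] for s in ens])
    sigma = np.sqrt(KB * 300.0 / 1.0)
    ks = stats.kstest(x, stats.norm(scale=sigma).cdf)
    assert ks.statistic < 0.05


def test_double_well_canonical_occupancy_matches_quadrature():
    sys_ = make_double_well(barrier=3.0, well_sep=2.0, tilt=0.4)
    sched = _sched(n_trajectories=6, production_steps=300_000,
                   snapshot_stride=50, seed=17)
    ens = run_canonical(sys_, 300.0, sched)
    p_left_q, _, _ = double_well_quadrature(3.0, 2.0, 0.4, 300.0)
    per_traj = []
    for tid in range(6):
        x = np.array([s.coords[0, 0] for s in ens if s.traj_id == tid])
        per_traj.append(np.mean(x < 0))
    per_traj = np.asarray(per_traj)
    se = per_traj.std(ddof=1) / np.sqrt(per_traj.size)
    assert abs(per_traj.mean() - p_left_q) < 3.0 * max(se, 1e-3)


def test_snapshot_energy_matches_fresh_evaluation(gated_mcmd):
    system, _, ensemble, _ = gated_mcmd
    for snap in ensemble[:: max(1, len(ensemble) // 50)]:
        assert check_snapshot_energy(system, snap, tol=1e-6)


def test_restraint_lowers_distance_variance():
    base = make_harmonic(k=0.5, n_particles=2, dim=3)
    tied = make_harmonic(k=0.5, n_particles=2, dim=3)
    tied.restraints = [Restraint(0, 1, target=2.0, k=10.0)]
    sched = _sched(production_steps=200_000, seed=21)
    var = {}
    for name, sys_ in (("free", base), ("restrained", tied)):
        ens = run_canonical(sys_, 300.0, sched)
        d = np.array([np.linalg.norm(s.coords[0] - s.coords[1]) for s in ens])
        var[name] = d.var()
    assert var["restrained"] < var["free"]


def test_langevin_equipartition():
    sys_ = make_harmonic(k=1.0, n_particles=1, dim=3)
    sched = _sched(production_steps=100_000, integrator="langevin",
                   timestep=0.005, friction=2.0, seed=9)
    ens = run_canonical(sys_, 300.0, sched)
    e = energies_array(ens)
    # BAOAB has O(dt²) configurational bias; 10% is ample at this dt
    assert e[200:].mean() == pytest.approx(1.5 * KB * 300.0, rel=0.10)


def test_langevin_divergence_raises_integration_error():
    sys_ = make_harmonic(k=100.0)
    sched = _sched(production_steps=10_000, integrator="langevin",
                   timestep=5.0, friction=0.01)
    with pytest.raises(IntegrationError):
        run_canonical(sys_, 300.0, sched)


# ---------------------------------------------------------------------------
# Bias learning
# ---------------------------------------------------------------------------


def test_learn_bias_requires_iterations():
    sched = _sched()
    sched.bias_update_iterations = 0
    with pytest.raises(InputError):
        learn_bias(make_harmonic(), sched)


def test_learned_bias_flattens_harmonic(harmonic_mcmd):
    _, bias, ensemble, _ = harmonic_mcmd
    assert flatness_ratio(ensemble, bias, n_bins=20) >= 0.5


def test_mcmd_energy_span_covers_canonical_means(harmonic_mcmd):
    _, _, ensemble, _ = harmonic_mcmd
    e = energies_array(ensemble)
    assert e.min() < 0.5 * KB * 300.0
    assert e.max() > 0.5 * KB * 700.0


def test_double_well_round_trips(double_well_mcmd):
    system, _, ensemble, schedule = double_well_mcmd
    w = system.params["well_sep"]
    for tid in range(schedule.n_trajectories):
        x = np.array([s.coords[0, 0] for s in ensemble if s.traj_id == tid])
        assert count_round_trips(x, -0.5 * w, 0.5 * w) >= 5


def test_gated_pocket_samples_both_gate_states(gated_mcmd):
    _, _, ensemble, _ = gated_mcmd
    gate_d = np.array([np.linalg.norm(s.coords[1] - s.coords[2]) for s in ensemble])
    assert np.mean(gate_d > 5.5) > 0.005  # open
    assert np.mean(gate_d < 4.0) > 0.10  # closed


def test_mcmd_requires_bias():
    with pytest.raises(InputError):
        run_mcmd(make_harmonic(), None, _sched())


# ---------------------------------------------------------------------------
# BiasFunction contract
# ---------------------------------------------------------------------------


def test_bias_knots_must_increase():
    with pytest.raises(InputError):
        BiasFunction(np.array([0.0, 0.0, 1.0]), np.zeros(3))


def test_bias_tails_have_canonical_slopes():
    bias = BiasFunction(np.array([0.0, 10.0]), np.array([0.0, 0.0]),
                        T_low=300.0, T_high=700.0, T_ref=300.0)
    assert bias.slope_low == pytest.approx(0.0)
    assert bias.slope_high == pytest.approx(300.0 / 700.0 - 1.0)
    # value continuity + slope below/above the knots
    assert bias(-2.0) == pytest.approx(bias.slope_low * -2.0)
    assert bias(12.0) == pytest.approx(bias.slope_high * 2.0)


@pytest.mark.parametrize("interpolation", ["linear", "cubic"])
def test_bias_interpolation_passes_through_knots(interpolation):
    knots = np.linspace(0.0, 5.0, 11)
    vals = np.sin(knots)
    bias = BiasFunction(knots, vals, interpolation=interpolation)
    assert bias(knots) == pytest.approx(vals, abs=1e-12)


def test_bias_python_eval_matches_kernel(rng):
    from mcdock._kernels import bias_value

    knots = np.linspace(-2.0, 8.0, 41)
    vals = 0.3 * knots**2 - knots
    bias = BiasFunction(knots, vals, interpolation="cubic")
    k, c, v0, v1, slo, shi = bias.tables()
    for e in rng.uniform(-4.0, 12.0, size=50):
        assert bias(float(e)) == pytest.approx(
            bias_value(float(e), k, c, v0, v1, slo, shi), abs=1e-10
        )


def test_schedule_validates_counts():
    with pytest.raises(InputError):
        SamplingSchedule(n_trajectories=0)
    with pytest.raises(InputError):
        SamplingSchedule(integrator="verlet")
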
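"""Multicanonical and canonical sampling on toy systems.

The multicanonical scheme samples the biased density

    ρ_mc(x) ∝ exp(−[E(x) + b(E(x))] / kB·T_ref)

where the energy-dependent bias b(E) is learned iteratively so that the
potential-energy histogram is approximately flat across the canonical mean
energies of a target temperature range (by default 300–700 K).  A flat
energy histogram lets the walker cross barriers at will; canonical
ensembles at any temperature inside the flattened range are recovered
afterwards by reweighting (:mod:`mcdock.reweighting`).

Bias learning is the classic flat-histogram iteration: run with the current
bias, histogram the visited energies, add kB·T_ref·ln ĥ(E) (smoothed; empty
bins inherit their nearest visited neighbour) and repeat.  The initial bias
is the linear ramp that makes sampling at T_ref equivalent to canonical
sampling at T_high, so the first iteration already visits the top of the
target range and subsequent iterations flatten downward.  Outside the knot
range the bias continues with the canonical-tail slopes T_ref/T_low − 1
(below) and T_ref/T_high − 1 (above), which bound the sampled energies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from . import _kernels
from .constants import KB, KCAL_PER_MOL_IN_AMU_A2_PS2
from .errors import ConvergenceError, InputError, IntegrationError
from .systems import ToySystem, potential_energy

logger = logging.getLogger(__name__)

_SEED_MASK = 0x7FFFFFFF
#: Energy (kcal/mol) above which a run is declared divergent.
ENERGY_BLOWUP = 1.0e6


@dataclass
class Snapshot:
    """One sampled configuration."""

    coords: np.ndarray  # (n_particles, dim), Å
    energy: float  # kcal/mol
    traj_id: int = 0
    step: int = 0

    def copy(self) -> "Snapshot":
        return Snapshot(self.coords.copy(), self.energy, self.traj_id, self.step)


@dataclass
class BiasFunction:
    """Tabulated multicanonical bias b(E) over an energy-knot grid.

    ``interpolation`` is ``linear`` (default; also what the samplers use)
    or ``cubic`` (natural cubic spline through the knots).  Outside the
    knot range the bias continues linearly with the canonical-tail slopes.
    """

    energy_knots: np.ndarray  # kcal/mol, strictly increasing
    bias_values: np.ndarray  # kcal/mol
    T_low: float = 300.0
    T_high: float = 700.0
    T_ref: float = 300.0
    interpolation: str = "linear"

    def __post_init__(self):
        self.energy_knots = np.asarray(self.energy_knots, dtype=float)
        self.bias_values = np.asarray(self.bias_values, dtype=float)
        if self.energy_knots.ndim != 1 or self.energy_knots.size < 2:
            raise InputError("bias needs at least two energy knots")
        if np.any(np.diff(self.energy_knots) <= 0):
            raise InputError("energy knots must be strictly increasing")
        if self.bias_values.shape != self.energy_knots.shape:
            raise InputError("bias values must match the knot grid")
        if not np.all(np.isfinite(self.bias_values)):
            raise InputError("bias must be finite at all knots")
        if self.interpolation not in ("linear", "cubic"):
            raise InputError("interpolation must be 'linear' or 'cubic'")
        if self.T_low <= 0 or self.T_high <= self.T_low:
            raise InputError("need 0 < T_low < T_high")

    # canonical-tail extrapolation slopes
    @property
    def slope_low(self) -> float:
        return self.T_ref / self.T_low - 1.0

    @property
    def slope_high(self) -> float:
        return self.T_ref / self.T_high - 1.0

    def tables(self):
        """(knots, coeffs, v_first, v_last, slope_lo, slope_hi) for kernels."""
        knots = self.energy_knots
        vals = self.bias_values
        if self.interpolation == "linear":
            coeffs = np.zeros((knots.size - 1, 4))
            coeffs[:, 0] = vals[:-1]
            coeffs[:, 1] = np.diff(vals) / np.diff(knots)
        else:
            cs = CubicSpline(knots, vals, bc_type="natural")
            coeffs = cs.c[::-1].T.copy()  # ascending powers, (m-1, 4)
        return (
            knots,
            coeffs,
            float(vals[0]),
            float(vals[-1]),
            self.slope_low,
            self.slope_high,
        )

    def __call__(self, energy):
        """Evaluate b(E); accepts scalars or arrays."""
        knots, coeffs, v0, v1, slo, shi = self.tables()
        e = np.atleast_1d(np.asarray(energy, dtype=float))
        out = np.empty_like(e)
        below = e <= knots[0]
        above = e >= knots[-1]
        inside = ~(below | above)
        out[below] = v0 + slo * (e[below] - knots[0])
        out[above] = v1 + shi * (e[above] - knots[-1])
        if np.any(inside):
            j = np.clip(np.searchsorted(knots, e[inside]) - 1, 0, knots.size - 2)
            t = e[inside] - knots[j]
            c = coeffs[j]
            out[inside] = ((c[:, 3] * t + c[:, 2]) * t + c[:, 1]) * t + c[:, 0]
        if np.isscalar(energy) or np.asarray(energy).ndim == 0:
            return float(out[0])
        return out

    @classmethod
    def zero(cls, e_min=-10.0, e_max=10.0, T_ref=300.0, T_low=300.0, T_high=700.0):
        """The trivial b ≡ 0 bias (sampling reduces to canonical at T_ref)."""
        return cls(
            np.array([e_min, e_max]),
            np.zeros(2),
            T_low=T_low,
            T_high=T_high,
            T_ref=T_ref,
        )


@dataclass
class SamplingSchedule:
    """Run-length and reproducibility parameters for the samplers.

    The defaults mirror, at desk scale, a 30-trajectory protocol with an
    iterated prerun (bias learning) followed by a long production run.
    """

    n_trajectories: int = 30
    prerun_steps: int = 200_000
    production_steps: int = 1_000_000
    bias_update_iterations: int = 8
    snapshot_stride: int = 100
    seed: int = 0
    integrator: str = "metropolis"  # or "langevin"
    step_width: float = 0.5  # Å, Metropolis proposal width
    timestep: float = 0.01  # ps, Langevin
    friction: float = 1.0  # 1/ps, Langevin

    def __post_init__(self):
        for name in (
            "n_trajectories",
            "prerun_steps",
            "production_steps",
            "snapshot_stride",
        ):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")
        if self.integrator not in ("metropolis", "langevin"):
            raise InputError("integrator must be 'metropolis' or 'langevin'")

    def with_(self, **kw) -> "SamplingSchedule":
        return replace(self, **kw)


def _trivial_bias_tables():
    knots = np.array([0.0, 1.0])
    coeffs = np.zeros((1, 4))
    return knots, coeffs, 0.0, 0.0, 0.0, 0.0


def _run_single(
    system: ToySystem,
    bias: BiasFunction | None,
    T: float,
    n_steps: int,
    stride: int,
    seed: int,
    start_coords: np.ndarray,
    use_restraints: bool,
    integrator: str = "metropolis",
    step_width: float = 0.5,
    timestep: float = 0.01,
    friction: float = 1.0,
    traj_id: int = 0,
):
    pp = system.packed_params()
    rest_ij, rest_par = system.packed_restraints()
    if bias is not None:
        knots, coeffs, v0, v1, slo, shi = bias.tables()
        use_bias = True
        beta = 1.0 / (KB * bias.T_ref)
    else:
        knots, coeffs, v0, v1, slo, shi = _trivial_bias_tables()
        use_bias = False
        beta = 1.0 / (KB * T)
    args = (
        np.ascontiguousarray(start_coords, dtype=np.float64),
        system.pot_id_int,
        pp,
        system.site_positions,
        system.site_depths,
        system.site_sigmas,
        system.tether_ref,
        system.tether_k,
        rest_ij,
        rest_par,
        use_restraints,
        knots,
        coeffs,
        v0,
        v1,
        slo,
        shi,
        use_bias,
    )
    if integrator == "metropolis":
        out_c, out_e, k_out, n_acc, flag = _kernels.mc_run(
            *args, beta, step_width, n_steps, stride, seed, ENERGY_BLOWUP
        )
    else:
        kbt = 1.0 / beta
        out_c, out_e, k_out, n_acc, flag = _kernels.langevin_run(
            *args,
            system.masses,
            kbt,
            timestep,
            friction,
            KCAL_PER_MOL_IN_AMU_A2_PS2,
            n_steps,
            stride,
            seed,
            ENERGY_BLOWUP,
        )
    if flag:
        raise IntegrationError(
            f"trajectory {traj_id} diverged (energy > {ENERGY_BLOWUP:g} kcal/mol "
            f"after recording {k_out} frames)"
        )
    snaps = [
        Snapshot(out_c[j].copy(), float(out_e[j]), traj_id, stride * (j + 1))
        for j in range(k_out)
    ]
    return snaps, n_acc / n_steps


def run_mcmd(
    system: ToySystem,
    bias: BiasFunction,
    schedule: SamplingSchedule,
    start: Snapshot | None = None,
    restraints_on: bool = True,
) -> list:
    """Multicanonical production sampling; one list of snapshots over all
    trajectories (trajectory i is seeded with ``schedule.seed + i``)."""
    if bias is None:
        raise InputError("run_mcmd requires a learned BiasFunction")
    start_coords = (
        start.coords if start is not None else system.reference_coords
    )
    out = []
    for i in range(schedule.n_trajectories):
        snaps, acc = _run_single(
            system,
            bias,
            bias.T_ref,
            schedule.production_steps,
            schedule.snapshot_stride,
            (schedule.seed + i) & _SEED_MASK,
            start_coords,
            restraints_on,
            schedule.integrator,
            schedule.step_width,
            schedule.timestep,
            schedule.friction,
            traj_id=i,
        )
        logger.info("mcmd traj %d: %d frames, acceptance %.3f", i, len(snaps), acc)
        out.extend(snaps)
    return out


def run_canonical(
    system: ToySystem,
    T: float,
    schedule: SamplingSchedule,
    start: Snapshot | None = None,
    restraints_on: bool = True,
) -> list:
    """Unbiased Boltzmann sampling at temperature ``T``."""
    if T <= 0:
        raise InputError("temperature must be positive")
    start_coords = (
        start.coords if start is not None else system.reference_coords
    )
    out = []
    for i in range(schedule.n_trajectories):
        snaps, acc = _run_single(
            system,
            None,
            T,
            schedule.production_steps,
            schedule.snapshot_stride,
            (schedule.seed + i) & _SEED_MASK,
            start_coords,
            restraints_on,
            schedule.integrator,
            schedule.step_width,
            schedule.timestep,
            schedule.friction,
            traj_id=i,
        )
        logger.info(
            "canonical traj %d at %g K: %d frames, acceptance %.3f",
            i, T, len(snaps), acc,
        )
        out.extend(snaps)
    return out


# ---------------------------------------------------------------------------
# Bias learning
# ---------------------------------------------------------------------------


def _probe_energy_range(system, schedule, T_pad_low, T_pad_high, restraints_on):
    """Short canonical probes bracketing the knot range."""
    n = min(schedule.prerun_steps, 50_000)
    sched = schedule.with_(n_trajectories=1)
    lo_snaps, _ = _run_single(
        system, None, T_pad_low, n, max(1, n // 2000),
        (schedule.seed + 90001) & _SEED_MASK,
        system.reference_coords, restraints_on,
        sched.integrator, sched.step_width, sched.timestep, sched.friction,
    )
    hi_snaps, _ = _run_single(
        system, None, T_pad_high, n, max(1, n // 2000),
        (schedule.seed + 90002) & _SEED_MASK,
        system.reference_coords, restraints_on,
        sched.integrator, sched.step_width, sched.timestep, sched.friction,
    )
    e_lo = np.array([s.energy for s in lo_snaps])
    e_hi = np.array([s.energy for s in hi_snaps])
    e_min = float(e_lo.min() - 2.0 * max(e_lo.std(), 0.05) - 0.05)
    # the canonical tail above the last knot handles E > e_max, so the
    # flattened range only needs to reach slightly past the T_high mean
    e_max = float(e_hi[e_hi.size // 2 :].mean() + 3.0 * max(e_hi.std(), 0.05))
    return e_min, e_max


def learn_bias(
    system: ToySystem,
    schedule: SamplingSchedule,
    T_low: float = 300.0,
    T_high: float = 700.0,
    T_ref: float = 300.0,
    n_knots: int = 201,
    smooth_sigma_bins: float = 1.0,
    restraints_on: bool = True,
    knot_pad_low: float = 280.0,
    knot_pad_high: float = 750.0,
) -> BiasFunction:
    """Iterative flat-histogram bias learning.

    Runs ``schedule.bias_update_iterations`` prerun legs of
    ``schedule.prerun_steps`` Metropolis steps each, updating

        b(E) ← b(E) + kB·T_ref · ln ĥ(E)

    on the visited knot bins (Gaussian-smoothed over ``smooth_sigma_bins``
    bins; unvisited bins inherit the value of their nearest visited
    neighbour).  The energy-knot grid spans the canonical ranges probed at
    ``knot_pad_low``/``knot_pad_high`` K.  Raises
    :class:`~mcdock.errors.ConvergenceError` when two consecutive
    iterations visit disjoint energy ranges.
    """
    if schedule.bias_update_iterations < 1:
        raise InputError("bias_update_iterations must be >= 1")
    e_min, e_max = _probe_energy_range(
        system, schedule, knot_pad_low, knot_pad_high, restraints_on
    )
    knots = np.linspace(e_min, e_max, n_knots)
    # start from the ramp equivalent to canonical sampling at T_high
    b = (T_ref / T_high - 1.0) * (knots - knots[-1])
    b -= b.min()

    dk = knots[1] - knots[0]
    edges = np.concatenate([[knots[0] - dk / 2], knots + dk / 2])
    prev_occupied = None
    for it in range(schedule.bias_update_iterations):
        bias = BiasFunction(knots, b, T_low=T_low, T_high=T_high, T_ref=T_ref)
        # every iteration restarts from the reference configuration so the
        # low-energy end of the range is revisited and corrected; without
        # this the walker lingers at high E (huge configurational entropy)
        # and the bias below the visited range keeps its initial ramp,
        # trapping production runs started from a bound pose.
        snaps, acc = _run_single(
            system,
            bias,
            T_ref,
            schedule.prerun_steps,
            max(1, schedule.snapshot_stride // 10),
            (schedule.seed + 100_003 * (it + 1)) & _SEED_MASK,
            system.reference_coords,
            restraints_on,
            "metropolis",
            schedule.step_width,
            traj_id=it,
        )
        energies = np.array([s.energy for s in snaps])
        h, _ = np.histogram(energies, bins=edges)
        occupied = h > 0
        if prev_occupied is not None and not np.any(occupied & prev_occupied):
            raise ConvergenceError(
                "energy histograms of consecutive bias iterations do not overlap",
                diagnostics={
                    "iteration": it,
                    "previous_range": _occupied_range(knots, prev_occupied),
                    "current_range": _occupied_range(knots, occupied),
                },
            )
        prev_occupied = occupied
        lnh = np.zeros_like(b)
        lnh[occupied] = np.log(h[occupied] / h[occupied].max())
        # unvisited bins inherit the nearest visited value
        idx = np.arange(knots.size)
        lnh = np.interp(idx, idx[occupied], lnh[occupied])
        lnh = gaussian_filter1d(lnh, sigma=smooth_sigma_bins, mode="nearest")
        b = b + KB * T_ref * lnh
        b -= b.min()
        logger.info(
            "bias iteration %d: %d/%d bins occupied, acceptance %.3f",
            it, int(occupied.sum()), occupied.size, acc,
        )
    return BiasFunction(knots, b, T_low=T_low, T_high=T_high, T_ref=T_ref)


def _occupied_range(knots, mask):
    if not np.any(mask):
        return (float("nan"), float("nan"))
    k = knots[mask]
    return (float(k.min()), float(k.max()))


def check_snapshot_energy(system: ToySystem, snapshot: Snapshot, tol=1e-6,
                          include_restraints: bool = True) -> bool:
    """Engine contract: a recorded energy matches a fresh evaluation."""
    e = potential_energy(system, snapshot.coords, include_restraints)
    return abs(e - snapshot.energy) <= tol


def energies_array(ensemble) -> np.ndarray:
    return np.array([s.energy for s in ensemble])


def coords_stack(ensemble) -> np.ndarray:
    return np.stack([s.coords for s in ensemble])
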
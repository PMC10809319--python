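"""Synthetic ensembles with known ground truth.

Three generators cover every input the analysis pipeline consumes:

* :func:`generate_planted_ensemble` — snapshots drawn from Gaussian
  binding-configuration clusters with chosen populations (many shallow
  surface poses, a gateway pose, one buried pocket pose), the oracle for
  FEL construction, basin clustering and CFE ranking;
* :func:`generate_bias_consistent_energies` — potential energies drawn
  from an analytic density of states under a given bias, the oracle for
  canonical reweighting;
* :func:`generate_binding_trace` — a continuous unbinding trace threading
  an opening-then-closing gate, plus decoy snapshots guaranteed to be far
  from the trace, the oracle for path extraction.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .engine import BiasFunction, Snapshot
from .errors import InputError, SpecError
from .systems import make_gated_pocket

# ---------------------------------------------------------------------------
# Planted clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSpec:
    centroid: tuple  # ligand position, Å
    spread: float  # isotropic Gaussian σ, Å
    population: float  # fraction
    label: str = "surface"  # {surface, gate, pocket}


@dataclass
class PlantedSpec:
    clusters: list
    n_snapshots: int = 100_000
    seed: int = 0
    gate_open_p: float = 0.25
    d_open: float = 8.0
    d_closed: float = 3.0

    def __post_init__(self):
        pops = np.array([c.population for c in self.clusters])
        if abs(pops.sum() - 1.0) > 1e-9:
            raise InputError("cluster populations must sum to 1")
        if any(c.spread <= 0 for c in self.clusters):
            raise InputError("cluster spreads must be positive")
        if self.d_open <= self.d_closed:
            raise InputError("gate open distance must exceed closed distance")


def default_planted_spec(n_snapshots=100_000, seed=0) -> PlantedSpec:
    """Three well-separated clusters with populations 0.5/0.3/0.2.

    Two surface poses and one buried pocket pose — the qualitative layout
    of a docking landscape where most density sits on the receptor surface
    and the native pose is buried.
    """
    return PlantedSpec(
        clusters=[
            ClusterSpec((0.0, 7.0, 0.0), 0.8, 0.5, "surface"),
            ClusterSpec((0.0, 0.0, 7.0), 0.8, 0.3, "surface"),
            ClusterSpec((0.0, 0.0, 0.0), 0.8, 0.2, "pocket"),
        ],
        n_snapshots=n_snapshots,
        seed=seed,
    )


@dataclass
class PlantedEnsemble:
    snapshots: list
    labels: np.ndarray  # planted cluster index per snapshot
    weights: np.ndarray  # uniform (populations enter as multiplicity)
    cluster_labels: tuple  # pose label per cluster
    roles: dict
    spec: PlantedSpec


def generate_planted_ensemble(spec: PlantedSpec) -> PlantedEnsemble:
    """Draw snapshots from the planted clusters on a gated-pocket scaffold.

    The receptor/gate beads come from the reference gated-pocket geometry;
    each snapshot places the single-bead ligand at its cluster's centroid
    plus isotropic Gaussian noise.  Gate dynamics are coupled to binding:
    when the snapshot's cluster is the ``pocket`` pose the gate is closed
    (holo), otherwise it is open with probability ``gate_open_p`` — so a
    bound ligand quenches the gate fluctuations, as in a conformational-
    selection mechanism.
    """
    rng = np.random.default_rng(spec.seed)
    base_sys = make_gated_pocket(d_open=spec.d_open, d_closed=spec.d_closed)
    base = base_sys.reference_coords
    k = len(spec.clusters)
    pops = np.array([c.population for c in spec.clusters])
    labels = rng.choice(k, size=spec.n_snapshots, p=pops)
    gate_noise = 0.05
    snaps = []
    for i in range(spec.n_snapshots):
        c = spec.clusters[labels[i]]
        coords = base.copy()
        coords[0] = np.asarray(c.centroid) + c.spread * rng.standard_normal(3)
        if c.label == "pocket":
            d = spec.d_closed
        else:
            d = spec.d_open if rng.random() < spec.gate_open_p else spec.d_closed
        coords[1] = (3.0, d / 2.0, 0.0)
        coords[2] = (3.0, -d / 2.0, 0.0)
        coords[1:3] += gate_noise * rng.standard_normal((2, 3))
        snaps.append(Snapshot(coords, 0.0, traj_id=0, step=i))
    weights = np.full(spec.n_snapshots, 1.0 / spec.n_snapshots)
    return PlantedEnsemble(
        snapshots=snaps,
        labels=labels,
        weights=weights,
        cluster_labels=tuple(c.label for c in spec.clusters),
        roles={key: v.copy() for key, v in base_sys.roles.items()},
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Bias-consistent energy samples
# ---------------------------------------------------------------------------


def exact_flattening_bias(
    alpha: float, e_min: float, e_max: float, T_ref: float = 300.0,
    n_knots: int = 201, T_low: float = 300.0, T_high: float = 700.0,
) -> BiasFunction:
    """The bias that exactly flattens a power-law density of states.

    For n(E) ∝ E^α the sampled density n(E)·exp(−[E+b]/kB·T_ref) is uniform
    when b(E) = kB·T_ref·α·ln E − E (+ constant).
    """
    if e_min <= 0:
        raise InputError("power-law density of states needs e_min > 0")
    knots = np.linspace(e_min, e_max, n_knots)
    b = KB * T_ref * alpha * np.log(knots) - knots
    b -= b.min()
    return BiasFunction(knots, b, T_low=T_low, T_high=T_high, T_ref=T_ref)


def generate_bias_consistent_energies(
    alpha: float,
    bias: BiasFunction | None,
    T_ref: float,
    n: int,
    seed: int = 0,
    e_max: float | None = None,
    grid_points: int = 20_000,
) -> np.ndarray:
    """Energies drawn from ∝ E^α · exp(−[E + b(E)]/kB·T_ref).

    ``alpha`` is the density-of-states exponent (α = f/2 − 1 for an
    f-dimensional harmonic system); with the exact flattening bias the
    sample is uniform in E over the knot range.  Inverse-CDF sampling on a
    dense grid; pure function of (inputs, seed).
    """
    if alpha <= -1:
        raise InputError("density-of-states exponent must exceed -1")
    if n < 0:
        raise InputError("sample size must be non-negative")
    if n == 0:
        return np.empty(0)
    if e_max is None:
        if bias is not None:
            e_max = float(bias.energy_knots[-1])
        else:
            e_max = 20.0 * KB * T_ref * (alpha + 1.0)
    e_lo = 1e-9 if bias is None else max(1e-9, float(bias.energy_knots[0]))
    grid = np.linspace(e_lo, e_max, grid_points)
    logp = alpha * np.log(grid) - grid / (KB * T_ref)
    if bias is not None:
        logp -= bias(grid) / (KB * bias.T_ref)
    logp -= logp.max()
    p = np.exp(logp)
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    return np.interp(rng.random(n), cdf, grid)


# ---------------------------------------------------------------------------
# Binding trace + decoys
# ---------------------------------------------------------------------------


@dataclass
class TraceSpec:
    lambda_start: float = 14.0
    lambda_end: float = 0.0
    step: float = 0.5  # Å along the dissociation ray
    d_holo: float = 2.8  # gate separation in the bound state
    d_apo: float = 3.2  # resting (apo) gate separation
    d_open: float = 8.0  # maximal gate opening mid-path
    gate_peak_lambda: float = 4.5
    gate_peak_sigma: float = 2.0
    turn_start_lambda: float = 5.0  # ligand reorientation window
    turn_end_lambda: float = 2.0
    bond_length: float = 1.0  # ligand dumbbell
    jitter: float = 0.08  # lateral noise of the trace, Å
    n_decoys: int = 60
    decoy_margin: float = 2.0  # × max inter-frame RMSD
    seed: int = 0

    def __post_init__(self):
        if self.lambda_start <= self.lambda_end:
            raise SpecError("trace must run from large λ down to the bound state")
        if self.step <= 0:
            raise SpecError("λ step must be positive")
        if not (self.d_holo < self.d_apo < self.d_open):
            raise SpecError("need d_holo < d_apo < d_open")


@dataclass
class BindingTrace:
    """A planted unbinding trace with decoys and full ground truth."""

    trace: list  # ordered snapshots, λ strictly decreasing
    decoys: list
    lambda_true: np.ndarray  # per trace frame
    gate_distance_true: np.ndarray
    orientation_true: np.ndarray  # ligand axis angle from +x, degrees
    roles: dict
    origin: np.ndarray  # bound ligand centroid
    vector: np.ndarray  # planted dissociation direction (+x)
    max_interframe_rmsd: float
    spec: TraceSpec
    ensemble: list = field(default_factory=list)  # trace + decoys
    trace_indices: np.ndarray | None = None

    def weights(self) -> np.ndarray:
        n = len(self.ensemble)
        return np.full(n, 1.0 / n)


def _gate_distance(lam, spec: TraceSpec) -> float:
    settle = 1.0 - np.exp(-((lam / 2.0) ** 2))  # 0 at bound, 1 away
    bump = np.exp(
        -((lam - spec.gate_peak_lambda) ** 2) / (2.0 * spec.gate_peak_sigma**2)
    )
    # the opening bump is gated by `settle` so the bound state (λ = 0) has
    # exactly the tight holo separation
    return float(
        spec.d_holo
        + (spec.d_apo - spec.d_holo) * settle
        + (spec.d_open - spec.d_apo) * bump * settle
    )


def _orientation_deg(lam, spec: TraceSpec) -> float:
    span = spec.turn_start_lambda - spec.turn_end_lambda
    f = np.clip((spec.turn_start_lambda - lam) / span, 0.0, 1.0)
    return float(90.0 * f)


def _trace_coords(lam, base, spec: TraceSpec, rng) -> np.ndarray:
    coords = base.copy()
    jit = spec.jitter * rng.standard_normal(2)
    centroid = np.array([lam, jit[0], jit[1]])
    psi = np.deg2rad(_orientation_deg(lam, spec))
    axis = np.array([np.cos(psi), np.sin(psi), 0.0])
    coords[0] = centroid + 0.5 * spec.bond_length * axis
    coords[1] = centroid - 0.5 * spec.bond_length * axis
    d = _gate_distance(lam, spec)
    coords[2] = (3.0, d / 2.0, 0.0)
    coords[3] = (3.0, -d / 2.0, 0.0)
    return coords


def generate_binding_trace(spec: TraceSpec) -> BindingTrace:
    """Continuous unbinding trace threading the gate, plus far decoys.

    Layout: particles 0–1 are the ligand dumbbell, 2–3 the gate beads,
    4–11 the receptor shell (six-bead ring + back wall, fixed).  Along the
    trace the gate opens mid-path (Gaussian bump peaking at
    ``gate_peak_lambda``) and closes tighter than the apo separation at the
    bound state; the ligand completes a 90° reorientation before λ reaches
    ``turn_end_lambda``.  Decoys are placed at high polar angles from the
    dissociation axis and are verified exhaustively to lie at least
    ``decoy_margin`` × (max inter-frame RMSD) from every trace frame.
    """
    rng = np.random.default_rng(spec.seed)
    shell = make_gated_pocket().reference_coords[3:]  # ring + back wall
    n = 4 + shell.shape[0]
    base = np.zeros((n, 3))
    base[4:] = shell
    lams = np.arange(spec.lambda_start, spec.lambda_end - 0.5 * spec.step, -spec.step)
    lams = np.round(lams, 10)
    if lams[-1] > 1e-9:
        lams = np.append(lams, 0.0)
    trace = []
    for i, lam in enumerate(lams):
        coords = _trace_coords(lam, base, spec, rng)
        trace.append(Snapshot(coords, 0.0, traj_id=0, step=i))
    gate_true = np.array([_gate_distance(l, spec) for l in lams])
    orient_true = np.array([_orientation_deg(l, spec) for l in lams])
    inter = [
        float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))
        for a, b in zip(trace[:-1], trace[1:])
    ]
    max_inter = max(inter)
    min_decoy_dist = spec.decoy_margin * max_inter
    decoys = []
    attempts = 0
    while len(decoys) < spec.n_decoys:
        attempts += 1
        if attempts > 100 * spec.n_decoys:
            raise SpecError(
                f"cannot place decoys ≥ {min_decoy_dist:.2f} Å (RMSD) from the trace"
            )
        radius = rng.uniform(8.0, 13.0)
        polar = np.deg2rad(rng.uniform(80.0, 100.0))
        azim = rng.uniform(0.0, 2.0 * np.pi)
        centroid = radius * np.array(
            [np.cos(polar), np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim)]
        )
        psi = rng.uniform(0.0, np.pi)
        axis = np.array([np.cos(psi), np.sin(psi), 0.0])
        coords = base.copy()
        coords[0] = centroid + 0.5 * spec.bond_length * axis
        coords[1] = centroid - 0.5 * spec.bond_length * axis
        d = spec.d_apo
        coords[2] = (3.0, d / 2.0, 0.0)
        coords[3] = (3.0, -d / 2.0, 0.0)
        dmin = min(
            float(np.sqrt(np.mean(np.sum((coords - t.coords) ** 2, axis=1))))
            for t in trace
        )
        if dmin >= min_decoy_dist:
            decoys.append(Snapshot(coords, 0.0, traj_id=1, step=len(decoys)))
    ensemble = list(trace) + list(decoys)
    return BindingTrace(
        trace=trace,
        decoys=decoys,
        lambda_true=lams,
        gate_distance_true=gate_true,
        orientation_true=orient_true,
        roles={
            "ligand": np.array([0, 1]),
            "gate": np.array([2, 3]),
            "receptor": np.arange(2, n),
            "shell": np.arange(4, n),
        },
        origin=np.zeros(3),
        vector=np.array([1.0, 0.0, 0.0]),
        max_interframe_rmsd=max_inter,
        spec=spec,
        ensemble=ensemble,
        trace_indices=np.arange(len(trace)),
    )
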
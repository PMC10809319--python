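"""Toy receptor–ligand systems and their analytic potentials.

Four potentials are provided, spanning the cases the sampling and
analysis stages need:

``harmonic``
    n particles in an isotropic harmonic well, 0.5·k·|r|² summed over all
    coordinates.  Exactly solvable: ⟨E⟩ = (n·dim/2)·kB·T.
``double_well``
    one particle in 1D, quartic h·(x²/w² − 1)² + tilt·x.  With tilt = 0 the
    minima sit at ±w with a barrier of height h at x = 0.
``mueller_like_2d``
    one particle on a scaled Müller–Brown surface (three basins connected
    by bent channels), the classic 2D test landscape.
``gated_pocket``
    a coarse-grained receptor–ligand model in 3D: a single-bead ligand, a
    shell of tethered receptor beads forming a cup with one entrance, two
    gate beads whose separation follows a tilted double-well (closed is
    favoured), Gaussian attraction wells at surface decoy sites and at one
    hidden pocket site behind the gate, and soft Gaussian repulsion between
    the ligand and every receptor/gate bead.  The ligand can only reach the
    pocket while the gate is open — a minimal cryptic-site model.

Every potential also supports pairwise harmonic distance restraints
0.5·k·(d − d0)², the toy counterpart of the hydrogen-bond restraints used
to keep a receptor folded during high-temperature sampling.

A pure-numpy implementation of every term lives here; the numba kernels in
:mod:`mcdock._kernels` reimplement them for the samplers and are tested
against this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ShapeError

POTENTIALS = ("harmonic", "double_well", "mueller_like_2d", "gated_pocket")
_POT_IDS = {name: i for i, name in enumerate(POTENTIALS)}

# Müller–Brown constants (unscaled); the `scale` parameter multiplies the sum.
_MB_A = (-200.0, -100.0, -170.0, 15.0)
_MB_a = (-1.0, -1.0, -6.5, 0.7)
_MB_b = (0.0, 0.0, 11.0, 0.6)
_MB_c = (-10.0, -10.0, -6.5, 0.7)
_MB_x0 = (1.0, 0.0, -0.5, -1.0)
_MB_y0 = (0.0, 0.5, 1.5, 1.0)


@dataclass(frozen=True)
class Restraint:
    """Harmonic distance restraint between particles ``i`` and ``j``."""

    i: int
    j: int
    target: float  # Å
    k: float  # kcal/mol/Å², must be >= 0

    def __post_init__(self):
        if self.k < 0:
            raise InputError("restraint force constant must be >= 0")
        if self.i == self.j:
            raise InputError("restraint must join two distinct particles")


@dataclass
class ToySystem:
    """A toy system: particles, potential, tethers, sites and restraints.

    ``roles`` maps selection names (``ligand``, ``gate``, ``receptor``) to
    index arrays; ``reference_coords`` is the canonical starting
    configuration (for ``gated_pocket`` the bound pose with the gate
    closed).
    """

    potential_id: str
    n_particles: int
    dim: int
    params: dict = field(default_factory=dict)
    masses: np.ndarray | None = None
    restraints: list = field(default_factory=list)
    reference_coords: np.ndarray | None = None
    roles: dict = field(default_factory=dict)
    # packed site/tether arrays used by gated_pocket (empty otherwise)
    site_positions: np.ndarray | None = None  # (m, dim)
    site_depths: np.ndarray | None = None  # kcal/mol
    site_sigmas: np.ndarray | None = None  # Å
    site_labels: tuple = ()
    tether_ref: np.ndarray | None = None  # (n, dim)
    tether_k: np.ndarray | None = None  # (n,)

    def __post_init__(self):
        if self.potential_id not in _POT_IDS:
            raise InputError(f"unknown potential_id {self.potential_id!r}")
        if self.masses is None:
            self.masses = np.ones(self.n_particles)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.reference_coords is None:
            self.reference_coords = np.zeros((self.n_particles, self.dim))
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.site_positions is None:
            self.site_positions = np.zeros((0, self.dim))
            self.site_depths = np.zeros(0)
            self.site_sigmas = np.ones(0)
        if self.tether_ref is None:
            self.tether_ref = np.zeros((self.n_particles, self.dim))
            self.tether_k = np.zeros(self.n_particles)
        self.tether_ref = np.asarray(self.tether_ref, dtype=float)
        self.tether_k = np.asarray(self.tether_k, dtype=float)

    # ---- packing for the numba kernels -------------------------------

    @property
    def pot_id_int(self) -> int:
        return _POT_IDS[self.potential_id]

    def packed_params(self) -> np.ndarray:
        p = self.params
        if self.potential_id == "harmonic":
            return np.array([p.get("k", 1.0)], dtype=float)
        if self.potential_id == "double_well":
            return np.array(
                [p.get("barrier", 3.0), p.get("well_sep", 2.0), p.get("tilt", 0.0)],
                dtype=float,
            )
        if self.potential_id == "mueller_like_2d":
            return np.array([p.get("scale", 0.05)], dtype=float)
        # gated_pocket
        d_open = p["d_open"]
        d_closed = p["d_closed"]
        return np.array(
            [
                0.5 * (d_open + d_closed),  # gate double-well centre
                0.5 * (d_open - d_closed),  # half-separation of the minima
                p.get("gate_barrier", 2.5),
                p.get("gate_tilt", 0.3),
                d_closed,
                p.get("repulsion", 50.0),
                p.get("repulsion_sigma", 1.0),
                p.get("confine_k", 5.0),
                p.get("confine_radius", 12.0),
            ],
            dtype=float,
        )

    def packed_restraints(self):
        if not self.restraints:
            return np.zeros((0, 2), dtype=np.int64), np.zeros((0, 2), dtype=float)
        ij = np.array([[r.i, r.j] for r in self.restraints], dtype=np.int64)
        par = np.array([[r.target, r.k] for r in self.restraints], dtype=float)
        return ij, par


# ---------------------------------------------------------------------------
# Reference (numpy) potential evaluation
# ---------------------------------------------------------------------------


def _base_energy_np(system: ToySystem, coords: np.ndarray) -> float:
    pid = system.potential_id
    pp = system.packed_params()
    e = 0.0
    if pid == "harmonic":
        e = 0.5 * pp[0] * float(np.sum(coords**2))
    elif pid == "double_well":
        x = coords[0, 0]
        h, w, tilt = pp
        u = x * x / (w * w) - 1.0
        e = h * u * u + tilt * x
    elif pid == "mueller_like_2d":
        x, y = coords[0, 0], coords[0, 1]
        s = 0.0
        for A, a, b, c, x0, y0 in zip(_MB_A, _MB_a, _MB_b, _MB_c, _MB_x0, _MB_y0):
            dx, dy = x - x0, y - y0
            s += A * np.exp(a * dx * dx + b * dx * dy + c * dy * dy)
        e = pp[0] * s
    else:  # gated_pocket
        dmid, hw, hg, tilt, dcl, A, sr, kc, rc = pp
        lig = coords[0]
        # attraction wells act on the ligand
        if system.site_positions.shape[0]:
            d2 = np.sum((system.site_positions - lig) ** 2, axis=1)
            e -= float(
                np.sum(system.site_depths * np.exp(-d2 / (2.0 * system.site_sigmas**2)))
            )
        # gate separation double-well, tilted toward closed
        dg = float(np.linalg.norm(coords[1] - coords[2]))
        u = ((dg - dmid) / hw) ** 2 - 1.0
        e += hg * u * u + tilt * (dg - dcl)
        # soft repulsion between the ligand and every other bead
        d2 = np.sum((coords[1:] - lig) ** 2, axis=1)
        e += float(A * np.sum(np.exp(-d2 / (2.0 * sr * sr))))
        # flat-bottom spherical confinement of the ligand
        r = float(np.linalg.norm(lig))
        if r > rc:
            e += 0.5 * kc * (r - rc) ** 2
    # harmonic tethers (receptor shell / gate anchors)
    k = system.tether_k
    if np.any(k > 0):
        d2 = np.sum((coords - system.tether_ref) ** 2, axis=1)
        e += float(0.5 * np.sum(k * d2))
    return e


def restraint_energy(system: ToySystem, coords: np.ndarray) -> float:
    e = 0.0
    for r in system.restraints:
        d = float(np.linalg.norm(coords[r.i] - coords[r.j]))
        e += 0.5 * r.k * (d - r.target) ** 2
    return e


def potential_energy(
    system: ToySystem, coords, include_restraints: bool = True
) -> float:
    """Total potential energy of ``coords`` (kcal/mol), restraints included.

    Raises :class:`ShapeError` when the coordinate array does not match the
    system's ``(n_particles, dim)`` shape.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_particles, system.dim):
        raise ShapeError(
            f"coords shape {coords.shape} does not match system "
            f"({system.n_particles}, {system.dim})"
        )
    e = _base_energy_np(system, coords)
    if include_restraints and system.restraints:
        e += restraint_energy(system, coords)
    return float(e)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def make_harmonic(k: float = 1.0, n_particles: int = 1, dim: int = 1) -> ToySystem:
    """Isotropic harmonic well; ⟨E⟩ = (n·dim/2)·kB·T canonically."""
    return ToySystem(
        potential_id="harmonic",
        n_particles=n_particles,
        dim=dim,
        params={"k": k},
    )


def make_double_well(
    barrier: float = 3.0, well_sep: float = 2.0, tilt: float = 0.0
) -> ToySystem:
    """1D quartic double well h·(x²/w² − 1)² + tilt·x.

    With ``tilt = 0`` the minima are at ±``well_sep`` (energy 0) and the
    barrier at x = 0 has height ``barrier``.
    """
    sys_ = ToySystem(
        potential_id="double_well",
        n_particles=1,
        dim=1,
        params={"barrier": barrier, "well_sep": well_sep, "tilt": tilt},
    )
    sys_.reference_coords = np.array([[-well_sep]])
    return sys_


def make_mueller(scale: float = 0.05) -> ToySystem:
    """Scaled Müller–Brown surface; ``scale``·(raw MB), one particle, 2D."""
    sys_ = ToySystem(
        potential_id="mueller_like_2d", n_particles=1, dim=2, params={"scale": scale}
    )
    sys_.reference_coords = np.array([[-0.558, 1.442]])  # deepest MB basin
    return sys_


def make_gated_pocket(
    pocket_depth: float = 8.0,
    surface_depths: tuple = (3.5, 3.0),
    site_sigma: float = 1.2,
    gate_barrier: float = 2.5,
    gate_tilt: float = 0.3,
    d_open: float = 8.0,
    d_closed: float = 3.0,
    repulsion: float = 50.0,
    repulsion_sigma: float = 1.0,
    shell_radius: float = 3.5,
    tether_k: float = 20.0,
    gate_tether_k: float = 2.0,
    restrain_shell: bool = False,
) -> ToySystem:
    """Coarse-grained cryptic-pocket receptor with a single-bead ligand.

    Geometry (3D, Å): the hidden pocket site sits at the origin, ringed in
    the y–z plane by eight receptor beads at ``shell_radius`` plus a
    back-wall bead at (−shell_radius, 0, 0); the +x direction is the only
    entrance and is blocked by two gate beads anchored near
    (3, ±d_closed/2, 0) — the gate gap is the widest opening in the shell.
    Surface decoy sites sit outside the shell at (0, 7, 0) and (0, 0, 7).
    Particle 0 is the ligand, particles 1–2 the gate, the rest the shell.

    ``restrain_shell`` adds pairwise distance restraints between adjacent
    ring beads (the toy analogue of hydrogen-bond restraints that keep a
    receptor folded at high effective temperatures).
    """
    if pocket_depth <= max(surface_depths):
        raise InputError("pocket well must be deeper than every surface decoy")
    if d_open <= d_closed:
        raise InputError("gate open distance must exceed the closed distance")
    ring = np.array(
        [
            [0.0, shell_radius * np.cos(t), shell_radius * np.sin(t)]
            for t in np.linspace(0.0, 2.0 * np.pi, 9)[:-1]
        ]
    )
    # a second, narrower ring closes the back hemisphere, and a collar ring
    # frames the entrance mouth at the gate plane, so the gap between the
    # two gate beads is the only passage wider than the inter-bead spacing
    back_ring = np.array(
        [
            [-2.0, 2.5 * np.cos(t), 2.5 * np.sin(t)]
            for t in (np.linspace(0.0, 2.0 * np.pi, 9)[:-1] + np.pi / 8.0)
        ]
    )
    collar = np.array(
        [
            [3.0, shell_radius * np.cos(t), shell_radius * np.sin(t)]
            for t in (np.linspace(0.0, 2.0 * np.pi, 9)[:-1] + np.pi / 8.0)
        ]
    )
    back = np.vstack([back_ring, collar, [[-shell_radius, 0.0, 0.0]]])
    gate = np.array([[3.0, d_closed / 2.0, 0.0], [3.0, -d_closed / 2.0, 0.0]])
    ligand = np.array([[0.0, 0.0, 0.0]])  # bound reference pose
    coords = np.vstack([ligand, gate, ring, back])
    n = coords.shape[0]

    sites = np.array([[0.0, 0.0, 0.0], [0.0, 7.0, 0.0], [0.0, 0.0, 7.0]])
    depths = np.array([pocket_depth, *surface_depths])
    labels = ("pocket", "surface", "surface")

    tether_ref = coords.copy()
    tether_k_arr = np.zeros(n)
    tether_k_arr[1:3] = gate_tether_k
    tether_k_arr[3:] = tether_k

    restraints = []
    if restrain_shell:
        ring_idx = list(range(3, 3 + ring.shape[0]))
        for a, b in zip(ring_idx, ring_idx[1:] + ring_idx[:1]):
            d0 = float(np.linalg.norm(coords[a] - coords[b]))
            restraints.append(Restraint(a, b, d0, 10.0))

    sys_ = ToySystem(
        potential_id="gated_pocket",
        n_particles=n,
        dim=3,
        params={
            "d_open": d_open,
            "d_closed": d_closed,
            "gate_barrier": gate_barrier,
            "gate_tilt": gate_tilt,
            "repulsion": repulsion,
            "repulsion_sigma": repulsion_sigma,
            "confine_k": 5.0,
            "confine_radius": 12.0,
        },
        restraints=restraints,
        reference_coords=coords,
        roles={
            "ligand": np.array([0]),
            "gate": np.array([1, 2]),
            "receptor": np.arange(1, n),  # gate beads are part of the receptor
            "shell": np.arange(3, n),
        },
        site_positions=sites,
        site_depths=depths,
        site_sigmas=np.full(3, site_sigma),
        site_labels=labels,
        tether_ref=tether_ref,
        tether_k=tether_k_arr,
    )
    return sys_


def site_position(system: ToySystem, label: str, occurrence: int = 0) -> np.ndarray:
    """Coordinates of the ``occurrence``-th site carrying ``label``."""
    hits = [i for i, lab in enumerate(system.site_labels) if lab == label]
    if occurrence >= len(hits):
        raise InputError(f"system has no site {label!r} #{occurrence}")
    return system.site_positions[hits[occurrence]].copy()
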
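"""Per-snapshot structural statistics: contacts, R-values, RMSD, SASA, RASA.

The R-value is the hard-count native-contact fraction (Q-value family): the
fraction of a reference receptor–ligand contact set that is conserved in an
observed configuration.  Contacts are (receptor residue, ligand atom) pairs
whose minimum heavy-atom distance is within a cutoff (4.5 Å by default,
boundary inclusive).

SASA uses the Shrake–Rupley construction with a deterministic golden-angle
sphere lattice, and RASA is the ligand's SASA in the complex divided by its
SASA isolated in the same conformation — low RASA means a buried pose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import InputError, ResolutionError, UndefinedStatisticError
from .fel import kabsch

DEFAULT_CONTACT_CUTOFF = 4.5  # Å
DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_SPHERE_POINTS = 960
DEFAULT_ATOM_RADIUS = 1.7  # Å, generic heavy-atom radius for toy beads


@dataclass(frozen=True)
class ContactSet:
    """Receptor-residue × ligand-atom contacts at a distance cutoff."""

    pairs: frozenset
    cutoff: float
    definition: str = "heavy_atom_min_distance"

    def __len__(self):
        return len(self.pairs)


@dataclass
class SasaResult:
    """Per-atom solvent-accessible surface areas (Å²)."""

    areas: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def _coords_of(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "coords", obj), dtype=float)


def contact_set(
    snapshot,
    receptor_selection,
    ligand_selection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    receptor_residue_ids=None,
    ligand_atom_ids=None,
) -> ContactSet:
    """Contacts between receptor residues and ligand atoms.

    ``receptor_residue_ids`` maps each selected receptor atom to its residue
    (defaults to one residue per atom, the natural choice for bead models);
    a (residue, ligand atom) pair is a contact iff the minimum distance
    over the residue's atoms is ≤ ``cutoff`` (inclusive).
    """
    coords = _coords_of(snapshot)
    rec = np.asarray(receptor_selection, dtype=int)
    lig = np.asarray(ligand_selection, dtype=int)
    if rec.size == 0 or lig.size == 0:
        raise InputError("receptor and ligand selections must be nonempty")
    if np.intersect1d(rec, lig).size:
        raise InputError("receptor and ligand selections must be disjoint")
    if receptor_residue_ids is None:
        receptor_residue_ids = rec
    receptor_residue_ids = np.asarray(receptor_residue_ids)
    if receptor_residue_ids.size != rec.size:
        raise InputError("one residue id per receptor atom required")
    if ligand_atom_ids is None:
        ligand_atom_ids = lig
    ligand_atom_ids = np.asarray(ligand_atom_ids)
    d = cdist(coords[rec], coords[lig])
    pairs = set()
    for res in np.unique(receptor_residue_ids):
        rows = receptor_residue_ids == res
        dmin = d[rows].min(axis=0)
        for k in np.nonzero(dmin <= cutoff)[0]:
            pairs.add((res.item() if hasattr(res, "item") else res,
                       int(ligand_atom_ids[k])))
    return ContactSet(frozenset(pairs), cutoff)


def r_value(observed: ContactSet, reference: ContactSet) -> float:
    """Fraction of reference contacts conserved in the observed set."""
    if len(reference) == 0:
        raise UndefinedStatisticError("R-value undefined for an empty reference")
    return len(observed.pairs & reference.pairs) / len(reference.pairs)


def r_value_trace(
    trajectories,
    reference: ContactSet,
    receptor_selection,
    ligand_selection,
    window: int,
    cutoff: float | None = None,
    receptor_residue_ids=None,
) -> tuple:
    """Mean and population SD of the per-frame R-value over final windows.

    ``trajectories`` is one snapshot list or a list of them; the final
    ``window`` frames of each trajectory are pooled.  Returns
    (mean, sd, per-frame values).
    """
    if window < 1:
        raise InputError("window must be >= 1")
    if trajectories and not isinstance(trajectories[0], (list, tuple)):
        trajectories = [trajectories]
    cutoff = reference.cutoff if cutoff is None else cutoff
    values = []
    for traj in trajectories:
        if window > len(traj):
            raise InputError(
                f"window {window} longer than trajectory ({len(traj)} frames)"
            )
        for snap in traj[-window:]:
            obs = contact_set(
                snap, receptor_selection, ligand_selection, cutoff,
                receptor_residue_ids,
            )
            values.append(r_value(obs, reference))
    values = np.asarray(values)
    return float(values.mean()), float(values.std()), values


def ligand_rmsd(snapshot, reference, superpose_selection, rmsd_selection) -> float:
    """RMSD over ``rmsd_selection`` after superposing on ``superpose_selection``.

    The fit is computed on the superpose selection only (e.g. receptor
    backbone) and applied to all particles; the RMSD is then taken over the
    ligand selection without refitting.
    """
    a = _coords_of(snapshot)
    b = _coords_of(reference)
    sup = np.asarray(superpose_selection, dtype=int)
    sel = np.asarray(rmsd_selection, dtype=int)
    if sel.size == 0:
        raise InputError("rmsd selection is empty")
    rot, t = kabsch(a[sup], b[sup])
    fitted = a @ rot.T + t
    diff = fitted[sel] - b[sel]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-angle (Fibonacci) lattice on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    coords,
    radii=None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area per atom.

    Each atom's sphere of radius r+probe is sampled at ``n_points`` lattice
    points; the accessible area is the exposed fraction times 4π(r+probe)².
    """
    coords = _coords_of(coords)
    n = coords.shape[0]
    if radii is None:
        radii = np.full(n, DEFAULT_ATOM_RADIUS)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise InputError("atomic radii must be positive")
    if n_points < 32:
        raise ResolutionError("sasa needs at least 32 sphere points")
    pts = sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n)
    r_max = ext.max()
    for i in range(n):
        sample = coords[i] + ext[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], ext[i] + r_max):
            if j == i:
                continue
            d2 = np.sum((sample - coords[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * ext[i] ** 2
    return SasaResult(areas, probe, n_points)


def rasa(
    complex_snapshot,
    ligand_selection,
    radii=None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Relative accessible surface area of the ligand.

    SASA of the ligand atoms within the complex divided by the SASA of the
    ligand alone in the identical conformation, clamped to [0, 1 + ε].
    """
    coords = _coords_of(complex_snapshot)
    lig = np.asarray(ligand_selection, dtype=int)
    if lig.size == 0:
        raise InputError("ligand selection is empty")
    n = coords.shape[0]
    if radii is None:
        radii = np.full(n, DEFAULT_ATOM_RADIUS)
    radii = np.asarray(radii, dtype=float)
    in_complex = sasa(coords, radii, probe, n_points).areas[lig].sum()
    isolated = sasa(coords[lig], radii[lig], probe, n_points).areas.sum()
    if isolated <= 0:
        raise UndefinedStatisticError("isolated ligand SASA is zero")
    return float(np.clip(in_complex / isolated, 0.0, 1.0 + 0.02))
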
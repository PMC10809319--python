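"""Binding-path extraction from an unbiased structural ensemble.

The bound pose defines the origin; a dissociation ray is estimated from the
receptor→ligand centroid direction, refined over a deterministic fan of
candidate rays by minimising the steric overlap with receptor atoms
integrated from the origin to the solvent boundary.  Each snapshot gets a
progress coordinate λ (the projection of its ligand centroid displacement
onto the ray; λ = 0 is bound).  Milestones are then chained window by
window outward from the bound pose: within every λ window the snapshot
closest (all-particle RMSD) to the previous milestone is selected, which
threads a geometrically continuous unbinding path through the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, PathGapError
from .reweighting import WeightedEnsemble

#: Default λ-window centres (Å) with ±1.5 Å half-width: the visible
#: milestones of a 14 Å dissociation (outside, approach, gateway, bound).
DEFAULT_WINDOW_CENTERS = (14.0, 9.0, 4.5, 0.0)
DEFAULT_WINDOW_HALF_WIDTH = 1.5


@dataclass
class PathMilestone:
    """One structure along the binding path."""

    window_lambda: float  # window centre, Å
    snapshot: object
    snapshot_index: int
    rmsd_to_prev: float  # Å; NaN for the outermost milestone
    window_bounds: tuple  # (lo, hi) Å


def lambda_windows(
    centers=DEFAULT_WINDOW_CENTERS, half_width=DEFAULT_WINDOW_HALF_WIDTH
):
    """[(center, lo, hi), ...] for explicit window centres."""
    return [(float(c), float(c - half_width), float(c + half_width)) for c in centers]


def auto_lambda_windows(lambdas, n_windows: int = 6):
    """Equal-count λ windows spanning the data, anchored so one contains 0.

    Snapshots behind the bound pose (λ < −0.5 Å) are not on the
    dissociation path and are ignored when placing the windows.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    lambdas = lambdas[lambdas >= -0.5]
    if lambdas.size == 0:
        raise InputError("no snapshots on the dissociation side of the origin")
    qs = np.quantile(lambdas, np.linspace(0, 1, n_windows + 1))
    qs[0] = min(qs[0], -1e-9)  # the first window must contain λ=0
    qs[1] = max(qs[1], 1e-9)
    out = []
    for lo, hi in zip(qs[:-1], qs[1:]):
        out.append((0.5 * (lo + hi), float(lo), float(hi)))
    return out


def estimate_dissociation_vector(
    bound,
    receptor_selection,
    ligand_selection,
    n_polar: int = 13,
    n_azimuth: int = 36,
    max_polar_deg: float = 180.0,
    ray_length: float = 15.0,
    ray_step: float = 0.25,
    steric_sigma: float = 1.5,
):
    """Estimate the dissociation direction from a bound pose.

    The base ray runs from the receptor centroid through the ligand
    centroid.  A deterministic fan of candidate rays (polar angles up to
    ``max_polar_deg`` in ``n_polar`` steps × ``n_azimuth`` azimuths around
    the base ray) is scanned; each candidate is scored by the Gaussian
    steric overlap with the receptor atoms accumulated along the ray from
    the ligand centroid to ``ray_length``, and the minimal-overlap ray wins
    (ties resolve to the smaller polar angle, then azimuth — i.e. toward
    the base ray).  Returns (unit vector, origin).
    """
    coords = np.asarray(getattr(bound, "coords", bound), dtype=float)
    rec = np.asarray(receptor_selection, dtype=int)
    lig = np.asarray(ligand_selection, dtype=int)
    if rec.size == 0 or lig.size == 0:
        raise InputError("receptor and ligand selections must be nonempty")
    origin = coords[lig].mean(axis=0)
    rec_centroid = coords[rec].mean(axis=0)
    base = origin - rec_centroid
    norm = np.linalg.norm(base)
    if norm < 1e-9:
        raise InputError(
            "ligand and receptor centroids coincide; dissociation direction "
            "is degenerate"
        )
    base = base / norm
    # orthonormal frame around the base direction
    helper = np.array([1.0, 0.0, 0.0])
    if abs(base @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(base, helper)
    u /= np.linalg.norm(u)
    v = np.cross(base, u)
    ts = np.arange(ray_step, ray_length + 0.5 * ray_step, ray_step)
    best = None
    best_key = None
    for ip in range(n_polar):
        theta = np.deg2rad(max_polar_deg) * ip / max(n_polar - 1, 1)
        azimuths = [0.0] if ip == 0 else [
            2.0 * np.pi * ia / n_azimuth for ia in range(n_azimuth)
        ]
        for ia, phi in enumerate(azimuths):
            d = (
                np.cos(theta) * base
                + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v)
            )
            pts = origin[None, :] + ts[:, None] * d[None, :]
            d2 = ((pts[:, None, :] - coords[rec][None, :, :]) ** 2).sum(axis=2)
            score = float(
                np.exp(-d2 / (2.0 * steric_sigma**2)).sum() * ray_step
            )
            key = (score, ip, ia)
            if best_key is None or key < best_key:
                best_key = key
                best = d
    return best / np.linalg.norm(best), origin


def assign_lambda(ensemble, vector, origin, ligand_selection) -> np.ndarray:
    """λ of every snapshot: ligand-centroid displacement projected on the ray.

    The ensemble must already be superposed into the bound reference frame;
    the bound pose maps to λ = 0.
    """
    vector = np.asarray(vector, dtype=float)
    vector = vector / np.linalg.norm(vector)
    lig = np.asarray(ligand_selection, dtype=int)
    snaps = ensemble.snapshots if isinstance(ensemble, WeightedEnsemble) else ensemble
    out = np.empty(len(snaps))
    for i, s in enumerate(snaps):
        centroid = s.coords[lig].mean(axis=0)
        out[i] = (centroid - origin) @ vector
    return out


def _rmsd(a, b, sel=None):
    if sel is not None:
        a = a[sel]
        b = b[sel]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def extract_path(
    ensemble,
    lambdas,
    windows,
    start: int,
    weights=None,
    rmsd_selection=None,
) -> list:
    """Chain nearest-neighbour milestones outward from the bound pose.

    ``windows`` is a list of (center, lo, hi); the window whose bounds
    contain λ = 0 seeds the chain with ``start`` (which must lie in it).
    In every subsequent window (ascending centre) the snapshot minimising
    all-particle RMSD to the previous milestone is chosen — exact RMSD ties
    resolve to the higher-weight snapshot, then the lower index.  Returned
    milestones are ordered from the outermost window down to λ = 0
    (strictly decreasing λ), with ``rmsd_to_prev`` relative to the previous
    (larger-λ) milestone.
    """
    snaps = ensemble.snapshots if isinstance(ensemble, WeightedEnsemble) else ensemble
    if weights is None:
        weights = (
            ensemble.weights
            if isinstance(ensemble, WeightedEnsemble)
            else np.full(len(snaps), 1.0 / max(len(snaps), 1))
        )
    weights = np.asarray(weights, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    windows = sorted(windows, key=lambda wdw: wdw[0])
    centers = [wdw[0] for wdw in windows]
    if len(set(centers)) != len(centers):
        raise InputError("window centres must be distinct")
    c0, lo0, hi0 = windows[0]
    if not (lo0 <= 0.0 <= hi0):
        raise InputError("the innermost window must contain λ = 0")
    if not (lo0 <= lambdas[start] <= hi0):
        raise InputError(
            f"start snapshot (λ={lambdas[start]:.3f}) is outside the λ=0 window"
        )
    sel = None if rmsd_selection is None else np.asarray(rmsd_selection, dtype=int)
    chain = [(windows[0], start)]
    prev = start
    for wdw in windows[1:]:
        c, lo, hi = wdw
        members = np.nonzero((lambdas >= lo) & (lambdas <= hi))[0]
        if members.size == 0:
            raise PathGapError(
                f"λ window centred at {c:g} Å ([{lo:g}, {hi:g}]) contains no "
                "snapshots", window=wdw,
            )
        best = None
        best_key = None
        for idx in members:
            r = _rmsd(snaps[prev].coords, snaps[idx].coords, sel)
            key = (r, -weights[idx], idx)
            if best_key is None or key < best_key:
                best_key = key
                best = int(idx)
        chain.append((wdw, best))
        prev = best
    milestones = []
    chain = chain[::-1]  # outermost first
    for k, (wdw, idx) in enumerate(chain):
        if k == 0:
            r = float("nan")
        else:
            r = _rmsd(snaps[chain[k - 1][1]].coords, snaps[idx].coords, sel)
        milestones.append(
            PathMilestone(
                window_lambda=wdw[0],
                snapshot=snaps[idx],
                snapshot_index=idx,
                rmsd_to_prev=r,
                window_bounds=(wdw[1], wdw[2]),
            )
        )
    return milestones


def gateway_metric(snapshot, gate_pair_selection) -> float:
    """Distance (Å) between the two named gate particles."""
    coords = np.asarray(getattr(snapshot, "coords", snapshot), dtype=float)
    pair = np.asarray(gate_pair_selection, dtype=int)
    if pair.size != 2:
        raise InputError("gate selection must name exactly two particles")
    if np.any(pair < 0) or np.any(pair >= coords.shape[0]):
        raise InputError("gate particle index out of range")
    return float(np.linalg.norm(coords[pair[0]] - coords[pair[1]]))
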
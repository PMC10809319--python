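"""Weighted ensemble observables: RMSF, DCC, ligand density, ion counts.

All statistics use the snapshot weights of the reweighted (canonical)
ensemble, so they describe the canonical average at the ensemble's
temperature rather than the flat multicanonical sampling distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError
from .reweighting import WeightedEnsemble


def _unpack(weighted_ensemble, selection=None):
    if not isinstance(weighted_ensemble, WeightedEnsemble):
        raise InputError("expected a WeightedEnsemble")
    coords = weighted_ensemble.coords()
    if selection is not None:
        coords = coords[:, np.asarray(selection, dtype=int), :]
    return coords, weighted_ensemble.weights


def weighted_rmsf(weighted_ensemble, selection=None) -> np.ndarray:
    """Per-particle RMS fluctuation about the weighted mean position (Å)."""
    coords, w = _unpack(weighted_ensemble, selection)
    if coords.shape[0] == 1:
        warnings.warn("RMSF of a single snapshot is identically zero",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(coords.shape[1])
    mean = np.einsum("n,nij->ij", w, coords)
    d2 = np.sum((coords - mean) ** 2, axis=2)
    return np.sqrt(np.einsum("n,ni->i", w, d2))


def dcc(weighted_ensemble, selection=None) -> np.ndarray:
    """Dynamic cross-correlation matrix C_ij ∈ [−1, 1].

    C_ij = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩⟨Δr_j²⟩)^½ with weighted moments; the
    diagonal is exactly 1.  Zero-variance particles yield NaN rows/columns
    (flagged with a warning) since their correlation is undefined.
    """
    coords, w = _unpack(weighted_ensemble, selection)
    mean = np.einsum("n,nij->ij", w, coords)
    dr = coords - mean
    cov = np.einsum("n,nid,njd->ij", w, dr, dr)
    var = np.diag(cov).copy()
    zero = var <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance particles: DCC entries undefined",
            RuntimeWarning, stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = cov / np.sqrt(np.outer(var, var))
    c[zero, :] = np.nan
    c[:, zero] = np.nan
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return c


@dataclass
class DensityGrid:
    """3D weighted ligand-density grid with nested level sets."""

    edges: tuple  # (x_edges, y_edges, z_edges)
    occupancy: np.ndarray  # sums to 1
    levels: tuple  # fractions of the max voxel density, descending

    def level_mask(self, level: float) -> np.ndarray:
        """Voxels with density ≥ level × max density."""
        return self.occupancy >= level * self.occupancy.max()


def density_grid(
    weighted_ensemble,
    ligand_selection,
    voxel: float = 1.0,
    levels: tuple = (0.5, 0.1, 0.01),
) -> DensityGrid:
    """Bin ligand-atom positions with snapshot weights into voxels.

    Every ligand atom of a snapshot contributes that snapshot's weight;
    the grid is normalized to total mass 1.  ``levels`` are the high/
    medium/low thresholds as fractions of the maximum voxel density and
    are nested by construction.
    """
    if voxel <= 0:
        raise InputError("voxel size must be positive")
    if tuple(sorted(levels, reverse=True)) != tuple(levels):
        raise InputError("levels must be given in descending order")
    coords, w = _unpack(weighted_ensemble, ligand_selection)
    n_snap, n_lig, _ = coords.shape
    pts = coords.reshape(-1, 3)
    wts = np.repeat(w, n_lig)
    edges = []
    for k in range(3):
        lo = np.floor(pts[:, k].min() / voxel) * voxel
        hi = np.ceil(pts[:, k].max() / voxel) * voxel + voxel
        edges.append(np.arange(lo, hi + 0.5 * voxel, voxel))
    h, _ = np.histogramdd(pts, bins=edges, weights=wts)
    h /= h.sum()
    return DensityGrid(tuple(edges), h, tuple(levels))


def ion_contact_counts(
    weighted_ensemble,
    ion_selection_by_type: dict,
    receptor_selection,
    cutoff: float = 5.0,
) -> dict:
    """Weighted mean number of bound ions per type.

    An ion is bound in a snapshot when its minimum distance to any receptor
    atom is ≤ ``cutoff`` (inclusive).
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    if not isinstance(weighted_ensemble, WeightedEnsemble):
        raise InputError("expected a WeightedEnsemble")
    coords = weighted_ensemble.coords()
    w = weighted_ensemble.weights
    rec = np.asarray(receptor_selection, dtype=int)
    if rec.size == 0:
        raise InputError("receptor selection is empty")
    n = coords.shape[1]
    out = {}
    for ion_type, sel in ion_selection_by_type.items():
        sel = np.asarray(sel, dtype=int)
        if sel.size == 0 or np.any(sel < 0) or np.any(sel >= n):
            raise InputError(f"unknown or invalid ion selection for type {ion_type!r}")
        counts = np.empty(coords.shape[0])
        for i in range(coords.shape[0]):
            d = cdist(coords[i, sel], coords[i, rec]).min(axis=1)
            counts[i] = np.count_nonzero(d <= cutoff)
        out[ion_type] = float(np.sum(w * counts))
    return out
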
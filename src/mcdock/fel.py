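"""Free-energy landscapes on principal components and basin clustering.

The reweighted ensemble is superposed onto a reference (least-squares
rigid-body fit on a receptor selection), the ligand coordinates are
projected onto their first two (weighted) principal components, and a 2D
free-energy surface F = −kB·T·ln(ρ/ρ_max) is histogrammed on that plane.
Basins are found by steepest descent on the occupied grid cells; each basin
is a cluster, ranked by its cluster free energy

    CFE = −kB·T·ln(population / largest population),

and clusters within a CFE cutoff (1 kcal/mol by convention) are reported
with a representative snapshot each: the highest-weight snapshot in the
basin's minimum-F cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .errors import InputError
from .reweighting import WeightedEnsemble

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation moving ``mobile`` onto ``target``.

    Standard SVD construction of the least-squares rigid-body fit.
    Returns (R, t) with fitted = mobile @ R.T + t.  Raises
    :class:`InputError` for fewer than 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise InputError("point sets must have identical shapes")
    if mobile.shape[0] < 3:
        raise InputError("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    if np.linalg.matrix_rank(b, tol=1e-10) < 2 or np.linalg.matrix_rank(a, tol=1e-10) < 2:
        raise InputError("selection points are collinear; rotation underdetermined")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dim = mobile.shape[1]
    corr = np.eye(dim)
    corr[-1, -1] = d
    rot = vt.T @ corr @ u.T
    t = tc - rot @ mc
    return rot, t


def superpose_snapshot(snapshot, reference, selection):
    """New snapshot with all particles moved by the selection's best fit."""
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise InputError("superposition selection is empty")
    rot, t = kabsch(snapshot.coords[sel], reference.coords[sel])
    out = snapshot.copy()
    out.coords = snapshot.coords @ rot.T + t
    return out


def superpose_ensemble(ensemble, reference, selection):
    """Superpose every snapshot onto ``reference`` using ``selection``.

    Accepts a list of snapshots or a :class:`WeightedEnsemble`; returns the
    same kind of container (weights unchanged).
    """
    if isinstance(ensemble, WeightedEnsemble):
        snaps = [superpose_snapshot(s, reference, selection) for s in ensemble.snapshots]
        return WeightedEnsemble(snaps, ensemble.weights, ensemble.T, ensemble.source_bias)
    return [superpose_snapshot(s, reference, selection) for s in ensemble]


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------


@dataclass
class Projection:
    """2D principal-component projection with reusable axes.

    ``axes`` (2, n_features) are orthonormal rows; ``mean_vector`` is the
    weighted feature mean, so projecting the ensemble mean yields (0, 0).
    ``feature_selection`` records which particles built the feature vector.
    """

    pc_coords: np.ndarray  # (N, 2)
    explained_variance: np.ndarray  # fractions, length 2
    mean_vector: np.ndarray
    axes: np.ndarray
    feature_selection: np.ndarray

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Project one snapshot's coordinates with the stored axes."""
        feats = np.asarray(coords, dtype=float)[self.feature_selection].ravel()
        return (feats - self.mean_vector) @ self.axes.T


def _features(coords_stack, selection):
    return coords_stack[:, selection, :].reshape(coords_stack.shape[0], -1)


def pca_project(ensemble, weights=None, feature_selection=None) -> Projection:
    """Weighted PCA of the (superposed) ensemble's feature coordinates.

    ``feature_selection`` defaults to the whole particle set; pass the
    ligand selection to obtain a binding-configuration landscape.  With
    ``weights=None`` the PCA is unweighted (multicanonical-ensemble PCA).
    """
    if isinstance(ensemble, WeightedEnsemble):
        if weights is None:
            weights = ensemble.weights
        coords = ensemble.coords()
    else:
        coords = np.stack([s.coords for s in ensemble])
    n = coords.shape[0]
    if n < 3:
        raise InputError("PCA needs at least 3 snapshots")
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    tot = weights.sum()
    if tot <= 0:
        raise InputError("zero total weight")
    w = weights / tot
    if feature_selection is None:
        feature_selection = np.arange(coords.shape[1])
    feature_selection = np.asarray(feature_selection, dtype=int)
    x = _features(coords, feature_selection)
    mean = w @ x
    xc = x - mean
    cov = (xc * w[:, None]).T @ xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order[:2]].T.copy()
    # deterministic sign: largest-magnitude loading positive
    for i in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] *= -1.0
    total = evals.sum()
    frac = evals[:2] / total if total > 0 else np.zeros(2)
    return Projection(
        pc_coords=xc @ axes.T,
        explained_variance=frac,
        mean_vector=mean,
        axes=axes,
        feature_selection=feature_selection,
    )


# ---------------------------------------------------------------------------
# FEL grid
# ---------------------------------------------------------------------------


@dataclass
class FELGrid:
    """2D free-energy surface; empty cells carry +inf."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny), kcal/mol, min over occupied = 0
    T: float

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def cell_of(self, pc: np.ndarray):
        """(ix, iy) of a PC1/PC2 point (clipped to the grid)."""
        ix = int(np.clip(np.searchsorted(self.x_edges, pc[0], "right") - 1,
                         0, self.x_edges.size - 2))
        iy = int(np.clip(np.searchsorted(self.y_edges, pc[1], "right") - 1,
                         0, self.y_edges.size - 2))
        return ix, iy


def build_fel(
    projection: Projection,
    weights,
    T: float = 300.0,
    grid: tuple = (100, 100),
    padding: float = 0.05,
) -> FELGrid:
    """Weighted 2D histogram → F = −kB·T·ln(ρ/ρ_max) on PC1/PC2."""
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise InputError("weights must be normalized")
    pc = projection.pc_coords
    spans = []
    for k in range(2):
        lo, hi = float(pc[:, k].min()), float(pc[:, k].max())
        pad = padding * max(hi - lo, 1e-9)
        spans.append((lo - pad, hi + pad))
    x_edges = np.linspace(*spans[0], grid[0] + 1)
    y_edges = np.linspace(*spans[1], grid[1] + 1)
    rho, _, _ = np.histogram2d(pc[:, 0], pc[:, 1], bins=(x_edges, y_edges),
                               weights=weights)
    fe = np.full_like(rho, np.inf)
    occ = rho > 0
    fe[occ] = -KB * T * np.log(rho[occ] / rho.max())
    return FELGrid(x_edges, y_edges, fe, T)


# ---------------------------------------------------------------------------
# Basin clustering
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    """A free-energy basin: member snapshots, population, CFE, representative."""

    member_indices: np.ndarray
    population: float
    cfe: float
    representative_index: int
    representative: object
    root_cell: tuple
    basin_cells: list


def _basin_map(fel: FELGrid):
    """Steepest-descent basin label for every occupied cell.

    Descent moves to the 8-neighbour with the lexicographically smallest
    (F, flat_index) key when that key is smaller than the cell's own, which
    makes the descent strictly decreasing (ties broken by index) and hence
    terminating; empty cells never participate.
    """
    fe = fel.free_energy
    nx, ny = fe.shape
    flat = lambda c: c[0] * ny + c[1]
    parent = {}
    occupied_cells = [tuple(c) for c in np.argwhere(np.isfinite(fe))]
    for cell in occupied_cells:
        best = (fe[cell], flat(cell))
        best_cell = cell
        for di, dj in _NEIGHBORS:
            i, j = cell[0] + di, cell[1] + dj
            if 0 <= i < nx and 0 <= j < ny and np.isfinite(fe[i, j]):
                key = (fe[i, j], flat((i, j)))
                if key < best:
                    best = key
                    best_cell = (i, j)
        parent[cell] = best_cell
    roots = {}

    def find(cell):
        path = []
        while parent[cell] != cell:
            path.append(cell)
            cell = parent[cell]
        for c in path:
            parent[c] = cell
        return cell

    for cell in occupied_cells:
        roots[cell] = find(cell)
    return roots


def _smoothed_fel(fel: FELGrid, sigma: float) -> FELGrid:
    """FEL with the underlying density Gaussian-smoothed by ``sigma`` cells.

    A histogrammed density is shot-noise-limited near its peaks, and
    steepest descent on the raw surface fragments one physical basin into
    several spurious ones; descending on a lightly smoothed copy removes
    the fragmentation while populations and CFEs are still computed from
    the raw snapshot weights.
    """
    from scipy.ndimage import gaussian_filter

    rho = np.zeros_like(fel.free_energy)
    occ = np.isfinite(fel.free_energy)
    rho[occ] = np.exp(-fel.free_energy[occ] / (KB * fel.T))
    rho_s = gaussian_filter(rho, sigma=sigma, mode="constant")
    fe = np.full_like(rho_s, np.inf)
    keep = rho_s > 1e-12 * rho_s.max()
    fe[keep] = -KB * fel.T * np.log(rho_s[keep] / rho_s.max())
    return FELGrid(fel.x_edges, fel.y_edges, fe, fel.T)


def cluster_basins(
    fel: FELGrid,
    projection: Projection,
    weights,
    cfe_cutoff: float = 1.0,
    smooth_sigma: float = 1.0,
) -> list:
    """Assign snapshots to FEL basins and rank clusters by CFE.

    Returns the clusters with CFE ≤ ``cfe_cutoff`` (use ``np.inf`` for
    all), ordered by increasing CFE, each with its representative
    structure.  Snapshots inherit the basin of their grid cell; the basin
    descent runs on a ``smooth_sigma``-cell smoothed surface (0 disables).
    """
    weights = np.asarray(weights, dtype=float)
    if not isinstance(projection, Projection):
        raise InputError("projection must be a Projection")
    pc = projection.pc_coords
    descent_fel = _smoothed_fel(fel, smooth_sigma) if smooth_sigma > 0 else fel
    roots = _basin_map(descent_fel)
    cells = [fel.cell_of(p) for p in pc]
    by_root: dict = {}
    for idx, cell in enumerate(cells):
        root = roots.get(cell)
        if root is None:
            # point fell in a cell emptied by histogram binning edge effects;
            # attach to the nearest occupied cell of its own location
            root = _nearest_root(fel, roots, cell)
        by_root.setdefault(root, []).append(idx)
    pops = {root: float(weights[idx].sum()) for root, idx in by_root.items()}
    pop_max = max(pops.values())
    basin_cells: dict = {}
    for cell, root in roots.items():
        basin_cells.setdefault(root, []).append(cell)
    order = sorted(by_root, key=lambda r: (-pops[r], r))
    clusters = []
    for root in order:
        cfe = -KB * fel.T * np.log(pops[root] / pop_max) + 0.0  # avoid -0.0
        if cfe > cfe_cutoff:
            continue
        members = np.asarray(by_root[root], dtype=int)
        rep = _representative(fel, root, members, cells, weights)
        clusters.append(
            Cluster(
                member_indices=members,
                population=pops[root],
                cfe=float(cfe),
                representative_index=rep,
                representative=None,
                root_cell=root,
                basin_cells=basin_cells[root],
            )
        )
    return clusters


def _nearest_root(fel, roots, cell):
    best = None
    best_d = np.inf
    for c, r in roots.items():
        d = (c[0] - cell[0]) ** 2 + (c[1] - cell[1]) ** 2
        if d < best_d:
            best_d = d
            best = r
    return best


def _representative(fel, root, members, cells, weights):
    in_root_cell = [i for i in members if cells[i] == root]
    pool = in_root_cell if in_root_cell else list(members)
    # max weight, ties by lowest snapshot index
    best = min(pool, key=lambda i: (-weights[i], i))
    return int(best)


def representative_structure(cluster: Cluster, projection: Projection, weights):
    """Representative snapshot index of a cluster.

    The snapshot in the basin's minimum-F cell with maximal weight; ties go
    to the lowest snapshot index.  (Clusters from :func:`cluster_basins`
    already carry this as ``representative_index``.)
    """
    if cluster.member_indices.size == 0:
        raise InputError("cluster has no members")
    return cluster.representative_index


def attach_representatives(clusters, ensemble):
    """Fill each cluster's ``representative`` with the actual snapshot."""
    snaps = ensemble.snapshots if isinstance(ensemble, WeightedEnsemble) else ensemble
    for c in clusters:
        c.representative = snaps[c.representative_index]
    return clusters
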
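"""Superposition, weighted PCA, FEL construction and basin clustering."""

import numpy as np
import pytest

from mcdock.constants import KB
from mcdock.engine import Snapshot
from mcdock.errors import InputError
from mcdock.fel import (
    Projection,
    attach_representatives,
    build_fel,
    cluster_basins,
    kabsch,
    pca_project,
    superpose_ensemble,
    superpose_snapshot,
)

from helpers_oracles import quaternion_rmsd, rmsd


def _rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def test_superpose_recovers_rigid_transform(rng):
    ref = Snapshot(rng.normal(size=(12, 3)), 0.0)
    rot = _rotation(rng)
    moved = Snapshot(ref.coords @ rot.T + np.array([3.0, -1.0, 2.0]), 0.0)
    fitted = superpose_snapshot(moved, ref, np.arange(12))
    assert rmsd(fitted.coords, ref.coords) <= 1e-8


def test_superpose_identity_unchanged(rng):
    ref = Snapshot(rng.normal(size=(8, 3)), 0.0)
    fitted = superpose_snapshot(ref, ref, np.arange(8))
    assert fitted.coords == pytest.approx(ref.coords, abs=1e-12)


def test_kabsch_matches_quaternion_oracle(rng):
    """SVD fit agrees with Horn's closed-form quaternion method."""
    for _ in range(30):
        a = rng.normal(size=(10, 3))
        b = a @ _rotation(rng).T + rng.normal(size=3) + 0.1 * rng.normal(size=(10, 3))
        rot, t = kabsch(a, b)
        assert abs(rmsd(a @ rot.T + t, b) - quaternion_rmsd(a, b)) <= 1e-6


def test_collinear_selection_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(InputError):
        kabsch(line, line)


def test_pca_line_explains_all_variance(rng):
    t = rng.normal(size=200)
    coords = np.zeros((200, 1, 3))
    coords[:, 0, 0] = t
    coords[:, 0, 1] = 2.0 * t
    snaps = [Snapshot(c, 0.0) for c in coords]
    proj = pca_project(snaps)
    assert proj.explained_variance[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_isotropic_split(rng):
    coords = np.zeros((4000, 1, 3))
    coords[:, 0, :2] = rng.normal(size=(4000, 2))
    proj = pca_project([Snapshot(c, 0.0) for c in coords])
    assert proj.explained_variance[0] == pytest.approx(0.5, abs=0.05)
    assert proj.explained_variance[1] == pytest.approx(0.5, abs=0.05)


def test_pca_projects_mean_to_origin(rng):
    coords = rng.normal(size=(50, 4, 3))
    snaps = [Snapshot(c, 0.0) for c in coords]
    w = rng.uniform(0.5, 1.5, size=50)
    w /= w.sum()
    proj = pca_project(snaps, weights=w)
    mean_coords = np.einsum("n,nij->ij", w, coords)
    assert proj.project(mean_coords) == pytest.approx(np.zeros(2), abs=1e-9)
    assert proj.axes @ proj.axes.T == pytest.approx(np.eye(2), abs=1e-10)


def test_pca_external_projection_invariant_to_reordering(rng):
    coords = rng.normal(size=(300, 2, 3))
    snaps = [Snapshot(c, 0.0) for c in coords]
    probe = rng.normal(size=(2, 3))
    p1 = pca_project(snaps).project(probe)
    order = rng.permutation(300)
    p2 = pca_project([snaps[i] for i in order]).project(probe)
    assert p1 == pytest.approx(p2, abs=1e-9)


def test_pca_zero_weight_rejected(rng):
    snaps = [Snapshot(rng.normal(size=(2, 3)), 0.0) for _ in range(5)]
    with pytest.raises(InputError):
        pca_project(snaps, weights=np.zeros(5))


# ---------------------------------------------------------------------------
# FEL grid
# ---------------------------------------------------------------------------


def _projection_from_points(pts):
    pts = np.asarray(pts, dtype=float)
    return Projection(
        pc_coords=pts,
        explained_variance=np.array([0.5, 0.5]),
        mean_vector=np.zeros(2),
        axes=np.eye(2),
        feature_selection=np.array([0]),
    )


def test_fel_uniform_density_is_zero():
    pts = np.array([[0.1, 0.1], [0.9, 0.9], [0.1, 0.9], [0.9, 0.1]])
    proj = _projection_from_points(pts)
    fel = build_fel(proj, np.full(4, 0.25), T=300.0, grid=(2, 2), padding=0.0)
    assert fel.free_energy[np.isfinite(fel.free_energy)] == pytest.approx(0.0)


def test_fel_two_to_one_density_ratio():
    """ΔF between cells with 2:1 density is kB·300·ln 2 = 0.413 kcal/mol."""
    pts = np.array([[0.25, 0.5]] * 2 + [[0.75, 0.5]])
    proj = _projection_from_points(pts)
    fel = build_fel(proj, np.full(3, 1 / 3), T=300.0, grid=(2, 1), padding=0.0)
    finite = np.sort(fel.free_energy[np.isfinite(fel.free_energy)])
    assert finite[0] == 0.0
    assert finite[1] == pytest.approx(KB * 300.0 * np.log(2.0), abs=1e-12)


def test_fel_min_is_zero(planted_small):
    proj = pca_project(planted_small.snapshots, feature_selection=np.array([0]))
    fel = build_fel(proj, planted_small.weights, T=300.0)
    assert np.nanmin(fel.free_energy[np.isfinite(fel.free_energy)]) == 0.0


# ---------------------------------------------------------------------------
# Basin clustering
# ---------------------------------------------------------------------------


def test_cluster_recovery_on_planted_ensemble(planted_small):
    """Three planted clusters (0.5/0.3/0.2) → three basins with the CFEs
    −kBT·ln(p/p_max) and representatives carrying the planted labels."""
    proj = pca_project(planted_small.snapshots, feature_selection=np.array([0]))
    fel = build_fel(proj, planted_small.weights, T=300.0)
    clusters = cluster_basins(fel, proj, planted_small.weights, cfe_cutoff=1.0)
    assert len(clusters) == 3
    expected = [0.0,
                -KB * 300.0 * np.log(0.3 / 0.5),
                -KB * 300.0 * np.log(0.2 / 0.5)]
    for c, ref in zip(clusters, expected):
        assert abs(c.cfe - ref) < 0.1
    # representatives carry the planted cluster labels in population order
    label_order = [planted_small.labels[c.representative_index] for c in clusters]
    assert label_order == [0, 1, 2]
    # members are (almost all) the planted members
    for c, planted_idx in zip(clusters, range(3)):
        frac = np.mean(planted_small.labels[c.member_indices] == planted_idx)
        assert frac > 0.99


def test_cluster_populations_sum_to_one(planted_small):
    proj = pca_project(planted_small.snapshots, feature_selection=np.array([0]))
    fel = build_fel(proj, planted_small.weights, T=300.0)
    clusters = cluster_basins(fel, proj, planted_small.weights, cfe_cutoff=np.inf)
    assert sum(c.population for c in clusters) == pytest.approx(1.0, abs=1e-9)
    pops = [c.population for c in clusters]
    assert pops == sorted(pops, reverse=True)
    assert clusters[0].cfe == 0.0


def test_single_gaussian_single_cluster(rng):
    pts = rng.normal(size=(5000, 2))
    proj = _projection_from_points(pts)
    w = np.full(5000, 1 / 5000)
    fel = build_fel(proj, w, T=300.0, grid=(25, 25))
    clusters = cluster_basins(fel, proj, w, cfe_cutoff=1.0)
    assert len(clusters) == 1
    assert clusters[0].cfe == 0.0


def test_equal_twin_gaussians_near_zero_cfe(rng):
    pts = np.vstack([
        rng.normal(size=(20_000, 2)) + [-8.0, 0.0],
        rng.normal(size=(20_000, 2)) + [8.0, 0.0],
    ])
    proj = _projection_from_points(pts)
    w = np.full(40_000, 1 / 40_000)
    fel = build_fel(proj, w, T=300.0, grid=(60, 60))
    clusters = cluster_basins(fel, proj, w, cfe_cutoff=1.0)
    assert abs(clusters[1].cfe) < 0.05


def test_representative_tie_breaks_to_lower_index():
    pts = np.array([[0.5, 0.5], [0.5, 0.5], [0.6, 0.5]])
    proj = _projection_from_points(pts)
    w = np.full(3, 1 / 3)
    fel = build_fel(proj, w, T=300.0, grid=(1, 1), padding=0.1)
    clusters = cluster_basins(fel, proj, w, cfe_cutoff=np.inf)
    assert clusters[0].representative_index == 0


def test_attach_representatives(planted_small):
    proj = pca_project(planted_small.snapshots, feature_selection=np.array([0]))
    fel = build_fel(proj, planted_small.weights, T=300.0)
    clusters = cluster_basins(fel, proj, planted_small.weights, cfe_cutoff=1.0)
    attach_representatives(clusters, planted_small.snapshots)
    for c in clusters:
        assert c.representative is planted_small.snapshots[c.representative_index]
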
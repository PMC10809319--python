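"""Weighted RMSF, DCC, ligand density grids, ion counts."""

import numpy as np
import pytest

from mcdock.engine import Snapshot
from mcdock.errors import InputError
from mcdock.observables import dcc, density_grid, ion_contact_counts, weighted_rmsf
from mcdock.reweighting import WeightedEnsemble


def _ensemble(coords_list, weights=None, T=300.0):
    snaps = [Snapshot(np.asarray(c, dtype=float), 0.0, 0, i)
             for i, c in enumerate(coords_list)]
    n = len(snaps)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    return WeightedEnsemble(snaps, np.asarray(weights, dtype=float), T)


def test_rmsf_frozen_ensemble_is_zero(rng):
    frame = rng.normal(size=(5, 3))
    we = _ensemble([frame] * 20)
    assert weighted_rmsf(we) == pytest.approx(np.zeros(5), abs=1e-12)


def test_rmsf_isotropic_jitter(rng):
    """σ = 0.5 Å isotropic jitter gives RMSF σ√3 ≈ 0.866 Å."""
    base = np.zeros((2, 3))
    frames = []
    for _ in range(20_000):
        f = base.copy()
        f[1] += 0.5 * rng.standard_normal(3)
        frames.append(f)
    we = _ensemble(frames)
    out = weighted_rmsf(we)
    assert out[0] == pytest.approx(0.0, abs=1e-12)
    assert out[1] == pytest.approx(0.5 * np.sqrt(3.0), rel=0.03)


def test_rmsf_weight_concentration_limit(rng):
    frames = [rng.normal(size=(3, 3)) for _ in range(10)]
    w = np.zeros(10)
    w[4] = 1.0
    we = _ensemble(frames, w)
    assert weighted_rmsf(we) == pytest.approx(np.zeros(3), abs=1e-12)


def test_rmsf_single_snapshot_warns(rng):
    we = _ensemble([rng.normal(size=(3, 3))])
    with pytest.warns(RuntimeWarning):
        out = weighted_rmsf(we)
    assert out == pytest.approx(np.zeros(3))


def test_rmsf_and_dcc_invariant_to_reordering_and_duplication(rng):
    frames = [rng.normal(size=(4, 3)) for _ in range(40)]
    we = _ensemble(frames)
    r1, c1 = weighted_rmsf(we), dcc(we)
    order = rng.permutation(40)
    we2 = _ensemble([frames[i] for i in order])
    assert weighted_rmsf(we2) == pytest.approx(r1)
    assert dcc(we2) == pytest.approx(c1)
    # weight-preserving duplication: each frame twice at half weight
    dup = _ensemble([f for f in frames for _ in range(2)])
    assert weighted_rmsf(dup) == pytest.approx(r1)
    assert dcc(dup) == pytest.approx(c1)


def test_dcc_diagonal_and_anticorrelation(rng):
    frames = []
    for _ in range(500):
        d = rng.standard_normal(3)
        frames.append(np.vstack([d, -d]))
    c = dcc(_ensemble(frames))
    assert c[0, 0] == 1.0 and c[1, 1] == 1.0
    assert c[0, 1] == pytest.approx(-1.0, abs=1e-9)


def test_dcc_independent_jitter_bounded(rng):
    n = 4000
    frames = [rng.standard_normal((3, 3)) for _ in range(n)]
    c = dcc(_ensemble(frames))
    off = c[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(off) <= 3.0 / np.sqrt(n))
    assert np.all(np.abs(c) <= 1.0)


def test_dcc_zero_variance_flagged(rng):
    frames = []
    for _ in range(50):
        f = np.zeros((2, 3))
        f[1] = rng.standard_normal(3)
        frames.append(f)
    with pytest.warns(RuntimeWarning, match="zero-variance"):
        c = dcc(_ensemble(frames))
    assert np.isnan(c[0, 1])
    assert c[0, 0] == 1.0


def test_density_point_mass_single_voxel():
    frame = np.zeros((2, 3))
    frame[1] = (5.2, 5.2, 5.2)
    grid = density_grid(_ensemble([frame] * 10), [1], voxel=1.0)
    assert np.count_nonzero(grid.occupancy) == 1
    assert grid.occupancy.max() == pytest.approx(1.0)


def test_density_two_sites_mass_ratio():
    a = np.zeros((1, 3))
    b = np.full((1, 3), 10.0)
    frames = [a] * 7 + [b] * 3
    grid = density_grid(_ensemble(frames), [0], voxel=1.0)
    vals = np.sort(grid.occupancy[grid.occupancy > 0])
    assert vals == pytest.approx([0.3, 0.7])


def test_density_level_sets_nested(rng):
    frames = [rng.normal(scale=3.0, size=(1, 3)) for _ in range(2000)]
    grid = density_grid(_ensemble(frames), [0], voxel=1.0)
    high, med, low = (grid.level_mask(level) for level in grid.levels)
    assert np.all(high <= med)
    assert np.all(med <= low)
    with pytest.raises(InputError):
        density_grid(_ensemble(frames), [0], voxel=0.0)


def test_ion_count_boundary():
    def frame(dist):
        f = np.zeros((2, 3))
        f[1, 0] = dist
        return f

    inside = _ensemble([frame(4.9)] * 5)
    outside = _ensemble([frame(5.1)] * 5)
    assert ion_contact_counts(inside, {"Mg": [1]}, [0])["Mg"] == pytest.approx(1.0)
    assert ion_contact_counts(outside, {"Mg": [1]}, [0])["Mg"] == 0.0


def test_ion_count_binomial_mean(rng):
    n_ions, p = 20, 0.6
    frames = []
    for _ in range(3000):
        f = np.zeros((1 + n_ions, 3))
        for k in range(n_ions):
            bound = rng.random() < p
            f[1 + k, 0] = 3.0 if bound else 30.0
        frames.append(f)
    we = _ensemble(frames)
    mean = ion_contact_counts(we, {"K": np.arange(1, 1 + n_ions)}, [0])["K"]
    se = np.sqrt(n_ions * p * (1 - p) / 3000)
    assert abs(mean - p * n_ions) < 3.0 * se


def test_ion_unknown_selection_rejected(rng):
    we = _ensemble([np.zeros((3, 3))] * 2)
    with pytest.raises(InputError):
        ion_contact_counts(we, {"Mg": [7]}, [0])
    with pytest.raises(InputError):
        ion_contact_counts(we, {"Mg": [1]}, [0], cutoff=-1.0)


def test_pocket_bound_subensemble_quenches_gate_rmsf(planted_small):
    """Ligand binding reduces gate fluctuations: the pocket-bound
    subensemble has lower mean gate-bead RMSF than the full ensemble."""
    we = WeightedEnsemble(planted_small.snapshots, planted_small.weights, 300.0)
    gate = planted_small.roles["gate"]
    full = weighted_rmsf(we, gate).mean()
    pocket_cluster = planted_small.cluster_labels.index("pocket")
    idx = np.nonzero(planted_small.labels == pocket_cluster)[0]
    bound = weighted_rmsf(we.subensemble(idx), gate).mean()
    assert bound < full
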
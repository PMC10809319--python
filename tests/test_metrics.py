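"""Contacts, R-values, ligand RMSD, SASA and RASA."""

import numpy as np
import pytest

from mcdock.engine import Snapshot
from mcdock.errors import InputError, ResolutionError, UndefinedStatisticError
from mcdock.metrics import (
    ContactSet,
    contact_set,
    ligand_rmsd,
    r_value,
    r_value_trace,
    rasa,
    sasa,
)

from helpers_oracles import brute_force_contacts, quaternion_fit, rmsd


def _pair_system(distance):
    coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    return Snapshot(coords, 0.0)


def test_contact_boundary_inclusive():
    assert len(contact_set(_pair_system(4.49), [0], [1], cutoff=4.5)) == 1
    assert len(contact_set(_pair_system(4.50), [0], [1], cutoff=4.5)) == 1
    assert len(contact_set(_pair_system(4.51), [0], [1], cutoff=4.5)) == 0


def test_contact_set_matches_brute_force(rng):
    coords = rng.uniform(-6, 6, size=(20, 3))
    rec = np.arange(12)
    lig = np.arange(12, 20)
    residues = np.repeat(np.arange(4), 3)  # 4 residues of 3 atoms
    cs = contact_set(Snapshot(coords, 0.0), rec, lig, cutoff=4.5,
                     receptor_residue_ids=residues)
    oracle = brute_force_contacts(coords, rec, lig, 4.5,
                                  residue_ids=residues)
    assert cs.pairs == oracle


def test_contact_selections_validated():
    with pytest.raises(InputError):
        contact_set(_pair_system(1.0), [], [1])
    with pytest.raises(InputError):
        contact_set(_pair_system(1.0), [0, 1], [1])


def test_r_value_examples():
    ref = ContactSet(frozenset({(1, 9), (2, 9)}), 4.5)
    assert r_value(ref, ref) == 1.0
    assert r_value(ContactSet(frozenset(), 4.5), ref) == 0.0
    big_ref = ContactSet(frozenset((i, 9) for i in range(8)), 4.5)
    obs = ContactSet(frozenset((i, 9) for i in range(6)), 4.5)
    assert r_value(obs, big_ref) == pytest.approx(0.75)
    with pytest.raises(UndefinedStatisticError):
        r_value(obs, ContactSet(frozenset(), 4.5))


def test_r_value_monotone_under_contact_removal(rng):
    ref_pairs = frozenset((i, 100) for i in range(10))
    ref = ContactSet(ref_pairs, 4.5)
    pairs = set(ref_pairs)
    last = 1.0
    while pairs:
        pairs.remove(next(iter(pairs)))
        r = r_value(ContactSet(frozenset(pairs), 4.5), ref)
        assert r <= last
        last = r


def test_r_value_trace_frozen_and_alternating():
    ref_snap = _pair_system(3.0)
    ref = contact_set(ref_snap, [0], [1], cutoff=4.5)
    frozen = [ref_snap] * 10
    mean, sd, _ = r_value_trace(frozen, ref, [0], [1], window=5)
    assert (mean, sd) == (1.0, 0.0)
    alternating = [_pair_system(3.0), _pair_system(9.0)] * 5
    mean, sd, _ = r_value_trace(alternating, ref, [0], [1], window=10)
    assert mean == pytest.approx(0.5)
    assert sd == pytest.approx(0.5)
    with pytest.raises(InputError):
        r_value_trace(frozen, ref, [0], [1], window=11)


def test_ligand_rmsd_identical_and_translated(rng):
    receptor = rng.normal(size=(8, 3))
    ligand = rng.normal(size=(3, 3)) + [5.0, 0.0, 0.0]
    ref = Snapshot(np.vstack([receptor, ligand]), 0.0)
    assert ligand_rmsd(ref, ref, np.arange(8), np.arange(8, 11)) == pytest.approx(0.0)
    moved = ref.coords.copy()
    moved[8:] += [3.0, 0.0, 0.0]
    assert ligand_rmsd(Snapshot(moved, 0.0), ref, np.arange(8),
                       np.arange(8, 11)) == pytest.approx(3.0, abs=1e-9)


def test_ligand_rmsd_matches_quaternion_oracle(rng):
    receptor = rng.normal(size=(10, 3))
    ligand = rng.normal(size=(4, 3)) + [6.0, 0.0, 0.0]
    ref = np.vstack([receptor, ligand])
    perturbed = ref + 0.3 * rng.normal(size=ref.shape)
    got = ligand_rmsd(Snapshot(perturbed, 0.0), Snapshot(ref, 0.0),
                      np.arange(10), np.arange(10, 14))
    # oracle: quaternion fit on the receptor, applied to all, ligand RMSD
    rot, t = quaternion_fit(perturbed[:10], ref[:10])
    oracle = rmsd((perturbed @ rot.T + t)[10:], ref[10:])
    assert abs(got - oracle) <= 1e-6


def test_rmsd_invariant_under_global_rigid_motion(rng):
    from test_fel import _rotation

    receptor = rng.normal(size=(10, 3))
    ligand = rng.normal(size=(4, 3)) + [6.0, 0.0, 0.0]
    ref = np.vstack([receptor, ligand])
    snap = ref + 0.3 * rng.normal(size=ref.shape)
    base = ligand_rmsd(Snapshot(snap, 0.0), Snapshot(ref, 0.0),
                       np.arange(10), np.arange(10, 14))
    moved = snap @ _rotation(rng).T + [10.0, -4.0, 2.0]
    again = ligand_rmsd(Snapshot(moved, 0.0), Snapshot(ref, 0.0),
                        np.arange(10), np.arange(10, 14))
    assert again == pytest.approx(base, rel=1e-6)


# ---------------------------------------------------------------------------
# SASA / RASA
# ---------------------------------------------------------------------------


def _cage(radius=2.0, n=12):
    """Icosahedral cage directions that fully occlude a central atom."""
    phi = (1 + np.sqrt(5)) / 2
    verts = []
    for a in (-1, 1):
        for b in (-phi, phi):
            verts += [(0, a, b), (a, b, 0), (b, 0, a)]
    verts = np.array(verts, dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    return radius * verts


def test_isolated_atom_area_closed_form():
    res = sasa(np.zeros((1, 3)), radii=np.array([1.7]), probe=1.4, n_points=960)
    exact = 4.0 * np.pi * 3.1**2  # 120.76 Å²
    assert res.areas[0] == pytest.approx(exact, rel=0.02)


def test_fully_caged_atom_has_zero_area():
    coords = np.vstack([np.zeros(3), _cage()])
    radii = np.full(13, 1.7)
    res = sasa(coords, radii)
    assert res.areas[0] == 0.0


def test_distant_atoms_additive():
    coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
    res = sasa(coords, np.array([1.7, 1.2]))
    iso0 = sasa(coords[:1], np.array([1.7])).areas[0]
    iso1 = sasa(coords[1:], np.array([1.2])).areas[0]
    assert res.areas == pytest.approx([iso0, iso1])


def test_sasa_resolution_floor():
    with pytest.raises(ResolutionError):
        sasa(np.zeros((1, 3)), np.array([1.7]), n_points=16)
    with pytest.raises(InputError):
        sasa(np.zeros((1, 3)), np.array([-1.0]))


def test_sasa_rigid_motion_invariance(rng):
    """Translation leaves the lattice SASA bit-identical; rotation moves
    occluders across lattice points, so agreement is at lattice resolution
    (~1/n_points per atom)."""
    from test_fel import _rotation

    coords = rng.normal(size=(6, 3)) * 2.0
    base = sasa(coords).areas
    shifted = sasa(coords + [4.0, 5.0, -6.0]).areas
    assert np.array_equal(shifted, base)
    rotated = sasa(coords @ _rotation(rng).T).areas
    assert rotated.sum() == pytest.approx(base.sum(), rel=5e-3)


def test_rasa_isolated_and_encapsulated():
    lone = np.array([[0.0, 0.0, 0.0], [60.0, 0.0, 0.0]])
    assert rasa(Snapshot(lone, 0.0), [1]) == pytest.approx(1.0)
    caged = np.vstack([np.zeros(3), _cage()])
    assert rasa(Snapshot(caged, 0.0), [0]) == 0.0
    with pytest.raises(InputError):
        rasa(Snapshot(lone, 0.0), [])


def test_rasa_half_occluded_matches_high_resolution():
    """Default lattice agrees with a 10⁴-point computation within 2%."""
    plane = np.array([[x, y, -3.0] for x in (-2.0, 0.0, 2.0) for y in (-2.0, 0.0, 2.0)])
    coords = np.vstack([np.zeros(3), plane])
    snap = Snapshot(coords, 0.0)
    lo = rasa(snap, [0], n_points=960)
    hi = rasa(snap, [0], n_points=10_000)
    assert lo == pytest.approx(hi, rel=0.02)
    assert 0.3 < hi < 0.95  # genuinely partially occluded


def test_rasa_separates_buried_from_surface_pose(gated_system):
    """The buried pocket pose has much lower RASA than a surface pose."""
    lig = gated_system.roles["ligand"]
    bound = Snapshot(gated_system.reference_coords.copy(), 0.0)
    surface = Snapshot(gated_system.reference_coords.copy(), 0.0)
    surface.coords = surface.coords.copy()
    surface.coords[0] = (0.0, 7.0, 0.0)
    assert rasa(bound, lig) < rasa(surface, lig)
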
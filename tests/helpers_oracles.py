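"""Independent oracle implementations used only by the tests.

These deliberately avoid the package's own code paths: the quaternion
superposition is Horn's closed-form method (the package uses the SVD
construction), contact sets are brute-force O(N²) scans, and free energies
come from 1D quadrature.
"""

import numpy as np
from scipy.integrate import quad

from mcdock.constants import KB


def quaternion_fit(mobile, target):
    """Horn's quaternion method for the optimal rigid superposition.

    Returns (R, t) with fitted = mobile @ R.T + t.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    evals, evecs = np.linalg.eigh(k)
    q = evecs[:, np.argmax(evals)]
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = tc - rot @ mc
    return rot, t


def rmsd(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def quaternion_rmsd(mobile, target):
    rot, t = quaternion_fit(mobile, target)
    return rmsd(mobile @ rot.T + t, target)


def brute_force_contacts(coords, receptor_idx, ligand_idx, cutoff,
                         residue_ids=None):
    """O(N²) all-pairs contact scan (residue granularity on the receptor)."""
    receptor_idx = list(receptor_idx)
    ligand_idx = list(ligand_idx)
    if residue_ids is None:
        residue_ids = receptor_idx
    pairs = set()
    for ri, res in zip(receptor_idx, residue_ids):
        for lj in ligand_idx:
            d = np.linalg.norm(coords[ri] - coords[lj])
            if d <= cutoff:
                pairs.add((res, lj))
    return frozenset(pairs)


def double_well_quadrature(barrier, well_sep, tilt, T, split=0.0, lim=12.0):
    """(p_left, p_right, ΔF) of the tilted quartic from 1D quadrature."""

    def u(x):
        return barrier * (x * x / (well_sep**2) - 1.0) ** 2 + tilt * x

    beta = 1.0 / (KB * T)
    za = quad(lambda x: np.exp(-beta * u(x)), -lim, split, limit=200)[0]
    zb = quad(lambda x: np.exp(-beta * u(x)), split, lim, limit=200)[0]
    z = za + zb
    return za / z, zb / z, -KB * T * np.log(zb / za)


def trajectory_weighted_means(ensemble, bias, T, values):
    """Per-trajectory reweighted means (for an honest standard error)."""
    from mcdock.reweighting import canonical_weights

    traj_ids = sorted({s.traj_id for s in ensemble})
    values = np.asarray(values, dtype=float)
    means = []
    for tid in traj_ids:
        idx = [i for i, s in enumerate(ensemble) if s.traj_id == tid]
        sub = [ensemble[i] for i in idx]
        we = canonical_weights(sub, bias, T)
        means.append(float(np.sum(we.weights * values[idx])))
    return np.asarray(means)
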
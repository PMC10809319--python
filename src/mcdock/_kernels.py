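"""Numba kernels for the toy samplers.

The energy functions mirror :mod:`mcdock.systems` exactly (tested for
agreement); the Metropolis and Langevin loops live here because a million
sequential Monte Carlo steps are not expressible as vectorised numpy.

Bias functions arrive tabulated as piecewise polynomials: ``knots`` (m,),
``coeffs`` (m−1, 4) with ascending powers in t = E − knot[j], plus the
boundary values/slopes of the canonical extrapolation tails.
"""

import math

import numpy as np
from numba import njit

_MB_A = (-200.0, -100.0, -170.0, 15.0)
_MB_a = (-1.0, -1.0, -6.5, 0.7)
_MB_b = (0.0, 0.0, 11.0, 0.6)
_MB_c = (-10.0, -10.0, -6.5, 0.7)
_MB_x0 = (1.0, 0.0, -0.5, -1.0)
_MB_y0 = (0.0, 0.5, 1.5, 1.0)


@njit(cache=True)
def base_energy(pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k, coords):
    n, dim = coords.shape
    e = 0.0
    if pot_id == 0:  # harmonic
        s = 0.0
        for i in range(n):
            for d in range(dim):
                s += coords[i, d] * coords[i, d]
        e = 0.5 * pp[0] * s
    elif pot_id == 1:  # double well
        x = coords[0, 0]
        u = x * x / (pp[1] * pp[1]) - 1.0
        e = pp[0] * u * u + pp[2] * x
    elif pot_id == 2:  # mueller_like_2d
        x = coords[0, 0]
        y = coords[0, 1]
        s = 0.0
        for t in range(4):
            dx = x - _MB_x0[t]
            dy = y - _MB_y0[t]
            s += _MB_A[t] * math.exp(
                _MB_a[t] * dx * dx + _MB_b[t] * dx * dy + _MB_c[t] * dy * dy
            )
        e = pp[0] * s
    else:  # gated_pocket
        dmid = pp[0]
        hw = pp[1]
        hg = pp[2]
        tilt = pp[3]
        dcl = pp[4]
        rep = pp[5]
        sr = pp[6]
        kc = pp[7]
        rc = pp[8]
        for s_i in range(site_pos.shape[0]):
            d2 = 0.0
            for d in range(dim):
                dd = coords[0, d] - site_pos[s_i, d]
                d2 += dd * dd
            sg = site_sigma[s_i]
            e -= site_depth[s_i] * math.exp(-d2 / (2.0 * sg * sg))
        d2 = 0.0
        for d in range(dim):
            dd = coords[1, d] - coords[2, d]
            d2 += dd * dd
        dg = math.sqrt(d2)
        u = ((dg - dmid) / hw) ** 2 - 1.0
        e += hg * u * u + tilt * (dg - dcl)
        for i in range(1, n):
            d2 = 0.0
            for d in range(dim):
                dd = coords[0, d] - coords[i, d]
                d2 += dd * dd
            e += rep * math.exp(-d2 / (2.0 * sr * sr))
        r2 = 0.0
        for d in range(dim):
            r2 += coords[0, d] * coords[0, d]
        r = math.sqrt(r2)
        if r > rc:
            e += 0.5 * kc * (r - rc) * (r - rc)
    for i in range(n):
        if tether_k[i] > 0.0:
            d2 = 0.0
            for d in range(dim):
                dd = coords[i, d] - tether_ref[i, d]
                d2 += dd * dd
            e += 0.5 * tether_k[i] * d2
    return e


@njit(cache=True)
def restraint_energy(coords, rest_ij, rest_par):
    e = 0.0
    for r in range(rest_ij.shape[0]):
        i = rest_ij[r, 0]
        j = rest_ij[r, 1]
        d2 = 0.0
        for d in range(coords.shape[1]):
            dd = coords[i, d] - coords[j, d]
            d2 += dd * dd
        dist = math.sqrt(d2)
        dd0 = dist - rest_par[r, 0]
        e += 0.5 * rest_par[r, 1] * dd0 * dd0
    return e


@njit(cache=True)
def total_energy(
    pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
    rest_ij, rest_par, use_restraints, coords,
):
    e = base_energy(pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k, coords)
    if use_restraints and rest_ij.shape[0] > 0:
        e += restraint_energy(coords, rest_ij, rest_par)
    return e


@njit(cache=True)
def bias_value(E, knots, coeffs, v_first, v_last, slope_lo, slope_hi):
    m = knots.shape[0]
    if E <= knots[0]:
        return v_first + slope_lo * (E - knots[0])
    if E >= knots[m - 1]:
        return v_last + slope_hi * (E - knots[m - 1])
    j = np.searchsorted(knots, E) - 1
    if j < 0:
        j = 0
    t = E - knots[j]
    c0 = coeffs[j, 0]
    c1 = coeffs[j, 1]
    c2 = coeffs[j, 2]
    c3 = coeffs[j, 3]
    return ((c3 * t + c2) * t + c1) * t + c0


@njit(cache=True)
def bias_slope(E, knots, coeffs, slope_lo, slope_hi):
    m = knots.shape[0]
    if E <= knots[0]:
        return slope_lo
    if E >= knots[m - 1]:
        return slope_hi
    j = np.searchsorted(knots, E) - 1
    if j < 0:
        j = 0
    t = E - knots[j]
    return (3.0 * coeffs[j, 3] * t + 2.0 * coeffs[j, 2]) * t + coeffs[j, 1]


@njit(cache=True)
def mc_run(
    coords0, pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
    rest_ij, rest_par, use_restraints,
    knots, coeffs, v_first, v_last, slope_lo, slope_hi, use_bias,
    beta, step_width, n_steps, stride, seed, e_max,
):
    """Single-particle-move Metropolis sampling of exp(−β·(E + b(E))).

    Returns (frames, energies, n_recorded, n_accepted, error_flag); the
    error flag is 1 when the energy exceeded ``e_max`` (divergence).
    """
    np.random.seed(seed)
    n, dim = coords0.shape
    coords = coords0.copy()
    e = total_energy(
        pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
        rest_ij, rest_par, use_restraints, coords,
    )
    n_out = n_steps // stride
    out_c = np.empty((n_out, n, dim))
    out_e = np.empty(n_out)
    old = np.empty(dim)
    n_acc = 0
    k_out = 0
    for step in range(1, n_steps + 1):
        p = np.random.randint(0, n)
        for d in range(dim):
            old[d] = coords[p, d]
            coords[p, d] = old[d] + step_width * np.random.normal()
        e_new = total_energy(
            pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
            rest_ij, rest_par, use_restraints, coords,
        )
        if use_bias:
            du = (
                e_new
                + bias_value(e_new, knots, coeffs, v_first, v_last, slope_lo, slope_hi)
                - e
                - bias_value(e, knots, coeffs, v_first, v_last, slope_lo, slope_hi)
            )
        else:
            du = e_new - e
        if du <= 0.0 or np.random.random() < math.exp(-beta * du):
            e = e_new
            n_acc += 1
        else:
            for d in range(dim):
                coords[p, d] = old[d]
        if e > e_max:
            return out_c, out_e, k_out, n_acc, 1
        if step % stride == 0:
            for i in range(n):
                for d in range(dim):
                    out_c[k_out, i, d] = coords[i, d]
            out_e[k_out] = e
            k_out += 1
    return out_c, out_e, k_out, n_acc, 0


@njit(cache=True)
def numeric_forces(
    pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
    rest_ij, rest_par, use_restraints, coords, h, forces,
):
    n, dim = coords.shape
    for i in range(n):
        for d in range(dim):
            x0 = coords[i, d]
            coords[i, d] = x0 + h
            ep = total_energy(
                pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
                rest_ij, rest_par, use_restraints, coords,
            )
            coords[i, d] = x0 - h
            em = total_energy(
                pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
                rest_ij, rest_par, use_restraints, coords,
            )
            coords[i, d] = x0
            forces[i, d] = -(ep - em) / (2.0 * h)


@njit(cache=True)
def langevin_run(
    coords0, pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
    rest_ij, rest_par, use_restraints,
    knots, coeffs, v_first, v_last, slope_lo, slope_hi, use_bias,
    masses, kbt, dt, friction, conv, n_steps, stride, seed, e_max,
):
    """BAOAB Langevin sampling with central-difference forces.

    Under the bias the force is scaled by (1 + b'(E)) — the gradient of the
    effective potential E + b(E).  ``conv`` converts kcal/mol to
    amu·Å²/ps².  Returns the same tuple as :func:`mc_run`.
    """
    np.random.seed(seed)
    n, dim = coords0.shape
    coords = coords0.copy()
    vel = np.empty((n, dim))
    for i in range(n):
        sv = math.sqrt(kbt * conv / masses[i])
        for d in range(dim):
            vel[i, d] = sv * np.random.normal()
    forces = np.empty((n, dim))
    h = 1e-4
    numeric_forces(
        pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
        rest_ij, rest_par, use_restraints, coords, h, forces,
    )
    e = total_energy(
        pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
        rest_ij, rest_par, use_restraints, coords,
    )
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    n_out = n_steps // stride
    out_c = np.empty((n_out, n, dim))
    out_e = np.empty(n_out)
    k_out = 0
    for step in range(1, n_steps + 1):
        scale = 1.0
        if use_bias:
            scale = 1.0 + bias_slope(e, knots, coeffs, slope_lo, slope_hi)
        for i in range(n):
            f = scale * conv / masses[i]
            for d in range(dim):
                vel[i, d] += 0.5 * dt * forces[i, d] * f
                coords[i, d] += 0.5 * dt * vel[i, d]
        for i in range(n):
            sv = math.sqrt(kbt * conv / masses[i])
            for d in range(dim):
                vel[i, d] = c1 * vel[i, d] + c2 * sv * np.random.normal()
                coords[i, d] += 0.5 * dt * vel[i, d]
        numeric_forces(
            pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
            rest_ij, rest_par, use_restraints, coords, h, forces,
        )
        e = total_energy(
            pot_id, pp, site_pos, site_depth, site_sigma, tether_ref, tether_k,
            rest_ij, rest_par, use_restraints, coords,
        )
        if use_bias:
            scale = 1.0 + bias_slope(e, knots, coeffs, slope_lo, slope_hi)
        for i in range(n):
            f = scale * conv / masses[i]
            for d in range(dim):
                vel[i, d] += 0.5 * dt * forces[i, d] * f
        if e > e_max:
            return out_c, out_e, k_out, 0, 1
        if step % stride == 0:
            for i in range(n):
                for d in range(dim):
                    out_c[k_out, i, d] = coords[i, d]
            out_e[k_out] = e
            k_out += 1
    return out_c, out_e, k_out, n_steps, 0
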
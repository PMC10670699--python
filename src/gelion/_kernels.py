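"""Numba kernels for short-range pair interactions.

All kernels use the minimum-image convention in a cubic box of side L and
operate on a precomputed Verlet pair list.  Electrostatics here is the
damped-shifted-force (DSF) approximation used for production dynamics; the
Ewald reference lives in :mod:`gelion.ewald`.
"""

import math

import numpy as np
from numba import njit

TWO_OVER_SQRT_PI = 2.0 / math.sqrt(math.pi)


@njit(cache=True)
def count_pairs(pos, L, rcut):
    n = pos.shape[0]
    rc2 = rcut * rcut
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            if dx * dx + dy * dy + dz * dz < rc2:
                count += 1
    return count


@njit(cache=True)
def build_pairs(pos, L, rcut):
    """Verlet list: all i<j pairs within rcut (minimum image)."""
    n = pos.shape[0]
    rc2 = rcut * rcut
    cap = count_pairs(pos, L, rcut)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    idx = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            if dx * dx + dy * dy + dz * dz < rc2:
                pi[idx] = i
                pj[idx] = j
                idx += 1
    return pi, pj


@njit(cache=True)
def pair_forces(pos, q, L, pi, pj, lB, alpha, rc_coul, rc_wca, forces):
    """WCA + DSF-Coulomb energies and forces over a pair list.

    Returns (e_wca, e_coul, overlap_i, overlap_j); overlap indices are -1
    unless a pair sits closer than 1e-6 sigma.  ``forces`` is accumulated
    in place (caller zeroes it).
    """
    e_wca = 0.0
    e_coul = 0.0
    rc_wca2 = rc_wca * rc_wca
    rc_c2 = rc_coul * rc_coul
    erfc_rc = math.erfc(alpha * rc_coul)
    e_shift = erfc_rc / rc_coul
    f_shift = erfc_rc / rc_c2 + TWO_OVER_SQRT_PI * alpha * \
        math.exp(-alpha * alpha * rc_c2) / rc_coul
    ov_i = -1
    ov_j = -1
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * round(dx / L)
        dy -= L * round(dy / L)
        dz -= L * round(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            ov_i = i
            ov_j = j
            continue
        fr = 0.0  # force magnitude / r
        if r2 < rc_wca2:
            inv2 = 1.0 / r2
            s6 = inv2 * inv2 * inv2
            s12 = s6 * s6
            e_wca += 4.0 * (s12 - s6) + 1.0
            fr += 24.0 * (2.0 * s12 - s6) * inv2
        qq = q[i] * q[j]
        if qq != 0.0 and r2 < rc_c2:
            r = math.sqrt(r2)
            er = math.erfc(alpha * r)
            gauss = TWO_OVER_SQRT_PI * alpha * math.exp(-alpha * alpha * r2)
            e_coul += lB * qq * (er / r - e_shift + f_shift * (r - rc_coul))
            fr += lB * qq * (er / r2 + gauss / r - f_shift) / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e_wca, e_coul, ov_i, ov_j


@njit(cache=True)
def bond_forces(pos, bonds, L, k_spring, l0, forces):
    """Stiff harmonic bonds V = k (r - l0)^2; returns energy, accumulates forces."""
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * round(dx / L)
        dy -= L * round(dy / L)
        dz -= L * round(dz / L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - l0
        e += k_spring * dr * dr
        fr = -2.0 * k_spring * dr / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e


@njit(cache=True)
def max_sq_displacement(pos, ref, L):
    n = pos.shape[0]
    best = 0.0
    for i in range(n):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        dx -= L * round(dx / L)
        dy -= L * round(dy / L)
        dz -= L * round(dz / L)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > best:
            best = d2
    return best
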
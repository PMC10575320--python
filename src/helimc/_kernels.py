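"""Compiled inner loops for the Monte Carlo sampler.

Everything here is an implementation detail of :mod:`helimc.sampler`; the
public, NumPy-based reference implementations live in :mod:`helimc.model`
and :mod:`helimc.moves` and the test suite asserts agreement between the
two paths.

Moves operate on a contiguous ``(N, 3)`` float64 coordinate array.  Energy
changes are computed incrementally: a single-monomer displacement only
rescores the terms touching that monomer, and the rigid-block moves
(global displacement, bend rotation, torsion rotation) only rescore the
interaction across the pivot, since the internal energy of a rigidly
moved block is unchanged.  A full recomputation is performed at every
block boundary, which bounds accumulation drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# move-kind codes
LOCAL, GLOBAL_DISP, BEND, TORSION = 0, 1, 2, 3


@njit(cache=True)
def energy_terms_kernel(coords, r0, R, sigma, rc, vc, theta0, tau0, min_sep):
    """Return (valid, e_fene, e_lj, e_bend, e_tor) unscaled term sums."""
    n = coords.shape[0]
    e_fene = 0.0
    for i in range(n - 1):
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        x = (r - r0) / R
        if x * x >= 1.0:
            return False, 0.0, 0.0, 0.0, 0.0
        e_fene += np.log1p(-x * x)

    e_lj = 0.0
    rc2 = rc * rc
    s2 = sigma * sigma
    for i in range(n):
        for j in range(i + min_sep, n):
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rc2:
                s6 = (s2 / d2) ** 3
                e_lj += 4.0 * (s6 * s6 - s6) - vc

    e_bend = 0.0
    for k in range(1, n - 1):
        e_bend += 1.0 - np.cos(_angle(coords, k - 1, k, k + 1) - theta0)

    e_tor = 0.0
    for l in range(n - 3):
        e_tor += 1.0 - np.cos(_dihedral(coords, l, l + 1, l + 2, l + 3) - tau0)

    return True, e_fene, e_lj, e_bend, e_tor


@njit(cache=True)
def _angle(coords, ia, ib, ic):
    ux = coords[ib, 0] - coords[ia, 0]
    uy = coords[ib, 1] - coords[ia, 1]
    uz = coords[ib, 2] - coords[ia, 2]
    vx = coords[ic, 0] - coords[ib, 0]
    vy = coords[ic, 1] - coords[ib, 1]
    vz = coords[ic, 2] - coords[ib, 2]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return np.arccos(c)


@njit(cache=True)
def _dihedral(coords, ia, ib, ic, id_):
    b1x = coords[ib, 0] - coords[ia, 0]
    b1y = coords[ib, 1] - coords[ia, 1]
    b1z = coords[ib, 2] - coords[ia, 2]
    b2x = coords[ic, 0] - coords[ib, 0]
    b2y = coords[ic, 1] - coords[ib, 1]
    b2z = coords[ic, 2] - coords[ib, 2]
    b3x = coords[id_, 0] - coords[ic, 0]
    b3y = coords[id_, 1] - coords[ic, 1]
    b3z = coords[id_, 2] - coords[ic, 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    x = n1x * n2x + n1y * n2y + n1z * n2z
    cx = n1y * n2z - n1z * n2y
    cy = n1z * n2x - n1x * n2z
    cz = n1x * n2y - n1y * n2x
    nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    y = (cx * b2x + cy * b2y + cz * b2z) / nb2
    return np.arctan2(y, x)


@njit(cache=True)
def lj_split_kernel(coords, sigma, rc, vc, min_sep):
    """Summed truncated-shifted LJ energy over long-range (|i-j| > 6) and
    short-range (min_sep <= |i-j| <= 6) pairs; used for the bundling order
    parameter q."""
    n = coords.shape[0]
    rc2 = rc * rc
    s2 = sigma * sigma
    num = 0.0
    den = 0.0
    for i in range(n):
        for j in range(i + min_sep, n):
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rc2:
                s6 = (s2 / d2) ** 3
                v = 4.0 * (s6 * s6 - s6) - vc
                if j - i > 6:
                    num += v
                else:
                    den += v
    return num, den


@njit(cache=True)
def _pair_lj(coords, i, j, s2, rc2, vc):
    dx = coords[j, 0] - coords[i, 0]
    dy = coords[j, 1] - coords[i, 1]
    dz = coords[j, 2] - coords[i, 2]
    d2 = dx * dx + dy * dy + dz * dz
    if d2 >= rc2:
        return 0.0
    s6 = (s2 / d2) ** 3
    return 4.0 * (s6 * s6 - s6) - vc


@njit(cache=True)
def _bond_fene(coords, i, r0, R):
    """FENE term of bond (i, i+1); returns (valid, value)."""
    dx = coords[i + 1, 0] - coords[i, 0]
    dy = coords[i + 1, 1] - coords[i, 1]
    dz = coords[i + 1, 2] - coords[i, 2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    x = (r - r0) / R
    if x * x >= 1.0:
        return False, 0.0
    return True, np.log1p(-x * x)


@njit(cache=True)
def _local_terms(coords, i, r0, R, sigma, rc, vc, theta0, tau0, min_sep):
    """Scaled-term sums of everything that involves monomer i.

    Used for single-monomer displacement deltas: FENE bonds (i-1,i) and
    (i,i+1); all LJ pairs containing i; bending angles centred at
    i-1, i, i+1; dihedrals over bonds touching i.
    Returns (valid, e_fene, e_lj, e_bend, e_tor).
    """
    n = coords.shape[0]
    e_fene = 0.0
    for b in range(max(0, i - 1), min(n - 1, i + 1)):
        ok, v = _bond_fene(coords, b, r0, R)
        if not ok:
            return False, 0.0, 0.0, 0.0, 0.0
        e_fene += v

    rc2 = rc * rc
    s2 = sigma * sigma
    e_lj = 0.0
    for j in range(n):
        if abs(j - i) >= min_sep:
            e_lj += _pair_lj(coords, min(i, j), max(i, j), s2, rc2, vc)

    e_bend = 0.0
    for k in range(max(1, i - 1), min(n - 1, i + 2)):
        e_bend += 1.0 - np.cos(_angle(coords, k - 1, k, k + 1) - theta0)

    e_tor = 0.0
    for l in range(max(0, i - 3), min(n - 3, i + 1)):
        e_tor += 1.0 - np.cos(_dihedral(coords, l, l + 1, l + 2, l + 3) - tau0)

    return True, e_fene, e_lj, e_bend, e_tor


@njit(cache=True)
def _cross_terms(coords, k, r0, R, sigma, rc, vc, theta0, tau0, min_sep):
    """Scaled-term sums of the interaction between blocks [0..k] and
    [k+1..N-1] plus everything spanning the boundary.

    When the tail block moves rigidly, only these terms can change:
    the pivot bond (k, k+1), LJ pairs with one end in each block, the
    bending angles at k and k+1, and dihedrals spanning the pivot bond.
    Returns (valid, e_fene, e_lj, e_bend, e_tor).
    """
    n = coords.shape[0]
    e_fene = 0.0
    if k < n - 1:  # k == n-1 (empty tail) has no pivot bond
        ok, e_fene = _bond_fene(coords, k, r0, R)
        if not ok:
            return False, 0.0, 0.0, 0.0, 0.0

    rc2 = rc * rc
    s2 = sigma * sigma
    e_lj = 0.0
    for i in range(k + 1):
        for j in range(k + 1, n):
            if j - i >= min_sep:
                e_lj += _pair_lj(coords, i, j, s2, rc2, vc)

    e_bend = 0.0
    for kk in range(max(1, k), min(n - 1, k + 2)):
        e_bend += 1.0 - np.cos(_angle(coords, kk - 1, kk, kk + 1) - theta0)

    e_tor = 0.0
    for l in range(max(0, k - 2), min(n - 3, k + 1)):
        e_tor += 1.0 - np.cos(_dihedral(coords, l, l + 1, l + 2, l + 3) - tau0)

    return True, e_fene, e_lj, e_bend, e_tor


@njit(cache=True)
def _rotate_tail(coords, out, k, axx, axy, axz, ang):
    """Rodrigues rotation of monomers k+1..N-1 about a unit axis through
    monomer k; head block copied unchanged."""
    n = coords.shape[0]
    for i in range(k + 1):
        out[i, 0] = coords[i, 0]
        out[i, 1] = coords[i, 1]
        out[i, 2] = coords[i, 2]
    c = np.cos(ang)
    s = np.sin(ang)
    px = coords[k, 0]
    py = coords[k, 1]
    pz = coords[k, 2]
    for i in range(k + 1, n):
        vx = coords[i, 0] - px
        vy = coords[i, 1] - py
        vz = coords[i, 2] - pz
        dot = axx * vx + axy * vy + axz * vz
        crx = axy * vz - axz * vy
        cry = axz * vx - axx * vz
        crz = axx * vy - axy * vx
        out[i, 0] = px + vx * c + crx * s + axx * dot * (1.0 - c)
        out[i, 1] = py + vy * c + cry * s + axy * dot * (1.0 - c)
        out[i, 2] = pz + vz * c + crz * s + axz * dot * (1.0 - c)


@njit(cache=True)
def run_block(
    coords,
    s_fene,
    s_lj,
    s_theta,
    s_tau,
    beta,
    r0,
    R,
    sigma,
    rc,
    vc,
    theta0,
    tau0,
    min_sep,
    n_sweeps,
    p_local,
    p_global,
    p_bend,
    local_step,
    rot_max,
    seed,
    e_samples,
    q_samples,
    acc,
    att,
):
    """Advance one replica by ``n_sweeps`` sweeps of N Metropolis attempts.

    Move mix: local displacement with probability ``p_local``, global
    displacement ``p_global``, bend rotation ``p_bend``, torsion rotation
    with the remainder.  Records (E, q) once per sweep into the provided
    arrays and per-kind acceptance counters into ``acc``/``att``.
    Returns (E, e_fene, e_lj, e_bend, e_tor) from a final full recompute.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    new = np.empty_like(coords)

    ok, ef, el, eb, et = energy_terms_kernel(
        coords, r0, R, sigma, rc, vc, theta0, tau0, min_sep
    )
    energy = s_fene * ef + s_lj * el + s_theta * eb + s_tau * et

    for sweep in range(n_sweeps):
        for _ in range(n):
            u = np.random.random()
            if u < p_local:
                kind = LOCAL
            elif u < p_local + p_global:
                kind = GLOBAL_DISP
            elif u < p_local + p_global + p_bend:
                kind = BEND
            else:
                kind = TORSION
            if kind == BEND and n < 3:
                kind = LOCAL  # a dimer has no bend pivot
            att[kind] += 1

            if kind == LOCAL:
                i = np.random.randint(0, n)
                ok0, f0, l0, b0, t0 = _local_terms(
                    coords, i, r0, R, sigma, rc, vc, theta0, tau0, min_sep
                )
                for d in range(n):
                    new[d, 0] = coords[d, 0]
                    new[d, 1] = coords[d, 1]
                    new[d, 2] = coords[d, 2]
                new[i, 0] += (2.0 * np.random.random() - 1.0) * local_step
                new[i, 1] += (2.0 * np.random.random() - 1.0) * local_step
                new[i, 2] += (2.0 * np.random.random() - 1.0) * local_step
                ok1, f1, l1, b1, t1 = _local_terms(
                    new, i, r0, R, sigma, rc, vc, theta0, tau0, min_sep
                )
            else:
                if kind == GLOBAL_DISP:
                    k = np.random.randint(0, n - 1)
                elif kind == BEND:
                    k = 1 + np.random.randint(0, n - 2)
                else:
                    k = 1 + np.random.randint(0, n - 1)
                ok0, f0, l0, b0, t0 = _cross_terms(
                    coords, k if kind != BEND else k, r0, R, sigma, rc, vc,
                    theta0, tau0, min_sep,
                )
                if kind == GLOBAL_DISP:
                    dx = (2.0 * np.random.random() - 1.0) * local_step
                    dy = (2.0 * np.random.random() - 1.0) * local_step
                    dz = (2.0 * np.random.random() - 1.0) * local_step
                    for d in range(k + 1):
                        new[d, 0] = coords[d, 0]
                        new[d, 1] = coords[d, 1]
                        new[d, 2] = coords[d, 2]
                    for d in range(k + 1, n):
                        new[d, 0] = coords[d, 0] + dx
                        new[d, 1] = coords[d, 1] + dy
                        new[d, 2] = coords[d, 2] + dz
                    ok1, f1, l1, b1, t1 = _cross_terms(
                        new, k, r0, R, sigma, rc, vc, theta0, tau0, min_sep
                    )
                else:
                    # rotation axis
                    u1x = coords[k, 0] - coords[k - 1, 0]
                    u1y = coords[k, 1] - coords[k - 1, 1]
                    u1z = coords[k, 2] - coords[k - 1, 2]
                    if kind == BEND:
                        u2x = coords[k + 1, 0] - coords[k, 0]
                        u2y = coords[k + 1, 1] - coords[k, 1]
                        u2z = coords[k + 1, 2] - coords[k, 2]
                        axx = u1y * u2z - u1z * u2y
                        axy = u1z * u2x - u1x * u2z
                        axz = u1x * u2y - u1y * u2x
                        norm = np.sqrt(axx * axx + axy * axy + axz * axz)
                        if norm < 1e-12:
                            # parallel bonds: any axis perpendicular to the
                            # shared direction, drawn uniformly
                            nb = np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
                            bx, by, bz = u1x / nb, u1y / nb, u1z / nb
                            # perpendicular basis
                            if abs(bx) < 0.9:
                                px_, py_, pz_ = 1.0, 0.0, 0.0
                            else:
                                px_, py_, pz_ = 0.0, 1.0, 0.0
                            e1x = by * pz_ - bz * py_
                            e1y = bz * px_ - bx * pz_
                            e1z = bx * py_ - by * px_
                            ne1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                            e1x, e1y, e1z = e1x / ne1, e1y / ne1, e1z / ne1
                            e2x = by * e1z - bz * e1y
                            e2y = bz * e1x - bx * e1z
                            e2z = bx * e1y - by * e1x
                            phi = 2.0 * np.pi * np.random.random()
                            axx = np.cos(phi) * e1x + np.sin(phi) * e2x
                            axy = np.cos(phi) * e1y + np.sin(phi) * e2y
                            axz = np.cos(phi) * e1z + np.sin(phi) * e2z
                        else:
                            axx, axy, axz = axx / norm, axy / norm, axz / norm
                    else:
                        norm = np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
                        axx, axy, axz = u1x / norm, u1y / norm, u1z / norm
                    ang = (2.0 * np.random.random() - 1.0) * rot_max
                    _rotate_tail(coords, new, k, axx, axy, axz, ang)
                    ok1, f1, l1, b1, t1 = _cross_terms(
                        new, k, r0, R, sigma, rc, vc, theta0, tau0, min_sep
                    )

            if not (ok0 and ok1):
                accept = ok1 and not ok0  # cannot happen from valid states
            else:
                de = (
                    s_fene * (f1 - f0)
                    + s_lj * (l1 - l0)
                    + s_theta * (b1 - b0)
                    + s_tau * (t1 - t0)
                )
                if de <= 0.0:
                    accept = True
                else:
                    accept = np.random.random() < np.exp(-beta * de)
                if accept:
                    energy += de

            if accept:
                acc[kind] += 1
                for d in range(n):
                    coords[d, 0] = new[d, 0]
                    coords[d, 1] = new[d, 1]
                    coords[d, 2] = new[d, 2]

        num, den = lj_split_kernel(coords, sigma, rc, vc, min_sep)
        q = 0.0
        if abs(den) > 1e-9:
            q = num / den
        e_samples[sweep] = energy
        q_samples[sweep] = q

    ok, ef, el, eb, et = energy_terms_kernel(
        coords, r0, R, sigma, rc, vc, theta0, tau0, min_sep
    )
    energy = s_fene * ef + s_lj * el + s_theta * eb + s_tau * et
    return energy, ef, el, eb, et
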
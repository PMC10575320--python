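"""Synthetic inputs and exact oracles.

* :func:`ideal_helix` — the reference geometry (all bonds at ``r0``, all
  bending angles at ``theta0``, all dihedrals at ``tau0``), built by
  sequential internal-coordinate placement.
* :func:`two_helix_template` — two antiparallel helical segments joined by
  a short turn, used to seed sampling of the bundle phase.
* :func:`enumerable_system` — a finite-level system with known
  degeneracies, an exact canonical sampler, and closed-form Z, mean energy
  and specific heat; the independent oracle for histogram reweighting.
* :func:`planted_entropy` — synthetic microcanonical entropy curves with a
  single transition of prescribed order planted at a known energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize

from .model import DEFAULT_PARAMS, ModelParameters, total_energy

__all__ = [
    "build_chain",
    "ideal_helix",
    "two_helix_template",
    "random_coil",
    "EnumerableSystem",
    "enumerable_system",
    "planted_entropy",
    "study_grids",
]


def build_chain(bond_lengths, thetas, taus) -> np.ndarray:
    """Place a chain from internal coordinates.

    ``bond_lengths`` has N-1 entries, ``thetas`` N-2 bond-vector bending
    angles, ``taus`` N-3 signed dihedrals.  The first monomer sits at the
    origin with the first bond along +x; the construction is deterministic
    and round-trips through the angle/dihedral computations in
    :mod:`helimc.model`.
    """
    bond_lengths = np.asarray(bond_lengths, float)
    thetas = np.asarray(thetas, float)
    taus = np.asarray(taus, float)
    n = len(bond_lengths) + 1
    coords = np.zeros((n, 3))
    coords[1] = [bond_lengths[0], 0.0, 0.0]
    if n == 2:
        return coords
    th = thetas[0]
    coords[2] = coords[1] + bond_lengths[1] * np.array(
        [math.cos(th), math.sin(th), 0.0]
    )
    for k in range(2, n - 1):
        b1 = coords[k - 1] - coords[k - 2]
        b2 = coords[k] - coords[k - 1]
        u = b2 / np.linalg.norm(b2)
        perp = b1 - np.dot(b1, u) * u
        m = perp / np.linalg.norm(perp)
        nvec = np.cross(u, m)
        th = thetas[k - 1]
        ta = taus[k - 2]
        direction = (
            math.cos(th) * u
            - math.sin(th) * (math.cos(ta) * m + math.sin(ta) * nvec)
        )
        coords[k + 1] = coords[k] + bond_lengths[k] * direction
    return coords


def ideal_helix(n: int, p: ModelParameters = DEFAULT_PARAMS) -> np.ndarray:
    """Ideal right-handed helix: every bond at ``r0``, every bending angle
    at ``theta0``, every dihedral at ``tau0``.  Bending and torsion energy
    terms vanish identically; the energy is pure (negative) LJ."""
    if n < 2:
        raise ValueError("need n >= 2")
    return build_chain(
        np.full(n - 1, p.r0), np.full(max(n - 2, 0), p.theta0),
        np.full(max(n - 3, 0), p.tau0),
    )


def random_coil(n: int, rng, p: ModelParameters = DEFAULT_PARAMS) -> np.ndarray:
    """Self-avoiding-ish random walk with valid bond lengths; an
    alternative initializer for ergodicity cross-checks."""
    thetas = rng.uniform(0.3, math.pi - 0.3, max(n - 2, 0))
    taus = rng.uniform(-math.pi, math.pi, max(n - 3, 0))
    return build_chain(np.full(n - 1, p.r0), thetas, taus)


def _helix_frame(coords: np.ndarray):
    """(unit axis direction, point on axis, radius) of a near-ideal helix,
    oriented from the first monomer toward the last.

    The axis direction is the rotation axis of the bond-to-bond rotation;
    the axis point and radius come from a least-squares circle fit of the
    monomers projected onto the plane perpendicular to the axis.
    """
    from scipy.spatial.transform import Rotation

    bonds = np.diff(coords, axis=0)
    rot, _ = Rotation.align_vectors(bonds[1:], bonds[:-1])
    rv = rot.as_rotvec()
    axis = rv / np.linalg.norm(rv)
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    # orthonormal frame perpendicular to the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = coords @ e1
    v = coords @ e2
    # Kasa circle fit: minimize |(u-a)^2 + (v-b)^2 - r^2|
    amat = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    sol, *_ = np.linalg.lstsq(amat, u**2 + v**2, rcond=None)
    a, b, cc = sol
    radius = math.sqrt(cc + a * a + b * b)
    center = a * e1 + b * e2 + np.dot(coords.mean(axis=0), axis) * axis
    return axis, center, radius


def two_helix_template(
    n: int,
    p: ModelParameters = DEFAULT_PARAMS,
    turn_monomers: int = 2,
    relax: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Two antiparallel ideal-helix segments joined by a short turn.

    The second segment is placed with its axis antiparallel to the first
    at helix-contact spacing; the lateral offset, axial shift and spin
    about its own axis are chosen by a coarse grid scan minimising the
    inter-segment LJ energy subject to a bridgeable end gap.  The turn
    monomers interpolate the gap, and the assembly is then relaxed by a
    short very-low-temperature Metropolis run.  Intended as an annealing
    seed for the bundle phase, not as a ground-state claim.
    """
    from scipy.spatial.distance import cdist
    from scipy.spatial.transform import Rotation

    if n < 12:
        raise ValueError("need n >= 12")
    n_rest = n - turn_monomers
    n1 = (n_rest + 1) // 2
    n2 = n_rest - n1

    seg_a = ideal_helix(n1, p)
    axis_a, center_a, radius = _helix_frame(seg_a)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis_a)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis_a, helper)
    e1 /= np.linalg.norm(e1)

    seg_b0 = ideal_helix(n2, p)
    axis_b, center_b, _ = _helix_frame(seg_b0)
    base_rot = Rotation.align_vectors(-axis_a[None, :], axis_b[None, :])[0]
    seg_b0 = (seg_b0 - center_b) @ base_rot.as_matrix().T

    z_end = float(np.dot(seg_a[-1] - center_a, axis_a))
    gap_lo = 0.75 * (turn_monomers + 1) * p.r0
    gap_hi = 1.25 * (turn_monomers + 1) * p.r0

    best = None
    for d in np.linspace(2.0 * radius + 0.4, 2.0 * radius + 1.8, 8):
        for psi in np.linspace(0.0, 2.0 * math.pi, 24, endpoint=False):
            spin = Rotation.from_rotvec(psi * axis_a).as_matrix()
            seg_spun = seg_b0 @ spin.T
            for dz in np.linspace(-1.5, 1.5, 7):
                offset = center_a + d * e1
                z_b0 = float(np.dot(seg_spun[0], axis_a))
                shift = offset + (z_end + 0.8 - z_b0 + dz) * axis_a
                seg_b = seg_spun + shift
                gap = float(np.linalg.norm(seg_b[0] - seg_a[-1]))
                if not (gap_lo <= gap <= gap_hi):
                    continue
                dist = cdist(seg_a, seg_b)
                if dist.min() < 0.9 * p.r0:
                    continue
                inside = dist[dist < p.rc]
                s6 = (p.sigma / inside) ** 6
                e_pack = float(np.sum(4.0 * (s6 * s6 - s6) - p.vc))
                if best is None or e_pack < best[0]:
                    best = (e_pack, seg_b)
    if best is None:
        raise RuntimeError("no feasible antiparallel placement found")
    seg_b = best[1]

    # turn monomers: chord between the segment ends, bulged axially over
    # the helix tops to avoid threading through the inter-helix groove
    frac = np.arange(1, turn_monomers + 1) / (turn_monomers + 1)
    chord = seg_a[-1] + frac[:, None] * (seg_b[0] - seg_a[-1])
    best_turn, best_score = chord, -np.inf
    for bulge in np.linspace(0.0, 1.2, 13):
        turn = chord + bulge * np.sin(math.pi * frac)[:, None] * axis_a
        cand = np.vstack([seg_a, turn, seg_b])
        bl = np.linalg.norm(np.diff(cand, axis=0), axis=1)
        if np.any(np.abs(bl - p.r0) >= 0.95 * p.R):
            continue
        other = np.vstack([seg_a[:-1], seg_b[1:]])
        score = float(cdist(turn, other).min())
        if score > best_score:
            best_score, best_turn = score, turn
    coords = np.ascontiguousarray(np.vstack([seg_a, best_turn, seg_b]))

    if relax:
        from . import _kernels

        seeds = np.random.SeedSequence(seed).generate_state(2)
        # stage 1: local moves only — eases turn clashes and angles while
        # the bundle topology cannot be swung apart
        _relax_block(coords, p, beta=30.0, sweeps=4000,
                     mix=(1.0, 0.0, 0.0), seed=int(seeds[0] % 2**31))
        # stage 2: gentle polish with the full move mix
        _relax_block(coords, p, beta=30.0, sweeps=1000,
                     mix=(0.8, 0.0, 0.1), seed=int(seeds[1] % 2**31))
    return coords


def _relax_block(coords, p, beta, sweeps, mix, seed):
    from . import _kernels

    e_samp = np.empty(sweeps)
    q_samp = np.empty(sweeps)
    acc = np.zeros(4, np.int64)
    att = np.zeros(4, np.int64)
    _kernels.run_block(
        coords, p.s_fene, p.s_lj, p.s_theta, p.s_tau, beta,
        p.r0, p.R, p.sigma, p.rc, p.vc, p.theta0, p.tau0,
        1 if p.include_bonded_lj else 2,
        sweeps, mix[0], mix[1], mix[2], 0.1, 0.1,
        seed, e_samp, q_samp, acc, att,
    )


@dataclass(frozen=True)
class EnumerableSystem:
    """Finite-level system with exact degeneracies.

    Provides closed-form canonical quantities and an exact multinomial
    sampler; the independent oracle for WHAM and prevalence tests.
    """

    energies: np.ndarray
    degeneracies: np.ndarray

    def log_z(self, beta: float) -> float:
        from scipy.special import logsumexp
        return float(
            logsumexp(np.log(self.degeneracies) - beta * self.energies)
        )

    def level_probs(self, beta: float) -> np.ndarray:
        w = np.log(self.degeneracies) - beta * self.energies
        w = np.exp(w - w.max())
        return w / w.sum()

    def mean_energy(self, beta: float) -> float:
        return float(np.dot(self.level_probs(beta), self.energies))

    def specific_heat(self, beta: float) -> float:
        prob = self.level_probs(beta)
        e1 = np.dot(prob, self.energies)
        e2 = np.dot(prob, self.energies**2)
        return float(beta**2 * (e2 - e1**2))

    def sample_counts(self, beta: float, m: int, rng) -> np.ndarray:
        """Exact canonical sample: multinomial counts over the levels."""
        return rng.multinomial(m, self.level_probs(beta))


def enumerable_system(levels, degeneracies) -> EnumerableSystem:
    levels = np.asarray(levels, float)
    degeneracies = np.asarray(degeneracies, float)
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    if np.any(degeneracies <= 0):
        raise ValueError("degeneracies must be positive")
    return EnumerableSystem(levels, degeneracies)


def planted_entropy(
    order: int,
    e_t: float,
    amplitude: float = 0.8,
    width: float | None = None,
    grid: np.ndarray | None = None,
):
    """Synthetic entropy curve with one transition of the given order.

    The construction plants a Gaussian feature in the derivative channel
    that defines the transition order — a backbending bump in ``dS/dE``
    for first order, a sub-zero local maximum of the second derivative for
    second order, a positive local minimum of the third derivative for
    third order, a sub-zero local maximum of the fourth derivative for
    fourth order — and integrates down to S on the grid.  ``amplitude`` is
    the feature size relative to the baseline magnitude (values > 1 are
    only meaningful for first order, where the bump must cross zero);
    ``amplitude = 0`` yields a transition-free curve.

    Returns ``(energy_grid, S, truth)`` where ``truth`` is ``None`` for
    ``amplitude = 0`` and otherwise a dict with keys ``order`` and
    ``energy``.
    """
    if order not in (1, 2, 3, 4):
        raise ValueError("order must be 1..4")
    if grid is None:
        grid = np.linspace(0.0, 100.0, 2001)
    grid = np.asarray(grid, float)
    if not (grid[2] < e_t < grid[-3]):
        raise ValueError("e_t must be interior to the grid")
    span = grid[-1] - grid[0]
    if width is None:
        width = 0.03 * span

    # Transition-free backbone: gamma_b = -a exp(-(E-E0)/lam), so every
    # derivative is monotone with the physically expected sign pattern
    # (beta > 0 decreasing, gamma < 0 rising toward zero, delta > 0
    # falling, S'''' < 0 rising) and all approach zero at high energy.
    a, lam = 0.1, 0.4 * span
    x = grid - grid[0]
    decay = np.exp(-x / lam)
    gamma_b = -a * decay
    delta_b = (a / lam) * decay
    s4_b = -(a / lam**2) * decay

    bump = np.exp(-((grid - e_t) ** 2) / (2.0 * width**2))
    amp = float(amplitude)
    i_t = int(np.argmin(np.abs(grid - e_t)))

    if amp == 0:
        gamma = gamma_b
    elif order == 1:
        # bump tall enough that gamma crosses zero: beta backbends
        gamma = gamma_b + (1.0 + amp) * a * decay[i_t] * bump
    elif order == 2:
        # sub-zero local maximum of gamma at e_t
        gamma = gamma_b * (1.0 - amp * bump)
    elif order == 3:
        # positive local minimum of delta at e_t
        delta = delta_b * (1.0 - amp * bump)
        gamma = gamma_b[0] + cumulative_trapezoid(delta, grid, initial=0.0)
    else:
        # sub-zero local maximum of the fourth derivative at e_t
        s4 = s4_b * (1.0 - amp * bump)
        delta = delta_b[0] + cumulative_trapezoid(s4, grid, initial=0.0)
        gamma = gamma_b[0] + cumulative_trapezoid(delta, grid, initial=0.0)

    beta = 4.5 + cumulative_trapezoid(gamma, grid, initial=0.0)
    s = cumulative_trapezoid(beta, grid, initial=0.0)

    truth = None if amp == 0 else {"order": order, "energy": float(e_t)}
    return grid, s, truth


def study_grids() -> dict:
    """Named schedule presets.

    * ``n30_full`` — the full 160-thread N=30 grid: 16 temperatures in
      [0.2, 1.6], 10 torsion scales in [5, 14];
    * ``n40_full`` — the N=40 analogue with torsion scales in [5, 25];
    * ``n30_reduced`` — one torsion-scale column at shortened length, for
      desk-scale reproduction of the main transition signals;
    * ``smoke`` — a minutes-scale N=10 end-to-end check.
    """
    from .sampler import build_schedule

    return {
        "n30_full": build_schedule(
            n=30, t_min=0.2, t_max=1.6, n_temperatures=16,
            s_tau_min=5.0, s_tau_max=14.0, n_s_tau=10,
            sweeps=1_000_000, burn_in=200_000,
        ),
        "n40_full": build_schedule(
            n=40, t_min=0.2, t_max=1.6, n_temperatures=16,
            s_tau_min=5.0, s_tau_max=25.0, n_s_tau=10,
            sweeps=1_000_000, burn_in=200_000,
            e_min=-120.0, e_max=120.0,
        ),
        "n30_reduced": build_schedule(
            n=30, t_min=0.2, t_max=1.6, n_temperatures=16,
            s_tau_min=8.0, s_tau_max=8.0, n_s_tau=1,
            sweeps=60_000, burn_in=15_000,
        ),
        "smoke": build_schedule(
            n=10, t_min=0.3, t_max=1.6, n_temperatures=4,
            s_tau_min=6.0, s_tau_max=10.0, n_s_tau=2,
            sweeps=2_000, burn_in=500, e_min=-30.0, e_max=30.0,
        ),
    }
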
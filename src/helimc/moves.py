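"""Monte Carlo update types and the Metropolis acceptance rule.

Four proposal kinds are used:

* ``local`` — displace one random monomer by a vector drawn uniformly
  from a cube;
* ``global_displacement`` — shift every monomer beyond a random pivot by
  one common random vector;
* ``bend`` — rotate the tail beyond a pivot rigidly about an axis through
  the pivot perpendicular to both of its neighbouring bonds;
* ``torsion`` — rotate the tail about the bond entering the pivot, which
  changes exactly one dihedral.

All proposal densities are symmetric, so the Metropolis rule
``P_acc = min(1, exp(-beta dE))`` satisfies detailed balance; proposals
that push any bond outside the finite FENE domain are rejected outright.

These are the reference implementations; the sampler runs an equivalent
compiled path (see :mod:`helimc._kernels`) whose agreement with this
module is asserted by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DEFAULT_PARAMS, ModelParameters

__all__ = [
    "MoveProposal",
    "propose_local_displacement",
    "propose_global_displacement",
    "propose_bend_rotation",
    "propose_torsion_rotation",
    "metropolis_decision",
    "proposal_is_valid",
]

MOVE_KINDS = ("local", "global_displacement", "bend", "torsion")


@dataclass(frozen=True)
class MoveProposal:
    kind: str
    pivot: int
    proposed_coords: np.ndarray
    #: displacement vector or rotation angle, for diagnostics
    parameter: object = None


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def propose_local_displacement(
    coords: np.ndarray, rng: np.random.Generator, step: float
) -> MoveProposal:
    """Displace one uniformly chosen monomer by a vector uniform in
    ``[-step, step]^3``."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = coords.shape[0]
    i = int(rng.integers(0, n))
    delta = rng.uniform(-step, step, 3)
    new = coords.copy()
    new[i] += delta
    return MoveProposal("local", i, new, delta)


def propose_global_displacement(
    coords: np.ndarray, rng: np.random.Generator, step: float
) -> MoveProposal:
    """Shift monomers ``k+1..N-1`` (pivot k uniform in 0..N-2) by one
    common vector uniform in ``[-step, step]^3``; the internal geometry of
    the moved block is unchanged."""
    n = coords.shape[0]
    k = int(rng.integers(0, n - 1))
    delta = rng.uniform(-step, step, 3)
    new = coords.copy()
    new[k + 1:] += delta
    return MoveProposal("global_displacement", k, new, delta)


def propose_bend_rotation(
    coords: np.ndarray, rng: np.random.Generator, max_angle: float
) -> MoveProposal:
    """Rotate monomers ``k+1..N-1`` rigidly about an axis through monomer k
    perpendicular to both of its neighbouring bonds (pivot k uniform in
    1..N-2); rotation angle uniform in ``[-max_angle, max_angle]``.

    If the neighbouring bonds are parallel the perpendicular axis is
    degenerate; an axis is then drawn uniformly in the plane perpendicular
    to the shared bond direction (a measure-symmetric, reversible choice).
    """
    n = coords.shape[0]
    k = int(rng.integers(1, n - 1))
    u1 = coords[k] - coords[k - 1]
    u2 = coords[k + 1] - coords[k]
    axis = np.cross(u1, u2)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        b = u1 / np.linalg.norm(u1)
        helper = np.array([1.0, 0.0, 0.0]) if abs(b[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(b, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(b, e1)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        axis = math.cos(phi) * e1 + math.sin(phi) * e2
    else:
        axis = axis / norm
    angle = rng.uniform(-max_angle, max_angle)
    rot = _rotation_matrix(axis, angle)
    new = coords.copy()
    new[k + 1:] = coords[k] + (coords[k + 1:] - coords[k]) @ rot.T
    return MoveProposal("bend", k, new, angle)


def propose_torsion_rotation(
    coords: np.ndarray, rng: np.random.Generator, max_angle: float
) -> MoveProposal:
    """Rotate monomers ``k+1..N-1`` about the axis of the bond (k-1, k)
    (pivot k uniform in 1..N-1); changes the dihedral at that bond by
    exactly the drawn angle and leaves all bond lengths and bending angles
    unchanged."""
    n = coords.shape[0]
    k = int(rng.integers(1, n))
    axis = coords[k] - coords[k - 1]
    angle = rng.uniform(-max_angle, max_angle)
    new = coords.copy()
    if k + 1 < n:
        rot = _rotation_matrix(axis, angle)
        new[k + 1:] = coords[k] + (coords[k + 1:] - coords[k]) @ rot.T
    return MoveProposal("torsion", k, new, angle)


def proposal_is_valid(
    proposal: MoveProposal, p: ModelParameters = DEFAULT_PARAMS
) -> bool:
    """True when every bond of the proposed conformation stays inside the
    finite FENE domain ``|r - r0| < R``."""
    r = np.linalg.norm(np.diff(proposal.proposed_coords, axis=0), axis=1)
    return bool(np.all(np.abs(r - p.r0) < p.R))


def metropolis_decision(
    delta_e: float,
    beta: float,
    rng: np.random.Generator,
    proposal_valid: bool = True,
) -> bool:
    """Metropolis rule: reject unconditionally if the proposal left the
    FENE domain, otherwise accept with probability ``min(1, e^(-beta dE))``
    using a single uniform draw."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not proposal_valid:
        return False
    if delta_e <= 0:
        return True
    return bool(rng.random() < math.exp(-beta * delta_e))
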
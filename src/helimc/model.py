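"""Coarse-grained helical homopolymer model.

A linear chain of N identical monomers interacts through four potentials:

* a FENE bond potential between bonded neighbours, finite only for
  ``|r - r0| < R``;
* a truncated and shifted Lennard-Jones potential between non-bonded
  monomers closer than the cutoff ``rc``;
* a cosine bending potential penalising deviation of the bond-vector
  bending angle from a reference ``theta0``;
* a chirally asymmetric cosine torsion potential penalising deviation of
  the signed dihedral from a reference ``tau0``.

The Hamiltonian is the sum of the four terms, each scaled by an energy
scale (``s_fene``, ``s_lj``, ``s_theta``, ``s_tau``).  The torsion scale
``s_tau`` is the control parameter that tunes helix-segment stiffness and
thereby selects between single-helix and helix-bundle low-energy phases.

All quantities are in reduced units with ``r0 = 1``, ``s_lj = 1`` and
``kB = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "DEFAULT_PARAMS",
    "bond_stretch_energy",
    "nonbonded_pair_energy",
    "bending_angle",
    "dihedral_angle",
    "bend_energy",
    "torsion_energy",
    "total_energy",
    "energy_terms",
    "order_parameter_q",
    "validate_conformation",
    "write_xyz",
    "read_xyz",
]

#: tolerance below which the q denominator is treated as zero
EPS_Q = 1e-9


class FeneDomainError(ValueError):
    """A bond length lies outside the finite FENE domain ``|r - r0| < R``."""


class DegenerateGeometryError(ValueError):
    """An angle or dihedral is requested for degenerate (zero-length or
    collinear) bond geometry."""


@dataclass(frozen=True)
class ModelParameters:
    """Hamiltonian constants of the helical homopolymer model.

    The defaults reproduce the standard parameterisation: equilibrium bond
    length ``r0 = 1``, maximum bond deviation ``R = 3/7``, LJ length
    ``sigma = 2^(-1/6) r0`` (so the LJ minimum sits at ``r0``), cutoff
    ``rc = 2.5 sigma``, reference bending angle ``theta0 = 1.742`` rad and
    reference dihedral ``tau0 = 0.873`` rad.  The energy scales are
    ``s_fene = -(98/5) r0^2 R^2 / 2 = -1.8``, ``s_lj = 1`` and
    ``s_theta = 200``; ``s_tau`` varies between simulation threads.

    ``vc`` (the LJ shift that makes the potential vanish continuously at
    the cutoff) and ``s_fene`` are derived quantities and recomputed in
    ``__post_init__``; they are never stored stale.
    """

    r0: float = 1.0
    R: float = 3.0 / 7.0
    sigma: float = 2.0 ** (-1.0 / 6.0)
    rc: float = 2.5 * 2.0 ** (-1.0 / 6.0)
    theta0: float = 1.742
    tau0: float = 0.873
    s_lj: float = 1.0
    s_theta: float = 200.0
    s_tau: float = 8.0
    # derived; recomputed in __post_init__ unless explicitly overridden
    vc: float = field(default=None)  # type: ignore[assignment]
    s_fene: float = field(default=None)  # type: ignore[assignment]
    #: include |i-j| == 1 pairs in the LJ sums (off: bonded pairs interact
    #: through FENE only)
    include_bonded_lj: bool = False

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and 0 < self.R < self.r0):
            raise ValueError("require r0 > 0 and 0 < R < r0")
        if not self.rc > self.sigma:
            raise ValueError("require rc > sigma")
        if self.s_tau <= 0:
            raise ValueError("require s_tau > 0")
        sr = self.sigma / self.rc
        object.__setattr__(self, "vc", 4.0 * (sr**12 - sr**6))
        if self.s_fene is None:
            object.__setattr__(
                self, "s_fene", -(98.0 / 5.0) * self.r0**2 * self.R**2 / 2.0
            )

    def with_s_tau(self, s_tau: float) -> "ModelParameters":
        """Copy of the parameters with a different torsion scale."""
        return replace(self, s_tau=s_tau)


DEFAULT_PARAMS = ModelParameters()


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------

def bond_stretch_energy(r: float, p: ModelParameters = DEFAULT_PARAMS) -> float:
    """Unscaled FENE bond energy ``log(1 - ((r - r0)/R)^2)``.

    Zero at ``r = r0`` and negative elsewhere; diverges to -inf at the
    domain boundary.  Raises :class:`FeneDomainError` for ``|r - r0| >= R``
    (the move layer must reject such proposals before scoring them).
    """
    x = (r - p.r0) / p.R
    if abs(x) >= 1.0:
        raise FeneDomainError(f"bond length {r} outside FENE domain r0 +/- R")
    return math.log1p(-x * x)


def nonbonded_pair_energy(r: float, p: ModelParameters = DEFAULT_PARAMS) -> float:
    """Truncated-shifted LJ energy: ``4[(sigma/r)^12 - (sigma/r)^6] - vc``
    for ``r < rc``, exactly 0 for ``r >= rc``."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= p.rc:
        return 0.0
    s6 = (p.sigma / r) ** 6
    return 4.0 * (s6 * s6 - s6) - p.vc


def bend_energy(theta: float, p: ModelParameters = DEFAULT_PARAMS) -> float:
    """Unscaled bending energy ``1 - cos(theta - theta0)``, in [0, 2]."""
    return 1.0 - math.cos(theta - p.theta0)


def torsion_energy(tau: float, p: ModelParameters = DEFAULT_PARAMS) -> float:
    """Unscaled torsion energy ``1 - cos(tau - tau0)``.

    Not symmetric under ``tau -> -tau``: the model is chiral and favours
    one helix handedness.
    """
    return 1.0 - math.cos(tau - p.tau0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def bending_angle(a, b, c) -> float:
    """Angle in [0, pi] between bond vectors ``b - a`` and ``c - b``.

    A straight chain gives 0; a hairpin reversal gives pi.  (This is the
    bond-vector convention; the interior angle at ``b`` is its supplement.)
    """
    u = np.asarray(b, float) - np.asarray(a, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length bond in bending angle")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cos))


def dihedral_angle(a, b, c, d) -> float:
    """Signed dihedral angle in (-pi, pi] for four consecutive monomers.

    Uses the standard atan2 convention on the two plane normals; the sign
    follows the handedness of the triple, so mirror-imaging a conformation
    negates every dihedral.  Right-handed helices have positive dihedrals.
    """
    b1 = np.asarray(b, float) - np.asarray(a, float)
    b2 = np.asarray(c, float) - np.asarray(b, float)
    b3 = np.asarray(d, float) - np.asarray(c, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise DegenerateGeometryError("degenerate geometry in dihedral")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = math.atan2(y, x)
    if ang <= -math.pi:
        ang += 2.0 * math.pi
    return ang


def validate_conformation(coords: np.ndarray, p: ModelParameters = DEFAULT_PARAMS) -> np.ndarray:
    """Check shape (N, 3) with N >= 2 and every bond inside the FENE domain."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("conformation must be an (N, 3) array with N >= 2")
    r = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(np.abs(r - p.r0) >= p.R):
        raise FeneDomainError("bond outside FENE domain")
    return coords


# ---------------------------------------------------------------------------
# total energy and order parameter
# ---------------------------------------------------------------------------

def energy_terms(coords: np.ndarray, p: ModelParameters = DEFAULT_PARAMS):
    """Unscaled term sums ``(fene, lj, bend, torsion)`` of a conformation.

    Vectorised NumPy implementation; the sampler uses an equivalent
    compiled kernel (their agreement is asserted in the test suite).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    bonds = np.diff(coords, axis=0)
    r_bond = np.linalg.norm(bonds, axis=1)
    x = (r_bond - p.r0) / p.R
    if np.any(np.abs(x) >= 1.0):
        raise FeneDomainError("bond outside FENE domain")
    e_fene = float(np.sum(np.log1p(-x * x)))

    # LJ over non-bonded pairs (optionally including bonded ones)
    min_sep = 1 if p.include_bonded_lj else 2
    e_lj = 0.0
    if n > min_sep:
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=-1))
        i, j = np.triu_indices(n, k=min_sep)
        d = dist[i, j]
        inside = d < p.rc
        if np.any(inside):
            s6 = (p.sigma / d[inside]) ** 6
            e_lj = float(np.sum(4.0 * (s6 * s6 - s6) - p.vc))

    e_bend = 0.0
    if n >= 3:
        u = bonds[:-1]
        v = bonds[1:]
        cos = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        theta = np.arccos(np.clip(cos, -1.0, 1.0))
        e_bend = float(np.sum(1.0 - np.cos(theta - p.theta0)))

    e_tor = 0.0
    if n >= 4:
        b1, b2, b3 = bonds[:-2], bonds[1:-1], bonds[2:]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        xs = np.sum(n1 * n2, axis=1)
        ys = np.sum(np.cross(n1, n2) * b2, axis=1) / np.linalg.norm(b2, axis=1)
        tau = np.arctan2(ys, xs)
        e_tor = float(np.sum(1.0 - np.cos(tau - p.tau0)))

    return e_fene, e_lj, e_bend, e_tor


def total_energy(coords: np.ndarray, p: ModelParameters = DEFAULT_PARAMS) -> float:
    """Total Hamiltonian: scaled sum of FENE, LJ, bending and torsion terms.

    Invariant under rigid translations and rotations of the conformation.
    """
    e_fene, e_lj, e_bend, e_tor = energy_terms(coords, p)
    return p.s_fene * e_fene + p.s_lj * e_lj + p.s_theta * e_bend + p.s_tau * e_tor


def order_parameter_q(coords: np.ndarray, p: ModelParameters = DEFAULT_PARAMS) -> float:
    """Helix-bundling order parameter.

    Ratio of the summed truncated-shifted LJ energy over long-range pairs
    (``|i - j| > 6``) to that over short-range non-bonded pairs
    (``2 <= |i - j| <= 6``).  Single helices have q near 0.01 (essentially
    no long-range contacts); two-helix bundles sit near 0.35.  Returns 0
    when the denominator vanishes (e.g. fully extended chains or N <= 7).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        return 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    i, j = np.triu_indices(n, k=2)
    d = dist[i, j]
    sep = j - i
    s6 = np.where(d < p.rc, (p.sigma / np.maximum(d, 1e-300)) ** 6, 0.0)
    vlj = np.where(d < p.rc, 4.0 * (s6 * s6 - s6) - p.vc, 0.0)
    num = float(np.sum(vlj[sep > 6]))
    den = float(np.sum(vlj[sep <= 6]))
    if abs(den) < EPS_Q:
        return 0.0
    return num / den + 0.0


# ---------------------------------------------------------------------------
# XYZ snapshot I/O
# ---------------------------------------------------------------------------

def write_xyz(path, coords: np.ndarray, comment: str = "", append: bool = False) -> None:
    """Write a conformation as a plain XYZ frame (element tag "C")."""
    coords = np.asarray(coords, dtype=float)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{coords.shape[0]}\n{comment}\n")
        for x, y, z in coords:
            fh.write(f"C {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path) -> tuple[np.ndarray, str]:
    """Read the first frame of an XYZ file; returns (coords, comment)."""
    with open(path) as fh:
        n = int(fh.readline())
        comment = fh.readline().rstrip("\n")
        rows = []
        for _ in range(n):
            parts = fh.readline().split()
            rows.append([float(v) for v in parts[1:4]])
    return np.asarray(rows, dtype=float), comment
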
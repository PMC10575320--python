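"""Multiple-histogram reweighting to the density of states.

Canonical energy histograms ``h_i(E)`` from threads at inverse
temperatures ``beta_i`` (all sharing one Hamiltonian) are combined into a
single density of states

    g(E) = sum_i h_i(E) / sum_i M_i Z_i^{-1} e^{-beta_i E}
    Z_i  = sum_E g(E) e^{-beta_i E}

iterated from Z_i = 1 until the partition-function estimates converge.
All arithmetic runs in log space (log-sum-exp); the returned ``log_g`` is
gauge-fixed to 0 at the most-populated bin.  The same machinery yields
the joint density of states ``g(E, q)`` — the reweighting factors depend
on E only — and canonical quantities are recovered by back-reweighting:
``h(E) = g(E) e^{-beta E}``, the mean energy, and the specific heat
``C_V = dE/dT``.

Threads at different ``s_tau`` sample different Hamiltonians and must be
reweighted separately, one density of states per ``s_tau``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .sampler import EnergyHistogram, JointHistogram

__all__ = [
    "DensityOfStates",
    "PartitionFunctionSet",
    "WhamWarning",
    "single_histogram_dos",
    "wham",
    "wham_2d",
    "canonical_energy_histogram",
    "mean_energy_and_specific_heat",
]


class WhamWarning(UserWarning):
    pass


@dataclass
class DensityOfStates:
    """log g on a fixed uniform energy grid (optionally energy x q).

    ``log_g`` is -inf off the support; the additive gauge constant is
    fixed so that ``log_g = 0`` at ``gauge_index`` (1D) or at the
    corresponding marginal bin (2D).
    """

    energies: np.ndarray
    log_g: np.ndarray
    gauge_index: int
    support: np.ndarray
    q_values: np.ndarray | None = None
    converged: bool = True
    iterations: int = 0

    @property
    def is_2d(self) -> bool:
        return self.log_g.ndim == 2

    def marginal(self) -> "DensityOfStates":
        """q-marginal of a 2D density of states (gauge re-fixed)."""
        if not self.is_2d:
            return self
        with np.errstate(divide="ignore"):
            log_g = logsumexp(self.log_g, axis=1)
        log_g = log_g - log_g[self.gauge_index]
        return DensityOfStates(
            self.energies, log_g, self.gauge_index,
            np.isfinite(log_g), None, self.converged, self.iterations,
        )


@dataclass
class PartitionFunctionSet:
    betas: np.ndarray
    log_z: np.ndarray


def _check_shared_edges(histograms):
    edges = histograms[0].edges
    for h in histograms[1:]:
        if len(h.edges) != len(edges) or not np.allclose(h.edges, edges):
            raise ValueError("histograms must share bin edges")
    return edges


def single_histogram_dos(h: EnergyHistogram) -> DensityOfStates:
    """Single-thread estimate ``g(E) = h(E) e^{beta E}``, gauge-fixed at
    the most-populated bin."""
    counts = np.asarray(h.counts, float)
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    centers = h.centers
    with np.errstate(divide="ignore"):
        log_g = np.where(counts > 0, np.log(counts) + h.beta * centers, -np.inf)
    gauge = int(np.argmax(counts))
    log_g = log_g - log_g[gauge]
    return DensityOfStates(centers, log_g, gauge, counts > 0)


def wham(
    histograms: list[EnergyHistogram],
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> tuple[DensityOfStates, PartitionFunctionSet, int]:
    """Iterate the multiple-histogram equations to convergence.

    Starts from ``Z_i = 1`` and alternates the density-of-states and
    partition-function updates entirely in log space until
    ``max_i |dlog Z_i| < tol`` or ``max_iter``.  Returns the gauge-fixed
    density of states, the per-thread log partition functions, and the
    iteration count.  A disconnected union support raises; non-overlap
    between some adjacent pair and non-convergence are warnings.
    """
    edges = _check_shared_edges(histograms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.asarray(h.counts, float) for h in histograms])
    betas = np.array([h.beta for h in histograms])
    m_i = counts.sum(axis=1)
    if np.any(m_i == 0):
        raise ValueError("empty histogram in WHAM input")

    support = counts.sum(axis=0) > 0
    idx = np.flatnonzero(support)
    if np.any(np.diff(idx) > 1):
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        largest = max(len(r) for r in runs)
        # isolated populated bins in the far tails are routine; warn only
        # when the support is substantially fragmented
        if largest < 0.8 * len(idx):
            warnings.warn(
                "union support is fragmented (largest contiguous run covers "
                f"{largest}/{len(idx)} populated bins)",
                WhamWarning,
            )
    # overlap check between the supports of temperature-adjacent histograms
    order = np.argsort(-betas)
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            warnings.warn(
                "adjacent-temperature histograms do not overlap; "
                "WHAM results may be unreliable",
                WhamWarning,
            )
            break

    with np.errstate(divide="ignore"):
        log_counts_sum = np.where(
            support, np.log(counts.sum(axis=0)), -np.inf
        )
    log_m = np.log(m_i)
    log_z = np.zeros(len(histograms))
    be = betas[:, None] * centers[None, :]  # (threads, bins)

    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        # log denominator: sum_i M_i Z_i^-1 e^{-beta_i E}
        log_denom = logsumexp(
            log_m[:, None] - log_z[:, None] - be, axis=0
        )
        log_g = log_counts_sum - log_denom
        new_log_z = logsumexp(
            np.where(support[None, :], log_g[None, :] - be, -np.inf), axis=1
        )
        # fix the gauge of Z to keep the iteration anchored
        new_log_z = new_log_z - new_log_z[0]
        delta = np.max(np.abs(new_log_z - log_z))
        log_z = new_log_z
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last dlogZ = {delta:.2e})",
            WhamWarning,
        )

    log_denom = logsumexp(log_m[:, None] - log_z[:, None] - be, axis=0)
    log_g = log_counts_sum - log_denom
    gauge = int(np.argmax(counts.sum(axis=0)))
    log_g = log_g - log_g[gauge]
    dos = DensityOfStates(centers, log_g, gauge, support,
                          converged=converged, iterations=it)
    return dos, PartitionFunctionSet(betas, log_z), it


def wham_2d(
    joint_histograms: list[JointHistogram],
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> DensityOfStates:
    """Joint density of states g(E, q).

    The reweighting factors depend on E only, so the converged partition
    functions from the 1D solve on the marginal histograms are reused;
    this makes the q-marginal of the result agree with the 1D density of
    states by construction.
    """
    marginals = [h.marginal() for h in joint_histograms]
    dos1d, zset, _ = wham(marginals, tol=tol, max_iter=max_iter)
    edges = _check_shared_edges(joint_histograms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array(
        [np.asarray(h.counts, float) for h in joint_histograms]
    )  # (threads, nE, nq)
    betas = np.array([h.beta for h in joint_histograms])
    log_m = np.log(counts.sum(axis=(1, 2)))
    be = betas[:, None] * centers[None, :]
    log_denom = logsumexp(
        log_m[:, None] - zset.log_z[:, None] - be, axis=0
    )  # (nE,)
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore"):
        log_counts = np.where(total > 0, np.log(total), -np.inf)
    log_g = log_counts - log_denom[:, None]
    # gauge: same energy bin as the 1D solve, pinned on the marginal
    with np.errstate(divide="ignore"):
        marg = logsumexp(log_g, axis=1)
    log_g = log_g - marg[dos1d.gauge_index]
    q_centers = joint_histograms[0].q_centers
    return DensityOfStates(
        centers, log_g, dos1d.gauge_index, total > 0, q_centers,
        dos1d.converged, dos1d.iterations,
    )


def canonical_energy_histogram(dos: DensityOfStates, beta: float) -> np.ndarray:
    """Normalized canonical bin weights ``h(E) propto g(E) e^{-beta E}``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if dos.is_2d:
        dos = dos.marginal()
    with np.errstate(divide="ignore"):
        log_w = np.where(dos.support, dos.log_g - beta * dos.energies, -np.inf)
    log_w = log_w - logsumexp(log_w)
    return np.exp(log_w)


def mean_energy_and_specific_heat(
    dos: DensityOfStates, temperatures: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical mean energy and specific heat on a temperature grid.

    Mean energy is the canonical bin-weighted average; C_V is the centred
    finite difference of the mean energy over T.  The fluctuation form
    ``(<E^2> - <E>^2)/T^2`` is computed alongside and the two are checked
    to agree within finite-differencing error.
    """
    temperatures = np.asarray(temperatures, float)
    if np.any(temperatures <= 0):
        raise ValueError("temperatures must be positive")
    e_mean = np.empty_like(temperatures)
    e_var = np.empty_like(temperatures)
    for k, t in enumerate(temperatures):
        w = canonical_energy_histogram(dos, 1.0 / t)
        e_mean[k] = np.sum(w * dos.energies)
        e_var[k] = np.sum(w * dos.energies**2) - e_mean[k] ** 2
    c_v = np.gradient(e_mean, temperatures)
    c_fluct = e_var / temperatures**2
    # agreement within O(dT^2) differencing error (interior points)
    dt = np.max(np.diff(temperatures))
    scale = max(np.max(np.abs(c_fluct)), 1.0)
    if len(temperatures) > 4:
        mism = np.max(np.abs(c_v[2:-2] - c_fluct[2:-2])) / scale
        if mism > max(50.0 * dt**2, 0.05):
            warnings.warn(
                f"finite-difference and fluctuation C_V disagree "
                f"(relative {mism:.3g}); refine the temperature grid",
                WhamWarning,
            )
    return e_mean, c_v
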
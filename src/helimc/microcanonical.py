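"""Microcanonical entropy and inflection-point transition analysis.

The microcanonical entropy is ``S(E) = log g(E)`` (``kB = 1``).  In a
finite system an n-th order transition appears as a region of least
sensitivity in the (n-1)-th derivative of S:

* first order — backbending of ``beta = dS/dE`` (an interval with
  ``dbeta/dE > 0``);
* second order — a local maximum of ``gamma = d2S/dE2`` that approaches
  zero from below without crossing (equivalently a zero-crossing of
  ``delta = d3S/dE3``);
* third order — a positive local minimum of ``delta`` dipping toward
  zero (an "inverted peak");
* fourth order — a sub-zero local maximum of ``d4S/dE4``.

S and its derivatives are estimated in a single pass with a
Savitzky-Golay filter, so every curve is produced by the same smoothing
operator.  Detected candidates are screened by prominence relative to a
local baseline and assigned lowest order first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .reweight import DensityOfStates

__all__ = [
    "EntropyCurves",
    "TransitionRecord",
    "entropy_from_dos",
    "smooth_derivatives",
    "detect_transitions",
    "analyze_dos",
]

DEFAULT_WINDOW = 51
DEFAULT_POLYORDER = 4
#: an extremum "approaches zero without crossing" when its magnitude is
#: below this fraction of the local baseline magnitude
APPROACH_FRACTION = 0.9


@dataclass
class EntropyCurves:
    """S and its smoothed derivatives on a shared energy grid."""

    energies: np.ndarray
    s: np.ndarray
    beta: np.ndarray = None
    gamma: np.ndarray = None
    delta: np.ndarray = None
    s4: np.ndarray = None
    window: int = 0
    polyorder: int = 0
    trimmed: tuple = (0, 0)

    @property
    def bin_width(self) -> float:
        return float(self.energies[1] - self.energies[0])


@dataclass
class TransitionRecord:
    """One detected transition."""

    energy: float
    order: int
    channel: str
    prominence: float
    s_tau: float = np.nan
    n: int = 0


def entropy_from_dos(
    dos: DensityOfStates,
    edge_trim: int = 2,
    counts: np.ndarray | None = None,
    min_count: int = 20,
) -> EntropyCurves:
    """Entropy on the largest contiguous support run of the density of
    states, with ``edge_trim`` sparse edge bins dropped from each end.

    When the aggregate per-bin sample ``counts`` are available, bins with
    fewer than ``min_count`` samples are additionally excluded before the
    contiguous run is taken: the relative error of log g in a bin scales
    like 1/sqrt(count), and derivative estimation amplifies that noise.
    """
    if dos.is_2d:
        dos = dos.marginal()
    finite = np.isfinite(dos.log_g) & dos.support
    if counts is not None:
        finite &= np.asarray(counts) >= min_count
    if not np.any(finite):
        raise ValueError("density of states has empty support")
    # largest contiguous run
    idx = np.flatnonzero(finite)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    run = max(splits, key=len)
    lo, hi = run[0] + edge_trim, run[-1] + 1 - edge_trim
    if hi - lo < 5:
        raise ValueError("contiguous support too short for analysis")
    return EntropyCurves(
        dos.energies[lo:hi], dos.log_g[lo:hi].astype(float),
        trimmed=(int(lo), int(len(dos.log_g) - hi)),
    )


def smooth_derivatives(
    curves: EntropyCurves,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> EntropyCurves:
    """Fill S (smoothed) and derivatives 1-4 with one Savitzky-Golay pass.

    The window auto-shrinks to the largest valid odd length when the
    support is shorter than requested; near the support edges the filter
    falls back to a polynomial fit of the edge window.  Polynomials of
    degree <= ``polyorder`` are differentiated exactly in the interior.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if polyorder < 4:
        raise ValueError("polyorder >= 4 required to form the 4th derivative")
    m = len(curves.s)
    if window > m:
        window = m if m % 2 == 1 else m - 1
        if window <= polyorder:
            raise ValueError("support too short for the smoothing window")
    d = curves.bin_width
    out = [
        savgol_filter(curves.s, window, polyorder, deriv=k, delta=d,
                      mode="interp")
        for k in range(5)
    ]
    return EntropyCurves(
        curves.energies, out[0], out[1], out[2], out[3], out[4],
        window=window, polyorder=polyorder, trimmed=curves.trimmed,
    )


def _local_baseline(values: np.ndarray, i: int, window: int) -> float:
    """Median of ``values`` over +-5 window-lengths around i, excluding the
    +-window/2 core of the feature itself.

    The statistic is local because the magnitude of the entropy
    derivatives varies by orders of magnitude across the support; a global
    baseline would drown subtle high-energy features under the large
    low-energy values.
    """
    m = len(values)
    half = 5 * window
    core = max(window // 2, 2)
    lo, hi = max(0, i - half), min(m, i + half + 1)
    sel = np.r_[values[lo:max(lo, i - core)], values[min(hi, i + core + 1):hi]]
    if len(sel) == 0:
        sel = values[lo:hi]
    return float(np.median(sel))


def _local_noise(detrended: np.ndarray, i: int, window: int) -> float:
    """MAD of the detrended channel over +-5 window-lengths around i.

    Detrending (subtracting a running-median trend) separates bin-scale
    statistical noise from the smooth physical structure of the channel,
    so a broad genuine feature does not inflate its own noise estimate.
    """
    m = len(detrended)
    half = 5 * window
    lo, hi = max(0, i - half), min(m, i + half + 1)
    sel = detrended[lo:hi]
    med = float(np.median(sel))
    return float(np.median(np.abs(sel - med)))


def _mad(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med)))


def _local_extrema(values: np.ndarray, kind: str, guard: int) -> np.ndarray:
    """Indices of strict local maxima/minima, at least ``guard`` bins from
    the ends."""
    v = values
    if kind == "max":
        mask = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    else:
        mask = (v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:])
    idx = np.flatnonzero(mask) + 1
    return idx[(idx >= guard) & (idx < len(v) - guard)]


def detect_transitions(
    curves: EntropyCurves,
    prominence_threshold: float | None = None,
    approach_fraction: float = APPROACH_FRACTION,
    beta_range: tuple | None = None,
) -> list[TransitionRecord]:
    """Inflection-point classification of the entropy derivatives.

    Candidates are collected lowest order first and each is assigned to
    exactly one order; a higher-order candidate within five smoothing
    windows of an accepted lower-order transition is discarded as the
    flank echo of the same feature seen one derivative up.
    ``prominence_threshold`` defaults to 3x the local median absolute
    deviation of the detrended derivative channel.  Transition-free
    curves return an empty list.
    """
    if curves.beta is None:
        raise ValueError("call smooth_derivatives first")
    # histogram reweighting interpolates between sampled temperatures;
    # where the microcanonical beta leaves the simulated ladder the
    # density of states is an extrapolation and its derivatives are not
    # trustworthy, so candidates there are excluded
    reliable = None
    if beta_range is not None:
        lo, hi = min(beta_range), max(beta_range)
        reliable = (curves.beta >= lo) & (curves.beta <= hi)
    window = max(curves.window, 5)
    # the edge windows are pure polynomial extrapolation fits; candidates
    # within one full window of the support edge are not trustworthy
    guard = max(window, 5)
    records: list[TransitionRecord] = []

    def excluded(i: int) -> bool:
        return reliable is not None and not reliable[i]

    def occupied(i: int) -> bool:
        # a localized feature in one channel echoes in the higher
        # derivatives over several widths of its flanks; suppress
        # higher-order candidates within the local-baseline neighborhood
        # of an accepted lower-order record
        e = curves.energies[i]
        return any(
            abs(e - r.energy) < 5 * window * curves.bin_width for r in records
        )

    from scipy.ndimage import median_filter

    beta_scale = float(np.max(np.abs(curves.beta)))

    def detrend(channel):
        return channel - median_filter(channel, size=window, mode="nearest")

    def threshold(channel: np.ndarray, local_mad: float, level: int) -> float:
        if prominence_threshold is not None:
            return prominence_threshold
        # 3x the local MAD, floored so float-level ripples never register:
        # one floor on the channel's own scale, one tied to the beta scale
        # propagated through ``level-1`` further differentiations (guards
        # channels that are analytically zero, where the own-scale floor
        # collapses)
        scale = float(np.max(np.abs(channel))) if len(channel) else 0.0
        cross = 1e-10 * beta_scale / curves.bin_width ** (level - 1)
        return max(3.0 * local_mad, 1e-3 * scale, cross)

    # --- first order: backbending regions of beta (gamma > 0) ---
    gamma = curves.gamma
    gamma_noise = detrend(gamma)
    pos = gamma > 0
    pos[:guard] = False
    pos[-guard:] = False
    if np.any(pos):
        idx = np.flatnonzero(pos)
        for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
            if len(run) < 2:
                continue
            i = run[np.argmax(gamma[run])]
            if excluded(i):
                continue
            prom = float(gamma[i])
            mad = _local_noise(gamma_noise, i, window)
            if prom >= threshold(gamma, mad, 2) and not occupied(i):
                records.append(TransitionRecord(
                    float(curves.energies[i]), 1, "beta", prom,
                ))

    # --- second order: sub-zero local maxima of gamma ---
    for i in _local_extrema(gamma, "max", guard):
        if gamma[i] >= 0 or excluded(i):
            continue  # backbending is handled as first order
        base = _local_baseline(gamma, i, window)
        mad = _local_noise(gamma_noise, i, window)
        prom = float(gamma[i] - base)
        if (
            prom >= threshold(gamma, mad, 2)
            and abs(gamma[i]) < approach_fraction * abs(base)
            and not occupied(i)
        ):
            records.append(TransitionRecord(
                float(curves.energies[i]), 2, "gamma", prom,
            ))

    # --- third order: positive local minima of delta ---
    delta = curves.delta
    delta_noise = detrend(delta)
    for i in _local_extrema(delta, "min", guard):
        if delta[i] <= 0 or excluded(i):
            continue
        base = _local_baseline(delta, i, window)
        mad = _local_noise(delta_noise, i, window)
        prom = float(base - delta[i])
        if (
            prom >= threshold(delta, mad, 3)
            and abs(delta[i]) < approach_fraction * abs(base)
            and not occupied(i)
        ):
            records.append(TransitionRecord(
                float(curves.energies[i]), 3, "delta", prom,
            ))

    # --- fourth order: sub-zero local maxima of the fourth derivative ---
    s4 = curves.s4
    s4_noise = detrend(s4)
    for i in _local_extrema(s4, "max", guard):
        if s4[i] >= 0 or excluded(i):
            continue
        base = _local_baseline(s4, i, window)
        mad = _local_noise(s4_noise, i, window)
        prom = float(s4[i] - base)
        if (
            prom >= threshold(s4, mad, 4)
            and abs(s4[i]) < approach_fraction * abs(base)
            and not occupied(i)
        ):
            records.append(TransitionRecord(
                float(curves.energies[i]), 4, "s4", prom,
            ))

    records.sort(key=lambda r: r.energy)
    return records


def analyze_dos(
    dos: DensityOfStates,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    prominence_threshold: float | None = None,
    edge_trim: int = 2,
    s_tau: float = np.nan,
    n: int = 0,
    counts: np.ndarray | None = None,
    min_count: int = 20,
    beta_range: tuple | None = None,
):
    """End-to-end: entropy, smoothed derivatives, detected transitions."""
    curves = smooth_derivatives(
        entropy_from_dos(dos, edge_trim, counts, min_count), window, polyorder
    )
    recs = detect_transitions(curves, prominence_threshold, beta_range=beta_range)
    for r in recs:
        r.s_tau = s_tau
        r.n = n
    return curves, recs
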
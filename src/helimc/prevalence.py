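"""Two-dimensional structural prevalence p(E, q).

``p(E, q) = g(E, q) / g(E)`` gives, for each microcanonical energy slice,
the normalized distribution of the bundling order parameter q: the
fraction of structures at energy E that live in each q bin.  Low-energy
two-helix bundles sit near q = 0.35, single helices near q = 0.01, and
the curves at intermediate q expose how strongly intermediate structures
are entropically suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .reweight import DensityOfStates

__all__ = ["PrevalenceField", "prevalence_field", "q_cross_sections"]


@dataclass
class PrevalenceField:
    energies: np.ndarray
    q_values: np.ndarray
    p: np.ndarray  # (nE, nq), rows sum to 1 on populated columns
    mask: np.ndarray  # True where the (E, q) cell is unpopulated

    def column_populated(self) -> np.ndarray:
        """True for energy rows with any populated q bin."""
        return ~self.mask.all(axis=1)


def prevalence_field(dos2d: DensityOfStates) -> PrevalenceField:
    """Normalize the joint density of states along q.

    The normalizer g(E) is the q-marginal of g(E, q), which makes every
    populated energy slice sum to exactly 1; unpopulated cells are masked
    (they carry no value, not zero counts of probability).
    """
    if not dos2d.is_2d:
        raise ValueError("prevalence requires a 2D density of states")
    log_g = dos2d.log_g
    mask = ~(np.isfinite(log_g) & dos2d.support)
    with np.errstate(divide="ignore"):
        norm = logsumexp(np.where(mask, -np.inf, log_g), axis=1)
    p = np.zeros_like(log_g, dtype=float)
    populated = np.isfinite(norm)
    p[populated] = np.exp(log_g[populated] - norm[populated, None])
    p[mask] = 0.0
    return PrevalenceField(dos2d.energies, dos2d.q_values, p, mask)


def q_cross_sections(
    field: PrevalenceField, q_values
) -> list[dict]:
    """Prevalence curves p(E) at the q bins nearest the requested values.

    Returns one record per request with the requested q, the bin center
    actually used, the curve, and a flag for fully masked columns.
    """
    out = []
    for q in np.atleast_1d(np.asarray(q_values, float)):
        if q < field.q_values[0] - 1e-12 or q > field.q_values[-1] + 1e-12:
            raise ValueError(f"q={q} outside the q grid")
        j = int(np.argmin(np.abs(field.q_values - q)))
        curve = field.p[:, j].copy()
        col_mask = field.mask[:, j]
        out.append(
            {
                "q_requested": float(q),
                "q_bin": float(field.q_values[j]),
                "energies": field.energies,
                "p": curve,
                "mask": col_mask,
                "empty": bool(col_mask.all()),
            }
        )
    return out
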
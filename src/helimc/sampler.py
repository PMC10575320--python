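"""Two-dimensional replica-exchange Metropolis sampling.

A grid of Metropolis threads spans a geometric temperature ladder
(vertical axis) and a ladder of torsion scales ``s_tau`` (horizontal,
Hamiltonian axis).  Every ``exchange_interval`` sweeps an exchange round
runs; rounds alternate between temperature-neighbour and
``s_tau``-neighbour pairs, with even/odd pairing alternating per round.
Exchanges swap conformations with the detailed-balance-preserving
probability

    P = min(1, exp[b_i H_i(X_i) + b_j H_j(X_j) - b_i H_i(X_j) - b_j H_j(X_i)])

which for a shared Hamiltonian reduces to ``min(1, exp[(b_i-b_j)(E_i-E_j)])``
and for the Hamiltonian axis requires only the torsion term sums, since
the Hamiltonians differ in ``s_tau`` alone.

Each thread accumulates a 1D energy histogram and a joint (E, q)
histogram, one deposit per sweep after burn-in; these are the inputs to
multiple-histogram reweighting (:mod:`helimc.reweight`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .model import DEFAULT_PARAMS, ModelParameters
from .fixtures import ideal_helix, random_coil

__all__ = [
    "SimulationSchedule",
    "ReplicaState",
    "EnergyHistogram",
    "JointHistogram",
    "GridResult",
    "geometric_ladder",
    "build_schedule",
    "run_thread_sweeps",
    "exchange_probability",
    "run_grid",
]


def geometric_ladder(t_min: float, t_max: float, k: int) -> np.ndarray:
    """Exponentially spaced temperatures: successive values differ by the
    same factor ``(t_max/t_min)^(1/(k-1))``."""
    if not (t_min < t_max and k >= 2):
        raise ValueError("need t_min < t_max and k >= 2")
    return t_min * (t_max / t_min) ** (np.arange(k) / (k - 1))


@dataclass(frozen=True)
class SimulationSchedule:
    """Everything that defines a reproducible grid run."""

    n: int = 30
    temperatures: np.ndarray = field(
        default_factory=lambda: geometric_ladder(0.2, 1.6, 16)
    )
    s_tau_values: np.ndarray = field(
        default_factory=lambda: np.linspace(5.0, 14.0, 10)
    )
    sweeps: int = 50_000
    burn_in: int = 10_000
    exchange_interval: int = 10
    move_mix: tuple = (0.7, 0.1, 0.1, 0.1)
    local_step: float = 0.3
    rot_max: float = 0.5
    seed: int = 0
    e_min: float = -100.0
    e_max: float = 100.0
    e_bin: float = 0.1
    q_min: float = -0.1
    q_max: float = 1.1
    q_bin: float = 0.02
    exchange_axes: tuple = ("temperature", "s_tau")
    init: str = "helix"
    params: ModelParameters = DEFAULT_PARAMS

    def __post_init__(self):
        t = np.asarray(self.temperatures, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval >= 1 required")
        if not (self.sweeps > self.burn_in >= 0):
            raise ValueError("need sweeps > burn_in >= 0")
        if abs(sum(self.move_mix) - 1.0) > 1e-9 or min(self.move_mix) < 0:
            raise ValueError("move_mix must be non-negative and sum to 1")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(
            self, "s_tau_values", np.asarray(self.s_tau_values, float)
        )

    @property
    def n_threads(self) -> int:
        return len(self.temperatures) * len(self.s_tau_values)

    @property
    def e_edges(self) -> np.ndarray:
        nb = int(round((self.e_max - self.e_min) / self.e_bin))
        return self.e_min + self.e_bin * np.arange(nb + 1)

    @property
    def q_edges(self) -> np.ndarray:
        nb = int(round((self.q_max - self.q_min) / self.q_bin))
        return self.q_min + self.q_bin * np.arange(nb + 1)


def build_schedule(config: dict | None = None, **overrides) -> SimulationSchedule:
    """Build a schedule from a flat configuration mapping.

    Recognised keys mirror :class:`SimulationSchedule` fields, plus the
    ladder shorthand ``t_min``/``t_max``/``n_temperatures`` and
    ``s_tau_min``/``s_tau_max``/``n_s_tau``.  Omitted keys fall back to
    the N=30 defaults (16 temperatures in [0.2, 1.6], 10 torsion scales in
    [5, 14]).
    """
    cfg = dict(config or {})
    cfg.update(overrides)
    known = set(SimulationSchedule.__dataclass_fields__)
    ladder_keys = {
        "t_min", "t_max", "n_temperatures", "s_tau_min", "s_tau_max", "n_s_tau"
    }
    unknown = set(cfg) - known - ladder_keys
    if unknown:
        raise ValueError(f"unknown schedule keys: {sorted(unknown)}")
    if ladder_keys & set(cfg):
        t_min = cfg.pop("t_min", 0.2)
        t_max = cfg.pop("t_max", 1.6)
        k = cfg.pop("n_temperatures", 16)
        cfg.setdefault("temperatures", geometric_ladder(t_min, t_max, k))
        s_lo = cfg.pop("s_tau_min", 5.0)
        s_hi = cfg.pop("s_tau_max", 14.0)
        ks = cfg.pop("n_s_tau", 10)
        cfg.setdefault("s_tau_values", np.linspace(s_lo, s_hi, ks))
    return SimulationSchedule(**cfg)


@dataclass
class EnergyHistogram:
    """Per-thread energy histogram with its sampling conditions."""

    beta: float
    s_tau: float
    edges: np.ndarray
    counts: np.ndarray
    underflow: int = 0
    overflow: int = 0

    @property
    def total(self) -> int:
        """Total in-range count M_i."""
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class JointHistogram(EnergyHistogram):
    """Joint (E, q) histogram; ``counts`` has shape (n_E, n_q)."""

    q_edges: np.ndarray = None

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])

    def marginal(self) -> EnergyHistogram:
        return EnergyHistogram(
            self.beta, self.s_tau, self.edges, self.counts.sum(axis=1),
            self.underflow, self.overflow,
        )


@dataclass
class ReplicaState:
    """One thread of the grid: conformation, cached energy decomposition,
    and its (temperature index, s_tau index) coordinates."""

    coords: np.ndarray
    energy: float
    torsion_sum: float
    it: int
    js: int


class GridResult:
    """Outputs of :func:`run_grid`, indexed by (i_temperature, i_s_tau)."""

    def __init__(self, schedule, hists, joints, exchange_attempts,
                 exchange_accepts, acc, att, final_states):
        self.schedule = schedule
        self.histograms = hists
        self.joint_histograms = joints
        self.exchange_attempts = exchange_attempts
        self.exchange_accepts = exchange_accepts
        self.move_accepts = acc
        self.move_attempts = att
        self.final_states = final_states

    def column(self, js: int) -> list[EnergyHistogram]:
        """All temperature histograms at one s_tau (one WHAM input set)."""
        return [self.histograms[(it, js)]
                for it in range(len(self.schedule.temperatures))]

    def joint_column(self, js: int) -> list[JointHistogram]:
        return [self.joint_histograms[(it, js)]
                for it in range(len(self.schedule.temperatures))]


def exchange_probability(
    beta_i, beta_j, e_i_of_xi, e_j_of_xj, e_i_of_xj, e_j_of_xi
) -> float:
    """Replica-exchange acceptance probability for threads with possibly
    different temperatures and Hamiltonians.

    Arguments are the four cross-evaluations H_i(X_i), H_j(X_j), H_i(X_j),
    H_j(X_i).  The exponent is clipped before exponentiation.
    """
    if beta_i <= 0 or beta_j <= 0:
        raise ValueError("betas must be positive")
    log_p = (
        beta_i * e_i_of_xi + beta_j * e_j_of_xj
        - beta_i * e_i_of_xj - beta_j * e_j_of_xi
    )
    return float(math.exp(min(0.0, log_p)))


def _thread_seed(master_seed: int, it: int, js: int, block: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(it, js, block))
    return int(ss.generate_state(1)[0] % 2**31)


def run_thread_sweeps(
    state: ReplicaState,
    n_sweeps: int,
    schedule: SimulationSchedule,
    seed: int,
):
    """Advance one replica by ``n_sweeps`` sweeps (N attempts each).

    Mutates ``state`` in place; returns per-sweep (E, q) sample arrays and
    per-kind (accepts, attempts) counters.
    """
    p = schedule.params.with_s_tau(schedule.s_tau_values[state.js])
    beta = 1.0 / schedule.temperatures[state.it]
    e_samp = np.empty(n_sweeps)
    q_samp = np.empty(n_sweeps)
    acc = np.zeros(4, np.int64)
    att = np.zeros(4, np.int64)
    if n_sweeps > 0:
        mix = schedule.move_mix
        energy, ef, el, eb, et = _kernels.run_block(
            state.coords, p.s_fene, p.s_lj, p.s_theta, p.s_tau, beta,
            p.r0, p.R, p.sigma, p.rc, p.vc, p.theta0, p.tau0,
            1 if p.include_bonded_lj else 2,
            n_sweeps, mix[0], mix[1], mix[2],
            schedule.local_step, schedule.rot_max,
            seed, e_samp, q_samp, acc, att,
        )
        if not np.isfinite(energy):
            raise FloatingPointError("non-finite energy in thread sweep")
        state.energy = energy
        state.torsion_sum = et
    return e_samp, q_samp, acc, att


def _bin_samples(e, q, sched, hist, joint):
    ei = np.floor((e - sched.e_min) / sched.e_bin).astype(np.int64)
    qi = np.floor((q - sched.q_min) / sched.q_bin).astype(np.int64)
    n_e = hist.counts.shape[0]
    n_q = joint.counts.shape[1]
    under_e = ei < 0
    over_e = ei >= n_e
    ok = ~(under_e | over_e)
    hist.underflow += int(under_e.sum())
    hist.overflow += int(over_e.sum())
    joint.underflow += int(under_e.sum())
    joint.overflow += int(over_e.sum())
    np.add.at(hist.counts, ei[ok], 1)
    qi = np.clip(qi, 0, n_q - 1)  # q range is generous; clamp edge spill
    np.add.at(joint.counts, (ei[ok], qi[ok]), 1)


def run_grid(schedule: SimulationSchedule, progress: bool = False) -> GridResult:
    """Run the full temperature x s_tau grid with replica exchange.

    Threads execute serially; results are a deterministic function of
    ``(schedule, schedule.seed)``.  Per-thread RNG streams are split with
    ``SeedSequence(seed, spawn_key=(i_T, i_s_tau, block))``; exchange
    decisions draw from their own stream.
    """
    sched = schedule
    n_t = len(sched.temperatures)
    n_s = len(sched.s_tau_values)
    betas = 1.0 / sched.temperatures

    init_rng = np.random.default_rng(np.random.SeedSequence(sched.seed, spawn_key=(9999,)))
    states = {}
    for it in range(n_t):
        for js in range(n_s):
            if sched.init == "helix":
                coords = ideal_helix(sched.n, sched.params)
            elif sched.init == "coil":
                coords = random_coil(sched.n, init_rng, sched.params)
            else:
                raise ValueError(f"unknown init '{sched.init}'")
            states[(it, js)] = ReplicaState(
                np.ascontiguousarray(coords), 0.0, 0.0, it, js
            )

    hists = {
        key: EnergyHistogram(
            betas[key[0]], sched.s_tau_values[key[1]], sched.e_edges,
            np.zeros(len(sched.e_edges) - 1, np.int64),
        )
        for key in states
    }
    joints = {
        key: JointHistogram(
            betas[key[0]], sched.s_tau_values[key[1]], sched.e_edges,
            np.zeros((len(sched.e_edges) - 1, len(sched.q_edges) - 1), np.int64),
            q_edges=sched.q_edges,
        )
        for key in states
    }
    acc_tot = {key: np.zeros(4, np.int64) for key in states}
    att_tot = {key: np.zeros(4, np.int64) for key in states}
    ex_att = {ax: 0 for ax in ("temperature", "s_tau")}
    ex_acc = {ax: 0 for ax in ("temperature", "s_tau")}
    ex_rng = np.random.default_rng(np.random.SeedSequence(sched.seed, spawn_key=(7777,)))

    total = sched.sweeps
    interval = sched.exchange_interval
    done = 0
    block = 0
    axes = sched.exchange_axes
    while done < total:
        n_sw = min(interval, total - done)
        for (it, js), st in states.items():
            e, q, acc, att = run_thread_sweeps(
                st, n_sw, sched, _thread_seed(sched.seed, it, js, block)
            )
            acc_tot[(it, js)] += acc
            att_tot[(it, js)] += att
            keep = max(0, sched.burn_in - done)
            if keep < n_sw:
                _bin_samples(e[keep:], q[keep:], sched,
                             hists[(it, js)], joints[(it, js)])
        done += n_sw
        if done >= total:
            break
        if axes:
            axis = axes[block % len(axes)]
            parity = (block // len(axes)) % 2
            _exchange_round(states, betas, sched, axis, parity,
                            ex_rng, ex_att, ex_acc)
        block += 1
        if progress:
            print(f"  sweeps {done}/{total}", flush=True)

    return GridResult(sched, hists, joints, ex_att, ex_acc,
                      acc_tot, att_tot, states)


def _exchange_round(states, betas, sched, axis, parity, rng, ex_att, ex_acc):
    n_t = len(sched.temperatures)
    n_s = len(sched.s_tau_values)
    s_vals = sched.s_tau_values
    if axis == "temperature":
        pairs = [
            ((it, js), (it + 1, js))
            for js in range(n_s)
            for it in range(parity, n_t - 1, 2)
        ]
    else:
        pairs = [
            ((it, js), (it, js + 1))
            for it in range(n_t)
            for js in range(parity, n_s - 1, 2)
        ]
    for a, b in pairs:
        sa, sb = states[a], states[b]
        beta_a, beta_b = betas[a[0]], betas[b[0]]
        # cross-Hamiltonian energies differ only through the torsion term
        ds_ab = s_vals[a[1]] - s_vals[b[1]]
        e_a_of_xb = sb.energy + ds_ab * sb.torsion_sum
        e_b_of_xa = sa.energy - ds_ab * sa.torsion_sum
        prob = exchange_probability(
            beta_a, beta_b, sa.energy, sb.energy, e_a_of_xb, e_b_of_xa
        )
        ex_att[axis] += 1
        if rng.random() < prob:
            ex_acc[axis] += 1
            sa.coords, sb.coords = sb.coords, sa.coords
            sa.energy, sb.energy = e_a_of_xb, e_b_of_xa
            sa.torsion_sum, sb.torsion_sum = sb.torsion_sum, sa.torsion_sum
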
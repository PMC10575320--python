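"""Schedules, replica threads, exchange rule, and grid runs."""

import math

import numpy as np
import pytest
from scipy import integrate

from helimc.fixtures import ideal_helix, study_grids
from helimc.model import DEFAULT_PARAMS as P
from helimc.sampler import (
    ReplicaState,
    build_schedule,
    exchange_probability,
    geometric_ladder,
    run_grid,
    run_thread_sweeps,
)


class TestSchedule:
    def test_two_point_ladder(self):
        np.testing.assert_allclose(geometric_ladder(0.2, 1.6, 2), [0.2, 1.6])

    def test_geometric_spacing_constant_ratio(self):
        t = geometric_ladder(0.2, 1.6, 16)
        ratios = t[1:] / t[:-1]
        assert np.all(np.abs(ratios - 8 ** (1 / 15)) < 1e-9)
        assert t[0] == pytest.approx(0.2) and t[-1] == pytest.approx(1.6)

    def test_default_grid_has_160_threads(self):
        sched = build_schedule()
        assert sched.n_threads == 160
        assert len(sched.temperatures) == 16
        assert len(sched.s_tau_values) == 10
        assert sched.s_tau_values[0] == 5.0 and sched.s_tau_values[-1] == 14.0

    def test_presets(self):
        g = study_grids()
        assert g["n30_full"].n_threads == 160
        assert g["n40_full"].s_tau_values[0] == 5.0
        assert g["n40_full"].s_tau_values[-1] == 25.0
        assert g["n40_full"].n == 40

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"temperatures": np.array([1.0, 0.5])},
            {"sweeps": 10, "burn_in": 10},
            {"exchange_interval": 0},
            {"move_mix": (0.5, 0.5, 0.5, 0.5)},
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_schedule(**kwargs)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="bogus"):
            build_schedule(bogus=1)


class TestExchangeProbability:
    def test_symmetric_swap_is_certain(self):
        assert exchange_probability(1.0, 1.0, -5.0, -5.0, -5.0, -5.0) == 1.0

    def test_same_hamiltonian_reduced_form(self):
        # min(1, exp[(b_i - b_j)(E_i - E_j)]) with b=(1.0, 0.5), E=(-10, -5)
        p = exchange_probability(1.0, 0.5, -10.0, -5.0, -5.0, -10.0)
        assert p == pytest.approx(math.exp(-2.5), rel=1e-12)

    def test_hamiltonian_axis_torsion_cancellation(self, rng):
        """For threads differing only in s_tau, the exponent computed from
        the four full energies reduces to beta * ds_tau * (tor_j - tor_i)."""
        from helimc.model import energy_terms, total_energy

        from conftest import random_valid_chain

        beta = 1.25
        s_i, s_j = 6.0, 9.0
        p_i, p_j = P.with_s_tau(s_i), P.with_s_tau(s_j)
        x_i = random_valid_chain(12, rng)
        x_j = random_valid_chain(12, rng)
        full = (
            beta * total_energy(x_i, p_i)
            + beta * total_energy(x_j, p_j)
            - beta * total_energy(x_j, p_i)
            - beta * total_energy(x_i, p_j)
        )
        tor_i = energy_terms(x_i, p_i)[3]
        tor_j = energy_terms(x_j, p_j)[3]
        algebraic = beta * (s_i - s_j) * (tor_i - tor_j)
        assert full == pytest.approx(algebraic, rel=1e-9, abs=1e-9)

    def test_log_space_no_overflow(self):
        assert exchange_probability(1.0, 2.0, -1e6, 1e6, 1e6, -1e6) == 1.0


def _dimer_state(it=0, js=0):
    coords = np.ascontiguousarray(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    return ReplicaState(coords, 0.0, 0.0, it, js)


class TestThreadSweeps:
    def test_zero_sweeps_is_identity(self):
        sched = build_schedule(n=2, sweeps=10, burn_in=0, n_temperatures=2,
                               n_s_tau=1)
        st = _dimer_state()
        before = st.coords.copy()
        run_thread_sweeps(st, 0, sched, 1)
        np.testing.assert_array_equal(st.coords, before)

    def test_seeded_reproducibility(self):
        sched = build_schedule(n=2, sweeps=100, burn_in=0, n_temperatures=2,
                               n_s_tau=1)
        out = []
        for _ in range(2):
            st = _dimer_state()
            e, q, acc, att = run_thread_sweeps(st, 100, sched, 77)
            out.append((e.copy(), st.coords.copy()))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        np.testing.assert_array_equal(out[0][1], out[1][1])

    def test_cached_energy_consistent(self, rng):
        from helimc.model import total_energy

        sched = build_schedule(n=8, sweeps=500, burn_in=0, n_temperatures=2,
                               n_s_tau=1)
        st = ReplicaState(np.ascontiguousarray(ideal_helix(8)), 0.0, 0.0, 1, 0)
        run_thread_sweeps(st, 500, sched, 3)
        p = sched.params.with_s_tau(sched.s_tau_values[0])
        assert st.energy == pytest.approx(total_energy(st.coords, p), abs=1e-8)

    def test_fene_dimer_mean_energy_matches_quadrature(self):
        """N=2 FENE-only thread at beta=1: histogram mean energy equals the
        1D quadrature of the bond Boltzmann integral (r^2 measure)."""
        beta = 1.0
        sched = build_schedule(
            n=2, sweeps=120_000, burn_in=5_000,
            temperatures=np.array([1.0, 2.0]), n_s_tau=1,
            move_mix=(1.0, 0.0, 0.0, 0.0), local_step=0.35,
        )
        st = _dimer_state(it=0)
        e, q, acc, att = run_thread_sweeps(st, sched.sweeps, sched, 11)
        e = e[sched.burn_in:]

        def boltz(r):
            x = (r - P.r0) / P.R
            u = P.s_fene * math.log1p(-x * x)
            return r**2 * math.exp(-beta * u), r**2 * math.exp(-beta * u) * u

        lo, hi = P.r0 - P.R + 1e-12, P.r0 + P.R - 1e-12
        z = integrate.quad(lambda r: boltz(r)[0], lo, hi)[0]
        ebar = integrate.quad(lambda r: boltz(r)[1], lo, hi)[0] / z
        # autocorrelation-inflated standard error (conservative block SE)
        blocks = e.reshape(-1, 1000).mean(axis=1)
        se = blocks.std(ddof=1) / math.sqrt(len(blocks))
        assert abs(e.mean() - ebar) < 3 * se + 1e-3


class TestIncrementalEnergy:
    def test_accumulated_deltas_match_full_recompute(self, rng):
        """The kernel scores moves incrementally (only terms touching the
        moved monomers); the running energy after many accepted moves must
        match a from-scratch recomputation."""
        from helimc import _kernels
        from helimc.model import DEFAULT_PARAMS as P

        from conftest import random_valid_chain

        for trial in range(6):
            coords = np.ascontiguousarray(random_valid_chain(14, rng))
            n_sweeps = 100
            e = np.empty(n_sweeps)
            q = np.empty(n_sweeps)
            acc = np.zeros(4, np.int64)
            att = np.zeros(4, np.int64)
            final_e, ef, el, eb, et = _kernels.run_block(
                coords, P.s_fene, P.s_lj, P.s_theta, 8.0, 1.0,
                P.r0, P.R, P.sigma, P.rc, P.vc, P.theta0, P.tau0, 2,
                n_sweeps, 0.7, 0.1, 0.1, 0.3, 0.5, 1000 + trial,
                e, q, acc, att,
            )
            # e[-1] is the delta-accumulated value; final_e a full recompute
            assert abs(e[-1] - final_e) < 1e-8


class TestGridRuns:
    def _smoke(self, **kw):
        kw.setdefault("n", 6)
        kw.setdefault("t_min", 0.5)
        kw.setdefault("t_max", 1.6)
        kw.setdefault("n_temperatures", 2)
        kw.setdefault("n_s_tau", 2)
        kw.setdefault("s_tau_min", 6.0)
        kw.setdefault("s_tau_max", 10.0)
        kw.setdefault("sweeps", 1500)
        kw.setdefault("burn_in", 500)
        kw.setdefault("e_min", -40.0)
        kw.setdefault("e_max", 40.0)
        return build_schedule(**kw)

    def test_histogram_count_conservation(self):
        sched = self._smoke(seed=5)
        grid = run_grid(sched)
        for h in grid.histograms.values():
            assert h.total + h.underflow + h.overflow == sched.sweeps - sched.burn_in

    def test_joint_marginal_matches_1d(self):
        sched = self._smoke(seed=5)
        grid = run_grid(sched)
        for key in grid.histograms:
            np.testing.assert_array_equal(
                grid.joint_histograms[key].marginal().counts,
                grid.histograms[key].counts,
            )

    def test_bitwise_reproducible(self):
        sched = self._smoke(seed=9)
        g1 = run_grid(sched)
        g2 = run_grid(sched)
        for key in g1.histograms:
            np.testing.assert_array_equal(
                g1.histograms[key].counts, g2.histograms[key].counts
            )
            np.testing.assert_array_equal(
                g1.final_states[key].coords, g2.final_states[key].coords
            )

    def test_decoupling_limit_matches_independent_threads(self):
        """exchange_interval beyond the run length reproduces no-exchange
        histograms exactly (same per-thread streams, no swaps)."""
        sched_off = self._smoke(seed=4, exchange_interval=10_000)
        sched_none = self._smoke(seed=4, exchange_interval=10_000,
                                 exchange_axes=())
        g1 = run_grid(sched_off)
        g2 = run_grid(sched_none)
        for key in g1.histograms:
            np.testing.assert_array_equal(
                g1.histograms[key].counts, g2.histograms[key].counts
            )

    def test_equal_conditions_exchanges_always_accepted(self):
        sched = build_schedule(
            n=6, temperatures=np.array([1.0, 1.0 + 1e-12]), n_s_tau=1,
            s_tau_min=8.0, s_tau_max=8.0,
            sweeps=400, burn_in=0, e_min=-40, e_max=40, seed=2,
            exchange_axes=("temperature",),
        )
        grid = run_grid(sched)
        assert grid.exchange_attempts["temperature"] > 0
        assert grid.exchange_accepts["temperature"] == grid.exchange_attempts["temperature"]

    def test_exchange_preserves_stationary_distribution(self):
        """1x2 grid (two s_tau, one T): canonical mean energies with
        exchanges agree with no-exchange runs within combined MC error."""
        def mean_energies(axes, seed):
            sched = build_schedule(
                n=8, temperatures=np.array([0.8]), n_s_tau=2,
                s_tau_min=6.0, s_tau_max=10.0, sweeps=30_000, burn_in=5_000,
                e_min=-60, e_max=60, exchange_axes=axes, seed=seed,
                exchange_interval=10,
            )
            grid = run_grid(sched)
            out = []
            for js in range(2):
                h = grid.histograms[(0, js)]
                out.append(np.average(h.centers, weights=h.counts))
            return np.array(out)

        with_ex = np.mean([mean_energies(("s_tau",), s) for s in (1, 2, 3)], axis=0)
        without = np.mean([mean_energies((), s) for s in (4, 5, 6)], axis=0)
        spread = np.std(
            [mean_energies(("s_tau",), s) - mean_energies((), s + 10) for s in (7, 8)],
            axis=0,
        )
        tol = 3 * np.maximum(spread, 0.5)
        assert np.all(np.abs(with_ex - without) < tol)
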
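"""Potentials, geometry, total energy, and the bundling order parameter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helimc import model
from helimc.fixtures import build_chain, ideal_helix
from helimc.model import (
    DEFAULT_PARAMS as P,
    DegenerateGeometryError,
    FeneDomainError,
    ModelParameters,
    bend_energy,
    bending_angle,
    bond_stretch_energy,
    dihedral_angle,
    energy_terms,
    nonbonded_pair_energy,
    order_parameter_q,
    torsion_energy,
    total_energy,
)

from conftest import random_valid_chain, rigid_motion


class TestModelParameters:
    def test_fene_scale_constant(self):
        # -(98/5) r0^2 R^2 / 2 with r0=1, R=3/7 is exactly -1.8
        assert ModelParameters().s_fene == pytest.approx(-1.8, abs=1e-15)

    def test_lj_shift_recomputed_from_cutoff(self):
        p = ModelParameters()
        sr = p.sigma / p.rc
        assert p.vc == pytest.approx(4 * (sr**12 - sr**6), rel=1e-15)
        p2 = ModelParameters(rc=2.0)
        assert p2.vc == pytest.approx(4 * ((p2.sigma / 2.0) ** 12 - (p2.sigma / 2.0) ** 6))

    @pytest.mark.parametrize(
        "kwargs", [{"r0": -1.0}, {"R": 1.5}, {"s_tau": -1.0}, {"s_tau": 0.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)


class TestBondStretch:
    def test_zero_at_equilibrium(self):
        assert bond_stretch_energy(1.0) == 0.0

    def test_derived_value(self):
        # independent scalar evaluation: ln(1 - (0.2 * 7/3)^2)
        expected = math.log(1.0 - (0.2 * 7.0 / 3.0) ** 2)
        assert bond_stretch_energy(1.2) == pytest.approx(expected, rel=1e-12)
        assert bond_stretch_energy(1.2) == pytest.approx(-0.2456, abs=5e-5)

    @pytest.mark.parametrize("r", [1.0 + 3.0 / 7.0, 1.0 - 3.0 / 7.0, 2.0])
    def test_domain_error_at_boundary(self, r):
        with pytest.raises(FeneDomainError):
            bond_stretch_energy(r)

    @given(st.floats(-0.99, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_nonpositive_with_unique_zero(self, x):
        v = bond_stretch_energy(P.r0 + x * P.R)
        assert v <= 0.0
        if abs(x) > 1e-8:
            assert v < 0.0


class TestNonbondedPair:
    def test_zero_at_and_beyond_cutoff(self):
        assert nonbonded_pair_energy(P.rc) == 0.0
        assert nonbonded_pair_energy(10 * P.rc) == 0.0

    def test_continuous_at_cutoff(self):
        eps = 1e-9
        left = nonbonded_pair_energy(P.rc - eps)
        assert abs(left) < 1e-7  # slope-bounded approach to 0
        inner = nonbonded_pair_energy(P.rc * (1 - 1e-13))
        assert abs(inner - 0.0) < 1e-12

    def test_derived_value_at_unit_distance(self):
        # independent oracle: 4[(sigma)^12 - (sigma)^6] - vc at r=1
        s6 = P.sigma**6
        expected = 4 * (s6 * s6 - s6) - P.vc
        assert nonbonded_pair_energy(1.0) == pytest.approx(expected, rel=1e-14)
        # 4(0.25 - 0.5) - vc = -1 + 0.016316... = -0.983684
        assert nonbonded_pair_energy(1.0) == pytest.approx(-0.98368, abs=5e-5)

    def test_minimum_at_r0(self):
        rs = np.linspace(0.9, 1.5, 2001)
        vals = [nonbonded_pair_energy(r) for r in rs]
        assert rs[int(np.argmin(vals))] == pytest.approx(P.r0, abs=1e-3)

    def test_domain_error_nonpositive(self):
        with pytest.raises(ValueError):
            nonbonded_pair_energy(0.0)


class TestAngles:
    def test_collinear_is_zero(self):
        assert bending_angle([0, 0, 0], [1, 0, 0], [2, 0, 0]) == pytest.approx(0.0)

    def test_right_angle(self):
        a, b, c = [0, 0, 0], [1, 0, 0], [1, 1, 0]
        assert bending_angle(a, b, c) == pytest.approx(math.pi / 2)

    def test_constructed_reference_angle(self):
        t = P.theta0
        a, b = np.zeros(3), np.array([1.0, 0, 0])
        c = b + np.array([math.cos(t), math.sin(t), 0.0])
        assert bending_angle(a, b, c) == pytest.approx(t, abs=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateGeometryError):
            bending_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_dihedral_cis_trans(self):
        a, b, c = [0, 0, 0], [1, 0, 0], [1, 1, 0]
        d_cis = [0, 1, 0]
        d_trans = [2, 1, 0]
        assert dihedral_angle(a, b, c, d_cis) == pytest.approx(0.0, abs=1e-12)
        assert abs(dihedral_angle(a, b, c, d_trans)) == pytest.approx(math.pi)

    def test_dihedral_from_helix_construction(self):
        h = ideal_helix(8)
        for i in range(5):
            assert dihedral_angle(*h[i : i + 4]) == pytest.approx(P.tau0, abs=1e-10)

    def test_mirror_negates_dihedral(self, rng):
        chain = random_valid_chain(6, rng)
        mirrored = chain * np.array([1.0, 1.0, -1.0])
        for i in range(3):
            assert dihedral_angle(*mirrored[i : i + 4]) == pytest.approx(
                -dihedral_angle(*chain[i : i + 4]), abs=1e-10
            )


class TestAnglePotentials:
    @pytest.mark.parametrize(
        "fn,ref", [(bend_energy, P.theta0), (torsion_energy, P.tau0)]
    )
    def test_zero_only_at_reference(self, fn, ref):
        assert fn(ref) == 0.0
        assert fn(ref + math.pi) == pytest.approx(2.0)
        xs = np.linspace(ref - 3, ref + 3, 301)
        vals = np.array([fn(x) for x in xs])
        assert np.all(vals >= 0)
        assert np.sum(np.isclose(vals, 0, atol=1e-12)) == 1

    def test_bend_at_straight_chain(self):
        assert bend_energy(0.0) == pytest.approx(1 - math.cos(-P.theta0))
        assert bend_energy(0.0) == pytest.approx(1.1702, abs=5e-4)

    def test_torsion_chiral_asymmetry(self):
        assert torsion_energy(-P.tau0) == pytest.approx(1 - math.cos(2 * P.tau0))
        assert torsion_energy(-P.tau0) == pytest.approx(1.1746, abs=5e-4)
        assert torsion_energy(-P.tau0) != pytest.approx(torsion_energy(P.tau0))


def brute_force_energy(coords, p):
    """Naive loop oracle over all term types."""
    n = len(coords)
    e = 0.0
    for i in range(n - 1):
        e += p.s_fene * bond_stretch_energy(
            float(np.linalg.norm(coords[i + 1] - coords[i])), p
        )
    min_sep = 1 if p.include_bonded_lj else 2
    for i in range(n):
        for j in range(i + min_sep, n):
            e += p.s_lj * nonbonded_pair_energy(
                float(np.linalg.norm(coords[j] - coords[i])), p
            )
    for k in range(1, n - 1):
        e += p.s_theta * bend_energy(
            bending_angle(coords[k - 1], coords[k], coords[k + 1]), p
        )
    for l in range(n - 3):
        e += p.s_tau * torsion_energy(dihedral_angle(*coords[l : l + 4]), p)
    return e


class TestTotalEnergy:
    def test_dimer_at_equilibrium(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert total_energy(coords) == pytest.approx(0.0, abs=1e-14)

    def test_ideal_helix_pure_lj(self, helix30):
        ef, el, eb, et = energy_terms(helix30)
        assert abs(eb) < 1e-10 and abs(et) < 1e-10
        assert abs(ef) < 1e-10
        assert total_energy(helix30) == pytest.approx(P.s_lj * el)
        assert el < 0  # compact helix: net attractive LJ

    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_matches_brute_force(self, n, rng):
        for _ in range(5):
            chain = random_valid_chain(n, rng)
            assert total_energy(chain) == pytest.approx(
                brute_force_energy(chain, P), rel=1e-10, abs=1e-10
            )

    def test_kernel_matches_reference(self, rng):
        from helimc._kernels import energy_terms_kernel

        for n in (5, 12, 30):
            chain = np.ascontiguousarray(random_valid_chain(n, rng))
            ok, ef, el, eb, et = energy_terms_kernel(
                chain, P.r0, P.R, P.sigma, P.rc, P.vc, P.theta0, P.tau0, 2
            )
            ref = energy_terms(chain)
            assert ok
            assert (ef, el, eb, et) == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        chain = random_valid_chain(20, rng)
        e0 = total_energy(chain)
        q0 = order_parameter_q(chain)
        for _ in range(5):
            moved = rigid_motion(chain, rng)
            assert abs(total_energy(moved) - e0) < 1e-9 * max(1.0, abs(e0))
            assert abs(order_parameter_q(moved) - q0) < 1e-9

    def test_fene_violation_propagates(self):
        coords = np.array([[0.0, 0, 0], [1.6, 0, 0], [2.6, 0, 0]])
        with pytest.raises(FeneDomainError):
            total_energy(coords)

    def test_scaled_terms_nonnegative(self, rng):
        # s_fene * v_fene >= 0, s_theta * v_bend >= 0, s_tau * v_tor >= 0
        chain = random_valid_chain(15, rng)
        ef, el, eb, et = energy_terms(chain)
        assert P.s_fene * ef >= 0
        assert P.s_theta * eb >= 0
        assert P.s_tau * et >= 0

    def test_bonded_lj_switch(self, rng):
        chain = random_valid_chain(10, rng)
        p_incl = ModelParameters(include_bonded_lj=True)
        with_bonded = total_energy(chain, p_incl)
        without = total_energy(chain)
        extra = sum(
            nonbonded_pair_energy(float(np.linalg.norm(chain[i + 1] - chain[i])))
            for i in range(9)
        )
        assert with_bonded - without == pytest.approx(extra, rel=1e-10)


class TestOrderParameter:
    def test_short_chain_is_zero(self, rng):
        for n in (3, 5, 7):
            chain = random_valid_chain(n, rng)
            assert order_parameter_q(chain) == 0.0

    def test_ideal_helix_near_zero(self, helix30):
        # single-helix signature: q of order 0.01 or below
        assert abs(order_parameter_q(helix30)) < 0.02

    def test_two_helix_bundle_band(self, bundle30):
        assert order_parameter_q(bundle30) == pytest.approx(0.35, abs=0.06)

    def test_extended_chain_zero_by_convention(self):
        coords = np.zeros((12, 3))
        coords[:, 0] = np.arange(12) * 1.0
        assert order_parameter_q(coords) == 0.0

    def test_kernel_split_matches(self, helix30, bundle30):
        from helimc._kernels import lj_split_kernel

        for chain in (helix30, bundle30):
            num, den = lj_split_kernel(
                np.ascontiguousarray(chain), P.sigma, P.rc, P.vc, 2
            )
            if abs(den) > 1e-9:
                assert num / den == pytest.approx(order_parameter_q(chain), rel=1e-12)


class TestXyzRoundTrip:
    def test_round_trip(self, tmp_path, helix30):
        path = tmp_path / "helix.xyz"
        model.write_xyz(path, helix30, "ideal helix")
        coords, comment = model.read_xyz(path)
        assert comment == "ideal helix"
        np.testing.assert_allclose(coords, helix30, atol=1e-9)
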
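"""Reference occupations with holes and the hole-tolerant Fermi smearing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xmecp.constants import KB_HARTREE
from xmecp.occupations import (
    FermiLevelError,
    OccupationError,
    ReferenceOccupation,
    fermi_level,
    make_state,
    parse_excitation,
    smear,
)


class TestMakeState:
    def test_ground_state_is_aufbau(self):
        gs = make_state("GS", 1, 1, [], n_orbitals=2)
        np.testing.assert_array_equal(gs.alpha_ref, [1, 0])
        np.testing.assert_array_equal(gs.beta_ref, [1, 0])
        assert not gs.has_holes()

    def test_os1_single_excitation(self):
        os1 = make_state("OS1", 1, 1, [("HOMO", "LUMO", "alpha")], n_orbitals=2)
        np.testing.assert_array_equal(os1.alpha_ref, [0, 1])
        np.testing.assert_array_equal(os1.beta_ref, [1, 0])

    def test_hole_below_occupied(self):
        """(HOMO-1 -> LUMO) on a 3-orbital 2-alpha-electron toy leaves a hole
        below an occupied orbital."""
        st_ = make_state("OS2", 2, 2, [("HOMO-1", "LUMO", "alpha")], n_orbitals=3)
        np.testing.assert_array_equal(st_.alpha_ref, [0, 1, 1])
        assert st_.has_holes()

    def test_cs1_double_excitation(self):
        cs1 = make_state(
            "CS1", 1, 1,
            [("HOMO", "LUMO", "alpha"), ("HOMO", "LUMO", "beta")],
            n_orbitals=3,
        )
        np.testing.assert_array_equal(cs1.alpha_ref, [0, 1, 0])
        np.testing.assert_array_equal(cs1.beta_ref, [0, 1, 0])

    def test_excite_from_empty_rejected(self):
        with pytest.raises(OccupationError, match="empty"):
            make_state("X", 1, 1, [("LUMO", "LUMO+1", "alpha")], n_orbitals=3)

    def test_excite_into_filled_rejected(self):
        with pytest.raises(OccupationError, match="filled"):
            make_state("X", 2, 2, [("HOMO-1", "HOMO", "alpha")], n_orbitals=3)

    def test_counts(self):
        s = make_state("GS", 3, 2, [], n_orbitals=5)
        assert s.n_alpha == 3 and s.n_beta == 2

    @pytest.mark.parametrize(
        "spec,n_occ,expected",
        [("HOMO", 4, 3), ("LUMO", 4, 4), ("HOMO-2", 4, 1), ("LUMO+1", 4, 5), (7, 4, 7)],
    )
    def test_parse_excitation(self, spec, n_occ, expected):
        assert parse_excitation(spec, n_occ) == expected


class TestFermiLevel:
    def test_t0_midpoint_convention(self):
        eps = np.array([-0.7, -0.4, -0.1])
        ref = np.array([1.0, 1.0, 0.0])
        ef = fermi_level(eps, ref, 2, 0.0)
        assert ef == pytest.approx(-0.25, abs=1e-14)

    @pytest.mark.parametrize("t_el", [100.0, 3000.0, 20000.0])
    def test_symmetric_two_level(self, t_el):
        """{-e, +e} with one electron: eps_F = 0 at any temperature."""
        eps = np.array([-0.3, 0.3])
        ref = np.array([1.0, 0.0])
        assert fermi_level(eps, ref, 1, t_el) == pytest.approx(0.0, abs=1e-9)

    def test_three_level_toy_against_bisection_oracle(self):
        """n_sigma = 2 at T_el = 3000 K: the implementation must agree with an
        independent plain-bisection root solve of the same particle-number
        residual to 1e-9 hartree."""
        eps = np.array([-0.5, -0.3, -0.1])
        ref = np.array([1.0, 1.0, 0.0])
        t_el = 3000.0
        kt = KB_HARTREE * t_el

        def occupation_sum(ef):
            z = np.abs(eps - ef) / kt
            h = np.exp(-z) / (1 + np.exp(-z))
            return float(np.sum(ref + (1 - 2 * ref) * h))

        lo, hi = -0.3, -0.1  # frontier bracket containing the sign change
        flo = occupation_sum(lo) - 2
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fm = occupation_sum(mid) - 2
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        oracle = 0.5 * (lo + hi)
        assert fermi_level(eps, ref, 2, t_el) == pytest.approx(oracle, abs=1e-9)

    def test_conservation_tolerance(self):
        rng = np.random.default_rng(11)
        eps = np.sort(rng.uniform(-1.0, 0.0, 12))
        ref = np.zeros(12)
        ref[[0, 1, 2, 4, 6]] = 1.0  # holes at 3 and 5
        ef = fermi_level(eps, ref, 5, 5000.0)
        z = np.abs(eps - ef) / (KB_HARTREE * 5000.0)
        h = np.exp(-z) / (1 + np.exp(-z))
        n = ref + (1 - 2 * ref) * h
        assert abs(n.sum() - 5.0) < 1e-10

    def test_invalid_count_rejected(self):
        with pytest.raises(OccupationError):
            fermi_level(np.array([-0.5, -0.1]), np.array([1.0, 1.0]), 3, 300.0)


class TestSmear:
    def test_t0_returns_reference_exactly(self):
        eps = np.array([-0.6, -0.2, 0.1])
        ref = make_state("OS1", 2, 1, [("HOMO", "LUMO", "alpha")], n_orbitals=3)
        occ = smear(eps, ref, 0.0)
        np.testing.assert_array_equal(occ.n_alpha_prime, ref.alpha_ref)
        np.testing.assert_array_equal(occ.n_beta_prime, ref.beta_ref)

    def test_gapped_limit_reproduces_reference(self):
        """Aufbau reference with a gap >> k_B T_el stays integer to 1e-6."""
        eps = np.array([-1.0, -0.9, -0.2, -0.1])
        gs = make_state("GS", 2, 2, [], n_orbitals=4)
        occ = smear(eps, gs, 3000.0)
        np.testing.assert_allclose(occ.n_alpha_prime, [1, 1, 0, 0], atol=1e-6)
        np.testing.assert_allclose(occ.total, [2, 2, 0, 0], atol=1e-6)

    def test_low_temperature_limit(self):
        eps = np.array([-0.5, -0.3, -0.1])
        ref = make_state("OS2", 2, 2, [("HOMO-1", "LUMO", "alpha")], n_orbitals=3)
        occ = smear(eps, ref, 1.0)
        np.testing.assert_allclose(occ.n_alpha_prime, ref.alpha_ref, atol=1e-6)

    def test_hole_vs_particle_references_differ(self):
        """[0,1] vs [1,0] on two alpha levels at 3000 K: distinct fractional
        vectors, each conserving one electron; cross-checked by bisection."""
        eps = np.array([-0.52, -0.48])

        def by_label(ref_vec):
            ref = ReferenceOccupation("x", np.array(ref_vec, float), np.array([1.0, 0.0]))
            return smear(eps, ref, 3000.0)

        occ_p = by_label([1.0, 0.0])
        occ_h = by_label([0.0, 1.0])
        assert occ_p.n_alpha_prime.sum() == pytest.approx(1.0, abs=1e-9)
        assert occ_h.n_alpha_prime.sum() == pytest.approx(1.0, abs=1e-9)
        assert not np.allclose(occ_p.n_alpha_prime, occ_h.n_alpha_prime, atol=1e-3)
        # the hole reference keeps most weight on the upper level
        assert occ_h.n_alpha_prime[1] > occ_h.n_alpha_prime[0]

    def test_holes_smear_back(self):
        """At finite T_el an orbital above a predefined hole loses occupation
        into the hole orbital."""
        eps = np.array([-0.505, -0.5, -0.495])
        ref = make_state("OS2", 2, 2, [("HOMO-1", "LUMO", "alpha")], n_orbitals=3)
        occ = smear(eps, ref, 3000.0)
        assert occ.n_alpha_prime[0] > 0.01       # hole partially refilled
        assert occ.n_alpha_prime.sum() == pytest.approx(2.0, abs=1e-9)

    def test_monotone_nonincreasing_for_gapped_aufbau(self):
        eps = np.array([-0.9, -0.6, -0.4, -0.35, -0.1])
        gs = make_state("GS", 3, 3, [], n_orbitals=5)
        occ = smear(eps, gs, 8000.0)
        assert np.all(np.diff(occ.n_alpha_prime) <= 1e-12)

    def test_determinism_same_reference_same_result(self):
        eps = np.array([-0.5, -0.45, -0.2, 0.0])
        a = make_state("A", 2, 2, [("HOMO", "LUMO", "alpha")], n_orbitals=4)
        b = make_state("B", 2, 2, [("HOMO", "LUMO", "alpha")], n_orbitals=4)
        oa, ob = smear(eps, a, 4000.0), smear(eps, b, 4000.0)
        np.testing.assert_array_equal(oa.n_alpha_prime, ob.n_alpha_prime)
        np.testing.assert_array_equal(oa.n_beta_prime, ob.n_beta_prime)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n_orb=st.integers(2, 10),
    t_el=st.sampled_from([1.0, 300.0, 3000.0, 15000.0]),
)
def test_conservation_and_bounds_property(seed, n_orb, t_el):
    """Per-spin electron counts conserved to 1e-10 and 0 <= n' <= 1 for random
    spectra and random (possibly hole-ridden) references."""
    rng = np.random.default_rng(seed)
    eps = np.sort(rng.uniform(-1.5, 0.5, n_orb))
    n_alpha = int(rng.integers(1, n_orb + 1))
    n_beta = int(rng.integers(1, n_orb + 1))
    aref = np.zeros(n_orb)
    aref[rng.choice(n_orb, n_alpha, replace=False)] = 1.0
    bref = np.zeros(n_orb)
    bref[rng.choice(n_orb, n_beta, replace=False)] = 1.0
    ref = ReferenceOccupation("rand", aref, bref)
    occ = smear(eps, ref, t_el)
    assert abs(occ.n_alpha_prime.sum() - n_alpha) < 1e-10
    assert abs(occ.n_beta_prime.sum() - n_beta) < 1e-10
    assert np.all(occ.n_alpha_prime >= -1e-14) and np.all(occ.n_alpha_prime <= 1 + 1e-14)
    assert np.all(occ.n_beta_prime >= -1e-14) and np.all(occ.n_beta_prime <= 1 + 1e-14)
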
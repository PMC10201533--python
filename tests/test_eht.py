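"""Tight-binding engine: Hamiltonian, diagonalization, energies, gradients."""

import numpy as np
import pytest

from xmecp import Geometry, build_fixture
from xmecp.basis import build_basis, overlap_matrix
from xmecp.constants import WOLFSBERG_HELMHOLZ_K
from xmecp.eht import (
    EHTCalculator,
    density_matrix,
    eht_hamiltonian,
    electronic_energy,
    nuclear_gradient,
    solve_orbitals,
    total_energy,
)
from xmecp.params import get_default_table
from xmecp.structures import GeometryError
from conftest import rigid_transform


@pytest.fixture(scope="module")
def h2_system(h2):
    basis = build_basis(h2)
    s = overlap_matrix(basis, h2)
    h = eht_hamiltonian(basis, s)
    return basis, s, h


class TestHamiltonian:
    def test_single_carbon_diagonal(self):
        g = Geometry.from_angstrom(["C"], [[0, 0, 0]])
        basis = build_basis(g)
        s = overlap_matrix(basis, g)
        h = eht_hamiltonian(basis, s)
        table = get_default_table()
        e2s = table["C"].shells[0].h_onsite
        e2p = table["C"].shells[1].h_onsite
        np.testing.assert_allclose(np.diag(h), [e2s, e2p, e2p, e2p], atol=1e-14)

    def test_offdiagonal_proportional_to_overlap(self, h2_system):
        basis, s, h = h2_system
        h_on = get_default_table()["H"].shells[0].h_onsite
        expected = 0.5 * WOLFSBERG_HELMHOLZ_K * (2 * h_on) * s[0, 1]
        assert h[0, 1] == pytest.approx(expected, abs=1e-14)

    def test_zero_overlap_gives_zero_element(self):
        g = Geometry.from_angstrom(["H", "H"], [[0, 0, 0], [0, 0, 45.0]])
        basis = build_basis(g)
        s = overlap_matrix(basis, g)
        h = eht_hamiltonian(basis, s)
        assert h[0, 1] == pytest.approx(0.0, abs=1e-14)


class TestSolveOrbitals:
    def test_identity_overlap_diagonal_h(self):
        h = np.diag([-2.0, -1.0, -0.5])
        sol = solve_orbitals(h, np.eye(3))
        np.testing.assert_allclose(sol.energies, [-2.0, -1.0, -0.5], atol=1e-14)
        np.testing.assert_allclose(np.abs(sol.coefficients), np.eye(3), atol=1e-12)

    def test_h2_closed_form(self, h2_system):
        basis, s, h = h2_system
        sol = solve_orbitals(h, s)
        h11, h12, s12 = h[0, 0], h[0, 1], s[0, 1]
        e_minus = (h11 + h12) / (1 + s12)
        e_plus = (h11 - h12) / (1 - s12)
        np.testing.assert_allclose(sol.energies, [e_minus, e_plus], atol=1e-10)

    def test_orthonormality_and_residual(self, azobenzene):
        basis = build_basis(azobenzene)
        s = overlap_matrix(basis, azobenzene)
        h = eht_hamiltonian(basis, s)
        sol = solve_orbitals(h, s)
        c, eps = sol.coefficients, sol.energies
        np.testing.assert_allclose(c.T @ s @ c, np.eye(len(basis)), atol=1e-8)
        resid = h @ c - s @ c * eps
        assert np.abs(resid).max() < 1e-8
        assert np.all(np.diff(eps) >= -1e-12)


class TestDensityAndEnergy:
    def test_zero_occupations_zero_density(self, h2_system):
        basis, s, h = h2_system
        sol = solve_orbitals(h, s)
        p = density_matrix(sol, [0.0, 0.0])
        np.testing.assert_allclose(p, 0.0, atol=1e-14)
        assert electronic_energy(p, h) == 0.0

    def test_rank_one_density(self, h2_system):
        basis, s, h = h2_system
        sol = solve_orbitals(h, s)
        p = density_matrix(sol, [2.0, 0.0])
        c0 = sol.coefficients[:, 0]
        np.testing.assert_allclose(p, 2.0 * np.outer(c0, c0), atol=1e-12)
        assert np.trace(p @ s) == pytest.approx(2.0, abs=1e-10)

    def test_negative_occupation_rejected(self, h2_system):
        basis, s, h = h2_system
        sol = solve_orbitals(h, s)
        with pytest.raises(ValueError):
            density_matrix(sol, [-0.1, 0.0])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_electron_conservation_random_occupations(self, h2_system, seed):
        basis, s, h = h2_system
        sol = solve_orbitals(h, s)
        rng = np.random.default_rng(seed)
        n = rng.uniform(0, 2, size=2)
        p = density_matrix(sol, n)
        assert np.trace(p @ s) == pytest.approx(n.sum(), abs=1e-10)

    def test_energy_equals_occupation_weighted_sum(self, azobenzene):
        basis = build_basis(azobenzene)
        s = overlap_matrix(basis, azobenzene)
        h = eht_hamiltonian(basis, s)
        sol = solve_orbitals(h, s)
        rng = np.random.default_rng(3)
        n = np.clip(rng.uniform(-0.5, 2.2, size=len(basis)), 0, 2)
        p = density_matrix(sol, n)
        assert electronic_energy(p, h) == pytest.approx(float(n @ sol.energies), abs=1e-8)

    def test_excited_occupation_above_ground(self, h2):
        e_gs = total_energy(h2, [2.0, 0.0])
        e_ex = total_energy(h2, [0.0, 2.0])
        assert e_ex > e_gs


class TestTotalEnergy:
    def test_rigid_motion_invariance(self, ethylene):
        calc = EHTCalculator(ethylene)
        occ = calc.aufbau_occupations()
        e0 = calc.total_energy(ethylene.coords, occ)
        for seed in (1, 2):
            e1 = calc.total_energy(rigid_transform(ethylene.coords, seed), occ)
            assert e1 == pytest.approx(e0, abs=1e-8)

    def test_single_atom_is_onsite_sum(self):
        g = Geometry.from_angstrom(["C"], [[0, 0, 0]])
        table = get_default_table()
        e2s = table["C"].shells[0].h_onsite
        e2p = table["C"].shells[1].h_onsite
        e = total_energy(g, [2.0, 2.0, 0.0, 0.0])
        assert e == pytest.approx(2 * e2s + 2 * e2p, abs=1e-12)

    def test_h2_curve_single_interior_minimum(self):
        g = build_fixture("h2")
        calc = EHTCalculator(g)
        occ = calc.aufbau_occupations()
        rs = np.linspace(0.5, 3.0, 101)
        es = np.array([
            calc.total_energy(np.array([[0, 0, 0], [0, 0, r]]), occ) for r in rs
        ])
        k = int(np.argmin(es))
        assert 0 < k < len(rs) - 1
        d = np.diff(es)
        assert int(np.sum((d[:-1] < 0) & (d[1:] > 0))) == 1

    def test_clash_rejected(self):
        g = build_fixture("h2")
        calc = EHTCalculator(g)
        with pytest.raises(GeometryError, match="closer than"):
            calc.total_energy(np.array([[0, 0, 0], [0, 0, 0.2]]), [2.0, 0.0])

    def test_aufbau_is_optimal_at_t0(self, ethylene):
        """At T=0 the Aufbau occupation minimizes the energy over all
        integer occupation vectors with the same electron count."""
        from itertools import combinations

        calc = EHTCalculator(ethylene)
        sol = calc.solve(ethylene.coords)
        nel = calc.n_electrons
        # enumerate double-occupation patterns over the lowest 8 orbitals
        e_aufbau = float(calc.aufbau_occupations() @ sol.energies)
        for occ_idx in combinations(range(8), nel // 2):
            n = np.zeros(len(calc.basis))
            n[list(occ_idx)] = 2.0
            assert float(n @ sol.energies) >= e_aufbau - 1e-12


class TestGradients:
    def test_equilibrium_gradient_vanishes(self):
        from scipy.optimize import minimize_scalar

        g = build_fixture("h2")
        calc = EHTCalculator(g)
        occ = calc.aufbau_occupations()
        f = lambda r: calc.total_energy(np.array([[0, 0, 0], [0, 0, r]]), occ)
        r_eq = minimize_scalar(f, bracket=(1.2, 1.7, 2.4)).x
        geq = Geometry(("H", "H"), np.array([[0, 0, 0], [0, 0, r_eq]]))
        grad = nuclear_gradient(geq, occ)
        assert np.linalg.norm(grad) < 1e-5

    def test_translational_sum_vanishes(self, azobenzene):
        rng = np.random.default_rng(7)
        distorted = azobenzene.with_coords(
            azobenzene.coords + 0.05 * rng.normal(size=azobenzene.coords.shape)
        )
        calc = EHTCalculator(distorted)
        occ = calc.aufbau_occupations()
        from xmecp.eht import fd_gradient

        grad = fd_gradient(lambda x: calc.total_energy(x, occ), distorted.coords)
        assert np.abs(grad.sum(axis=0)).max() < 1e-6

    def test_gradient_matches_polynomial_fit(self):
        """Slope at r = 2.0 bohr from the FD gradient vs a 5-point polynomial
        fit to the energy curve."""
        g = build_fixture("h2")
        calc = EHTCalculator(g)
        occ = calc.aufbau_occupations()
        f = lambda r: calc.total_energy(np.array([[0, 0, 0], [0, 0, r]]), occ)
        rs = 2.0 + np.array([-0.02, -0.01, 0.0, 0.01, 0.02])
        poly = np.polynomial.Polynomial.fit(rs, [f(r) for r in rs], deg=4)
        slope_fit = poly.deriv()(2.0)
        geo = Geometry(("H", "H"), np.array([[0, 0, 0], [0, 0, 2.0]]))
        grad = nuclear_gradient(geo, occ)
        assert grad[1, 2] == pytest.approx(slope_fit, abs=1e-6)
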
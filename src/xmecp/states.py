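"""Energies and gradients of several diabatic states at one geometry.

All states at a geometry share one orbital solution: the extended-Hueckel
Hamiltonian does not depend on the electron distribution, so a single
diagonalization provides the orbitals for every occupation pattern.  A
state's total energy is its smeared occupation-weighted orbital-energy sum
plus the classical pair energy, which is identical across states and hence
cancels exactly in every state-energy difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eht import EHTCalculator, FD_STEP, OrbitalSolution
from .occupations import DEFAULT_T_EL, FractionalOccupation, ReferenceOccupation, smear
from .params import ParameterTable
from .structures import Geometry

__all__ = ["StateEnergies", "evaluate_states", "state_gradients", "MultiStateEvaluator"]


@dataclass(frozen=True)
class StateEnergies:
    """Per-state total energies sharing one orbital solution."""

    energies: np.ndarray                      # (n_states,), hartree
    occupations: tuple[FractionalOccupation, ...]
    orbitals: OrbitalSolution
    geometry: Geometry
    states: tuple[ReferenceOccupation, ...]
    classical_energy: float

    def gap(self, i: int, j: int) -> float:
        """Energy gap E_i - E_j (hartree); classical terms cancel exactly."""
        return float(self.energies[i] - self.energies[j])


class MultiStateEvaluator:
    """Repeated multi-state evaluation on one element sequence (fast path)."""

    def __init__(
        self,
        geometry: Geometry,
        states: tuple[ReferenceOccupation, ...] | list[ReferenceOccupation],
        t_el: float = DEFAULT_T_EL,
        table: ParameterTable | None = None,
    ):
        if not states:
            raise ValueError("at least one state is required")
        self.calc = EHTCalculator(geometry, table)
        n_orb = self.calc.basis.n_functions
        nel = self.calc.n_electrons
        for st in states:
            if st.n_orbitals != n_orb:
                raise ValueError(
                    f"state {st.label!r} sized for {st.n_orbitals} orbitals, "
                    f"geometry has {n_orb}"
                )
            if st.n_alpha + st.n_beta != nel:
                raise ValueError(
                    f"state {st.label!r} has {st.n_alpha + st.n_beta} electrons, "
                    f"geometry has {nel}"
                )
        self.states = tuple(states)
        self.t_el = float(t_el)
        self.template = geometry

    def energies(self, coords_bohr: np.ndarray) -> tuple[np.ndarray, float, OrbitalSolution, tuple]:
        """All state energies at the given coordinates from one diagonalization."""
        coords = np.asarray(coords_bohr, float).reshape(-1, 3)
        sol = self.calc.solve(coords)
        e_cl = self.calc.repulsion(coords)
        occs = tuple(smear(sol.energies, st, self.t_el) for st in self.states)
        es = np.array([float(occ.total @ sol.energies) + e_cl for occ in occs])
        return es, e_cl, sol, occs

    def energies_only(self, coords_bohr: np.ndarray) -> np.ndarray:
        """State energies without keeping orbitals (eigenvalues-only path)."""
        coords = np.asarray(coords_bohr, float).reshape(-1, 3)
        eps = self.calc.orbital_energies(coords)
        e_cl = self.calc.repulsion(coords)
        return np.array([
            float(smear(eps, st, self.t_el).total @ eps) + e_cl
            for st in self.states
        ])

    def gradients(
        self,
        coords_bohr: np.ndarray,
        step: float = FD_STEP,
        scheme: str = "central",
    ) -> np.ndarray:
        """Finite-difference gradients, shape (n_states, n_atoms, 3).

        ``scheme="central"`` (default) is second-order accurate;
        ``scheme="forward"`` halves the cost and carries an O(step) bias
        (~1e-4 x curvature), adequate for loose relaxations on smooth
        regions.

        Occupations are re-smeared at every displaced geometry; each
        displacement costs one diagonalization regardless of state count.
        Single-atom displacements reuse the unmoved atoms' overlap
        contributions, and the displaced Fermi levels are warm-started from
        the base geometry's, so the dominant cost is the eigensolves.
        """
        import scipy.linalg

        import xmecp.eht as eht_mod

        coords = np.asarray(coords_bohr, float).reshape(-1, 3)
        calc = self.calc
        basis = calc.basis
        nbf = basis.n_functions
        flat_base = basis._flat_upper(coords)
        # base smear for warm-started Fermi levels
        s0 = basis.flat_to_full(flat_base, nbf)
        from .eht import eht_hamiltonian
        h0 = eht_hamiltonian(basis, s0, calc.table)
        eht_mod._DIAG_COUNT += 1
        eps0 = scipy.linalg.eigh(h0, s0, eigvals_only=True)
        base_occ = [smear(eps0, st, self.t_el) for st in self.states]
        guesses = [(o.fermi_level_alpha, o.fermi_level_beta) for o in base_occ]
        if scheme not in ("central", "forward"):
            raise ValueError(f"unknown finite-difference scheme {scheme!r}")
        e_base = None
        if scheme == "forward":
            e_cl0 = calc.repulsion(coords)
            e_base = np.array([
                float(o.total @ eps0) + e_cl0 for o in base_occ
            ])

        h_on = basis.onsite_energies
        wh = 0.5 * calc.table.wolfsberg_helmholz * (h_on[:, None] + h_on[None, :])
        diag = np.arange(nbf)

        dsygvd = scipy.linalg.lapack.dsygvd

        def energies_at(flat: np.ndarray, coords_d: np.ndarray) -> np.ndarray:
            s = basis.flat_to_full(flat, nbf)
            h = wh * s
            h[diag, diag] = h_on
            eht_mod._DIAG_COUNT += 1
            eps, _, info = dsygvd(h, s, itype=1, jobz="N")
            if info != 0:
                eps = scipy.linalg.eigh(h, s, eigvals_only=True)
            e_cl = calc.repulsion(coords_d)
            return np.array([
                float(smear(eps, st, self.t_el, guesses=g).total @ eps) + e_cl
                for st, g in zip(self.states, guesses)
            ])

        n_atoms = coords.shape[0]
        grads = np.zeros((len(self.states), n_atoms, 3))
        for a in range(n_atoms):
            contrib = basis.atom_flat(coords, a)
            rest = flat_base - contrib
            for ax in range(3):
                cd = coords.copy()
                cd[a, ax] += step
                ep = energies_at(rest + basis.atom_flat(cd, a), cd)
                if scheme == "central":
                    cd[a, ax] -= 2.0 * step
                    em = energies_at(rest + basis.atom_flat(cd, a), cd)
                    grads[:, a, ax] = (ep - em) / (2.0 * step)
                else:
                    grads[:, a, ax] = (ep - e_base) / step
        return grads


def evaluate_states(
    geometry: Geometry,
    states,
    t_el: float = DEFAULT_T_EL,
    table: ParameterTable | None = None,
) -> StateEnergies:
    """Evaluate all states at a geometry; exactly one diagonalization is used."""
    ev = MultiStateEvaluator(geometry, tuple(states), t_el, table)
    es, e_cl, sol, occs = ev.energies(geometry.coords)
    return StateEnergies(
        energies=es,
        occupations=occs,
        orbitals=sol,
        geometry=geometry,
        states=ev.states,
        classical_energy=e_cl,
    )


def state_gradients(
    geometry: Geometry,
    states,
    t_el: float = DEFAULT_T_EL,
    table: ParameterTable | None = None,
) -> np.ndarray:
    """Per-state nuclear gradients (n_states, n_atoms, 3), hartree/bohr."""
    ev = MultiStateEvaluator(geometry, tuple(states), t_el, table)
    return ev.gradients(geometry.coords)
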
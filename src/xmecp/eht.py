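"""Non-self-consistent extended-Hueckel engine.

The electronic problem is a single generalized eigenvalue problem
H C = S C eps per geometry; the Hamiltonian is built from on-site energies
and the overlap via the Wolfsberg-Helmholz approximation
H_mn = 1/2 K (H_mm + H_nn) S_mn.  Because H does not depend on the electron
distribution, one diagonalization serves every occupation pattern: the energy
of a state with (possibly fractional, possibly non-Aufbau) occupations n_i is

    E_EHT = sum_mn P_mn H_nm = sum_i n_i eps_i,   P = C diag(n) C^T,

plus a classical pairwise Born-Mayer repulsion that makes the total surface
bound, so that geometry optimization is meaningful.

Gradients are central finite differences of the total energy (step 1e-4 bohr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .basis import BasisSet, build_basis, overlap_matrix
from .constants import WOLFSBERG_HELMHOLZ_K
from .params import ParameterTable, get_default_table
from .structures import Geometry, GeometryError

__all__ = [
    "OrbitalSolution",
    "EHTCalculator",
    "eht_hamiltonian",
    "solve_orbitals",
    "density_matrix",
    "electronic_energy",
    "repulsion_energy",
    "total_energy",
    "nuclear_gradient",
    "diagonalization_count",
    "reset_diagonalization_count",
]

#: Atoms closer than this (bohr) are treated as a hard clash.
CLASH_DISTANCE = 0.3

#: Finite-difference step for nuclear gradients, bohr.
FD_STEP = 1e-4

# module-level instrumentation: incremented on every generalized eigensolve
_DIAG_COUNT = 0


def diagonalization_count() -> int:
    """Number of generalized eigensolves performed since the last reset."""
    return _DIAG_COUNT


def reset_diagonalization_count() -> None:
    global _DIAG_COUNT
    _DIAG_COUNT = 0


@dataclass(frozen=True)
class OrbitalSolution:
    """Result of one diagonalization: C, eps (ascending), S and the basis."""

    coefficients: np.ndarray  # (nbf, norb)
    energies: np.ndarray      # (norb,), hartree, ascending
    overlap: np.ndarray       # (nbf, nbf)
    basis: BasisSet

    @property
    def n_orbitals(self) -> int:
        return self.energies.size


def eht_hamiltonian(
    basis: BasisSet, s: np.ndarray, table: ParameterTable | None = None
) -> np.ndarray:
    """Wolfsberg-Helmholz Hamiltonian from the overlap and on-site energies."""
    table = table or basis.table
    h_on = basis.onsite_energies
    k = table.wolfsberg_helmholz
    h = 0.5 * k * (h_on[:, None] + h_on[None, :]) * s
    np.fill_diagonal(h, h_on)
    return h


def solve_orbitals(h: np.ndarray, s: np.ndarray, basis: BasisSet | None = None) -> OrbitalSolution:
    """Solve the generalized eigenproblem H C = S C eps (one diagonalization).

    The returned coefficients satisfy C^T S C = I; energies are ascending.
    """
    global _DIAG_COUNT
    _DIAG_COUNT += 1
    try:
        eps, c = scipy.linalg.eigh(h, s)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(f"overlap matrix not positive definite: {exc}") from exc
    return OrbitalSolution(coefficients=c, energies=eps, overlap=s, basis=basis)


def density_matrix(orbitals: OrbitalSolution, occupations: np.ndarray) -> np.ndarray:
    """P = C diag(n) C^T for per-orbital occupations n in [0, 2]."""
    n = np.asarray(occupations, float)
    if n.size != orbitals.n_orbitals:
        raise ValueError(
            f"occupation vector length {n.size} != {orbitals.n_orbitals} orbitals"
        )
    if np.any(n < 0):
        raise ValueError("negative occupation numbers are not allowed")
    if np.any(n > 2 + 1e-12):
        raise ValueError("spatial-orbital occupations cannot exceed 2")
    c = orbitals.coefficients
    return (c * n) @ c.T


def electronic_energy(p: np.ndarray, h: np.ndarray) -> float:
    """E_EHT = sum_mn P_mn H_nm (equals sum_i n_i eps_i for consistent P)."""
    return float(np.sum(p * h))


class EHTCalculator:
    """Fast path for repeated evaluations on one element sequence.

    The basis (and its primitive-pair tables) is precomputed once; each call
    to :meth:`solve` then costs one overlap build plus one diagonalization.
    """

    def __init__(self, geometry: Geometry, table: ParameterTable | None = None):
        self.table = table or get_default_table()
        self.elements = geometry.elements
        self.charge = geometry.charge
        self.basis = build_basis(geometry, self.table)
        z = [self.table[el].valence_electrons for el in geometry.elements]
        self._zval = np.array(z, float)
        self.n_electrons = int(round(sum(z))) - geometry.charge
        if self.n_electrons < 1:
            raise GeometryError("no electrons left at this charge")
        b, c = self.table.repulsion_b, self.table.repulsion_c
        self._rep_b, self._rep_c = b, c
        self._srb_d = self.table.srb_depth
        self._srb_beta = self.table.srb_width
        iu = np.triu_indices(len(z), k=1)
        self._pair_i, self._pair_j = iu
        self._pair_zz = self._zval[iu[0]] * self._zval[iu[1]]
        rc = np.array([self.table[el].r_cov for el in geometry.elements])
        self._pair_r0 = rc[iu[0]] + rc[iu[1]]

    # -- energies ----------------------------------------------------------

    def _check_clash(self, coords: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(coords[self._pair_i] - coords[self._pair_j], axis=1)
        if d.size and d.min() < CLASH_DISTANCE:
            k = int(np.argmin(d))
            i, j = self._pair_i[k], self._pair_j[k]
            raise GeometryError(
                f"atoms {i} and {j} closer than {CLASH_DISTANCE} bohr ({d[k]:.3f})"
            )
        return d

    def repulsion(self, coords: np.ndarray) -> float:
        """Classical pair energy, hartree: Born-Mayer repulsion plus the
        short-range bond well centered at the covalent-radius sum.

        The well compensates bare extended-Hueckel underbinding of covalent
        bonds (strongest for lone-pair-rich ones) so that relaxed molecular
        geometries come out chemically sensible.  Identical for all electronic
        states, so it cancels exactly in every state-energy difference.
        """
        d = self._check_clash(coords)
        if d.size == 0:
            return 0.0
        b, c = self._rep_b, self._rep_c
        e = np.sum(self._pair_zz / d * np.exp(-b * d**c))
        if self._srb_d:
            e -= self._srb_d * np.sum(
                np.sqrt(self._pair_zz)
                * np.exp(-self._srb_beta * (d - self._pair_r0) ** 2)
            )
        return float(e)

    def solve(self, coords: np.ndarray) -> OrbitalSolution:
        """Overlap + Hamiltonian + one diagonalization at these coordinates."""
        global _DIAG_COUNT
        coords = np.asarray(coords, float).reshape(-1, 3)
        self._check_clash(coords)
        s = self.basis._raw_overlap(coords)
        h = eht_hamiltonian(self.basis, s, self.table)
        _DIAG_COUNT += 1
        try:
            eps, cmat = scipy.linalg.eigh(h, s)
        except scipy.linalg.LinAlgError as exc:
            # re-check through the careful path for a better message
            overlap_matrix(self.basis, Geometry(self.elements, coords, self.charge))
            raise ValueError(f"eigensolve failed: {exc}") from exc
        return OrbitalSolution(coefficients=cmat, energies=eps, overlap=s, basis=self.basis)

    def orbital_energies(self, coords: np.ndarray) -> np.ndarray:
        """Orbital energies only (skips the eigenvector back-transform).

        Counts as a diagonalization like :meth:`solve`; used on hot paths
        where the coefficients are not needed (state energies, scans).
        """
        global _DIAG_COUNT
        coords = np.asarray(coords, float).reshape(-1, 3)
        self._check_clash(coords)
        s = self.basis._raw_overlap(coords)
        h = eht_hamiltonian(self.basis, s, self.table)
        _DIAG_COUNT += 1
        try:
            return scipy.linalg.eigh(h, s, eigvals_only=True)
        except scipy.linalg.LinAlgError as exc:
            overlap_matrix(self.basis, Geometry(self.elements, coords, self.charge))
            raise ValueError(f"eigensolve failed: {exc}") from exc

    def total_energy(self, coords: np.ndarray, occupations: np.ndarray) -> float:
        """E_EHT + E_rep for an explicit per-orbital occupation vector."""
        sol = self.solve(coords)
        n = np.asarray(occupations, float)
        if n.size != sol.n_orbitals:
            raise ValueError("occupation vector length mismatch")
        return float(np.dot(n, sol.energies)) + self.repulsion(
            np.asarray(coords, float).reshape(-1, 3)
        )

    def aufbau_occupations(self) -> np.ndarray:
        """T=0 Aufbau spatial-orbital occupations for the neutral electron count."""
        n = np.zeros(self.basis.n_functions)
        nel = self.n_electrons
        nfull = nel // 2
        n[:nfull] = 2.0
        if nel % 2:
            n[nfull] = 1.0
        return n


def repulsion_energy(geometry: Geometry, table: ParameterTable | None = None) -> float:
    return EHTCalculator(geometry, table).repulsion(geometry.coords)


def total_energy(
    geometry: Geometry,
    occupations: np.ndarray,
    table: ParameterTable | None = None,
) -> float:
    """Total energy (hartree) for an explicit per-orbital occupation vector."""
    return EHTCalculator(geometry, table).total_energy(geometry.coords, occupations)


def nuclear_gradient(
    geometry: Geometry,
    occupations: np.ndarray,
    table: ParameterTable | None = None,
) -> np.ndarray:
    """Central finite-difference gradient of the total energy, hartree/bohr."""
    calc = EHTCalculator(geometry, table)
    return fd_gradient(
        lambda x: calc.total_energy(x, occupations), geometry.coords
    )


def fd_gradient(func, coords: np.ndarray, step: float = FD_STEP) -> np.ndarray:
    """Central finite differences of a scalar function of (n, 3) coordinates."""
    coords = np.asarray(coords, float)
    grad = np.zeros_like(coords)
    flat = coords.ravel().copy()
    for k in range(flat.size):
        orig = flat[k]
        flat[k] = orig + step
        ep = func(flat.reshape(coords.shape))
        flat[k] = orig - step
        em = func(flat.reshape(coords.shape))
        flat[k] = orig
        grad.ravel()[k] = (ep - em) / (2.0 * step)
    return grad
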
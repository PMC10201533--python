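"""Valence minimal basis of Slater-type orbitals, expanded in Gaussians.

Each valence shell is a Slater-type orbital (STO) represented by a 3-term
Gaussian expansion (STO-3G style), which makes all overlap integrals closed
form.  The expansion is precomputed per element sequence so that repeated
overlap evaluations along an optimization are cheap: per geometry only the
interatomic vectors enter the (vectorized) Gaussian product formulas.

Basis ordering is deterministic: atom-major, then shell (s before p), then
angular component (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ElementParams, ParameterTable, get_default_table
from .structures import Geometry, GeometryError

__all__ = ["BasisSet", "BasisFunction", "build_basis", "overlap_matrix", "OverlapConditioningError"]


class OverlapConditioningError(ValueError):
    """Overlap matrix numerically singular (near-dependent basis functions)."""


#: 3-Gaussian expansions of zeta=1 Slater shells: (n, l) -> (exponents, coefficients).
#: 1s/2s/2p are the standard published STO-3G fits; 3s/3p were fitted once by
#: the same overlap-maximization criterion (see scratch/fit_sto3.py history in
#: the repository).  Contractions are renormalized at build time, so only the
#: coefficient ratios are significant here.
STO3G_EXPANSIONS: dict[tuple[int, str], tuple[tuple[float, ...], tuple[float, ...]]] = {
    (1, "s"): (
        (2.227660584, 0.405771156, 0.109818),
        (0.154328967, 0.535328142, 0.444634542),
    ),
    (2, "s"): (
        (0.994203, 0.231031, 0.0751386),
        (-0.09996723, 0.39951283, 0.70011547),
    ),
    (2, "p"): (
        (0.994203, 0.231031, 0.0751386),
        (0.15591627, 0.60768372, 0.39195739),
    ),
    (3, "s"): (
        (0.56414868, 0.06924421, 0.03269528),
        (-0.63190746, 3.05314500, 0.80180165),
    ),
    (3, "p"): (
        (0.16374447, 0.07248319, 0.03560744),
        (0.80896158, 1.14436678, 0.23522106),
    ),
}

_NPRIM = 3


@dataclass(frozen=True)
class BasisFunction:
    """One atom-centered basis function (atom index, shell label, component)."""

    atom: int
    shell: str  # e.g. "2s", "2p"
    m: int      # 0 for s; 0,1,2 = x,y,z for p


class BasisSet:
    """Valence minimal basis for a fixed element sequence.

    Holds the per-function bookkeeping plus precomputed primitive-pair tables
    used by :func:`overlap_matrix`.  A :class:`BasisSet` is tied to the element
    sequence it was built for, not to one particular set of coordinates.
    """

    def __init__(self, elements: tuple[str, ...], table: ParameterTable):
        self.elements = tuple(elements)
        self.table = table
        shells: list[tuple[int, int, str, np.ndarray, np.ndarray, float]] = []
        functions: list[BasisFunction] = []
        atom_ranges: list[tuple[int, int]] = []
        onsite: list[float] = []
        for ia, el in enumerate(elements):
            par: ElementParams = table[el]
            start = len(functions)
            for shell in par.shells:
                exps, coefs = _scaled_expansion(shell.n, shell.l, shell.zeta)
                l = 0 if shell.l == "s" else 1
                fidx = len(functions)
                ncomp = 1 if l == 0 else 3
                for m in range(ncomp):
                    functions.append(BasisFunction(ia, f"{shell.n}{shell.l}", m))
                    onsite.append(shell.h_onsite)
                shells.append((ia, l, f"{shell.n}{shell.l}", exps, coefs, fidx))
            atom_ranges.append((start, len(functions)))
        self.functions = tuple(functions)
        self.atom_ranges = tuple(atom_ranges)
        self.onsite_energies = np.array(onsite)
        self._shells = shells
        self.n_functions = len(functions)
        self._build_pair_tables()

    def __len__(self) -> int:
        return self.n_functions

    # -- precomputed primitive-pair tables ---------------------------------

    def _build_pair_tables(self) -> None:
        nbf = self.n_functions
        ss: list[tuple] = []  # (flat_idx, atom_i, atom_j, mu, pref)
        sp: list[tuple] = []  # (f_s, f_p, atom_s, atom_p, mu, pref, a_s/p)
        pp: list[tuple] = []  # (f_i, f_j, atom_i, atom_j, mu, pref, ab/p^2, 1/2p)
        shells = self._shells
        for si in range(len(shells)):
            ai, li, _, ei, ci, fi = shells[si]
            for sj in range(si, len(shells)):
                aj, lj, _, ej, cj, fj = shells[sj]
                for a, ca in zip(ei, ci):
                    for b, cb in zip(ej, cj):
                        p = a + b
                        mu = a * b / p
                        base = ca * cb * (np.pi / p) ** 1.5
                        if li == 0 and lj == 0:
                            ss.append((fi * nbf + fj, ai, aj, mu, base))
                        elif li == 0 and lj == 1:
                            sp.append((fi, fj, ai, aj, mu, base, a / p))
                        elif li == 1 and lj == 0:
                            sp.append((fj, fi, aj, ai, mu, base, b / p))
                        else:
                            pp.append((fi, fj, ai, aj, mu, base, a * b / p**2, 0.5 / p))
        def cols(rows, types):
            if not rows:
                return [np.empty(0, t) for t in types]
            arr = list(zip(*rows))
            return [np.asarray(col, t) for col, t in zip(arr, types)]

        self._ss = cols(ss, (np.intp, np.intp, np.intp, float, float))
        self._sp = cols(sp, (np.intp, np.intp, np.intp, np.intp, float, float, float))
        self._pp = cols(pp, (np.intp, np.intp, np.intp, np.intp, float, float, float, float))
        # normalization: scale coefficients so diagonal overlaps are exactly 1.
        s_diag = np.diag(self._raw_overlap(np.zeros((len(self.elements), 3))))
        scale = 1.0 / np.sqrt(s_diag)
        self._apply_norm(scale)

    def _apply_norm(self, scale: np.ndarray) -> None:
        idx, ai, aj, mu, pref = self._ss
        self._ss = (idx, ai, aj, mu, pref * scale[idx // self.n_functions] * scale[idx % self.n_functions])
        fs, fp, as_, ap, mu, pref, asp = self._sp
        self._sp = (fs, fp, as_, ap, mu, pref * scale[fs] * scale[fp], asp)
        fi, fj, ai, aj, mu, pref, abp2, i2p = self._pp
        self._pp = (fi, fj, ai, aj, mu, pref * scale[fi] * scale[fj], abp2, i2p)

    def _raw_overlap(self, coords: np.ndarray) -> np.ndarray:
        """Overlap with all atoms at the given coordinates (bohr)."""
        return self.flat_to_full(self._flat_upper(coords), self.n_functions)

    # -- incremental updates for single-atom displacements -----------------

    def _build_atom_masks(self) -> None:
        """Per-atom pre-sliced primitive-pair tables for fast single-atom
        displacement updates (same-atom pairs are rigid and excluded)."""
        idx, ai, aj, mu, pref = self._ss
        fs, fp, as_, ap, mu2, pref2, asp = self._sp
        fi, fj, ai3, aj3, mu3, pref3, abp2, i2p = self._pp
        self._atom_masks = []
        for a in range(len(self.elements)):
            mss = np.nonzero(((ai == a) | (aj == a)) & (ai != aj))[0]
            msp = np.nonzero(((as_ == a) | (ap == a)) & (as_ != ap))[0]
            mpp = np.nonzero(((ai3 == a) | (aj3 == a)) & (ai3 != aj3))[0]
            ss = tuple(col[mss] for col in self._ss)
            sp = tuple(col[msp] for col in self._sp)
            pp = tuple(col[mpp] for col in self._pp)
            self._atom_masks.append((ss, sp, pp))

    def _flat_upper(self, coords: np.ndarray) -> np.ndarray:
        """Upper (scatter) representation of the overlap as a flat array."""
        nbf = self.n_functions
        flat = np.zeros(nbf * nbf)
        self._accumulate(flat, coords, None)
        return flat

    def _accumulate(self, flat: np.ndarray, coords: np.ndarray, masks) -> None:
        """Scatter primitive-pair contributions into ``flat``; ``masks``
        optionally restricts to the pre-sliced subsets of one atom."""
        nbf = self.n_functions
        if masks is None:
            idx, ai, aj, mu, pref = self._ss
            fs, fp, as_, ap, mu2, pref2, asp = self._sp
            fi, fj, ai3, aj3, mu3, pref3, abp2, i2p = self._pp
        else:
            ss, sp, pp = masks
            idx, ai, aj, mu, pref = ss
            fs, fp, as_, ap, mu2, pref2, asp = sp
            fi, fj, ai3, aj3, mu3, pref3, abp2, i2p = pp
        if idx.size:
            d = coords[ai] - coords[aj]
            r2 = np.einsum("ij,ij->i", d, d)
            flat += np.bincount(idx, pref * np.exp(-mu * r2), minlength=flat.size)
        if fs.size:
            vec = coords[as_] - coords[ap]
            r2 = np.einsum("ij,ij->i", vec, vec)
            e = pref2 * np.exp(-mu2 * r2) * asp
            base = fs * nbf + fp
            for m in range(3):
                flat += np.bincount(base + m, e * vec[:, m], minlength=flat.size)
        if fi.size:
            d = coords[ai3] - coords[aj3]
            r2 = np.einsum("ij,ij->i", d, d)
            e = pref3 * np.exp(-mu3 * r2)
            base = fi * nbf + fj
            for m in range(3):
                dm = d[:, m]
                for n_ in range(3):
                    val = -abp2 * dm * d[:, n_]
                    if m == n_:
                        val = val + i2p
                    flat += np.bincount(base + m * nbf + n_, e * val,
                                        minlength=flat.size)

    def atom_flat(self, coords: np.ndarray, atom: int) -> np.ndarray:
        """Flat scatter array holding only the pair contributions that
        involve ``atom`` (excluding rigid same-atom blocks)."""
        if not hasattr(self, "_atom_masks"):
            self._build_atom_masks()
        flat = np.zeros(self.n_functions * self.n_functions)
        self._accumulate(flat, coords, self._atom_masks[atom])
        return flat

    @staticmethod
    def flat_to_full(flat: np.ndarray, nbf: int) -> np.ndarray:
        upper = flat.reshape(nbf, nbf)
        s = upper + upper.T
        s[np.arange(nbf), np.arange(nbf)] *= 0.5
        return s

    # The s-p block convention above: the scatter always writes the (s-row,
    # p-column) entry.  When the s shell comes later in the shell list the
    # entry lands below the diagonal instead; the symmetrization handles both.


def _scaled_expansion(n: int, l: str, zeta: float) -> tuple[np.ndarray, np.ndarray]:
    try:
        exps, coefs = STO3G_EXPANSIONS[(n, l)]
    except KeyError:
        raise ValueError(f"no Gaussian expansion for shell {n}{l}") from None
    exps = np.asarray(exps) * zeta**2
    coefs = np.asarray(coefs, float).copy()
    # fold primitive normalization in (contraction renormalized afterwards)
    if l == "s":
        coefs *= (2.0 * exps / np.pi) ** 0.75
    else:
        coefs *= (2.0 * exps / np.pi) ** 0.75 * 2.0 * np.sqrt(exps)
    return exps, coefs


def build_basis(geometry: Geometry, table: ParameterTable | None = None) -> BasisSet:
    """Construct the valence minimal basis for a geometry's element sequence."""
    table = table or get_default_table()
    for el in geometry.elements:
        if el not in table:
            raise GeometryError(f"element {el} not in parameter table")
    return BasisSet(geometry.elements, table)


def overlap_matrix(basis: BasisSet, geometry: Geometry) -> np.ndarray:
    """Overlap matrix S (symmetric, unit diagonal) at the geometry's coordinates.

    Raises
    ------
    OverlapConditioningError
        If S is numerically singular (smallest eigenvalue < 1e-10), naming
        the closest atom pair as the likely culprit.
    """
    if geometry.elements != basis.elements:
        raise GeometryError("geometry element sequence does not match basis")
    s = basis._raw_overlap(geometry.coords)
    w = np.linalg.eigvalsh(s)
    if w[0] < 1e-10:
        d = np.linalg.norm(
            geometry.coords[:, None, :] - geometry.coords[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise OverlapConditioningError(
            f"overlap matrix singular (min eigenvalue {w[0]:.3e}); "
            f"closest atom pair: {geometry.elements[i]}{i}-{geometry.elements[j]}{j} "
            f"at {d[i, j]:.3f} bohr"
        )
    return s
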
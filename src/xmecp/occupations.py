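"""Reference occupation vectors (with holes) and hole-tolerant Fermi smearing.

A diabatic electronic state is encoded by a per-spin *reference occupation*:
a 0/1 vector over the energy-ordered spatial orbitals, which may contain
holes (an empty orbital below a filled one).  At electronic temperature
``T_el`` each spin channel is fractionally smeared around its reference via

    n'_i = ref_i + (1 - 2 ref_i) * h(|eps_i - eps_F| / k_B T_el),
    h(z) = exp(-z) / (1 + exp(-z)),

a two-sided Fermi-type distribution centered on the spin channel's Fermi
level.  For an Aufbau reference this reduces exactly to ordinary Fermi-Dirac
smearing; for references with holes it lets higher orbitals smear partially
back into the hole.  The Fermi level of each spin channel is adjusted so the
smeared occupations sum to that channel's electron count.  No electronic
entropy term is computed from the fractional occupations: the state energy is
the plain occupation-weighted orbital-energy sum, so a gap penalty built on
these energies can reach zero at a crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import KB_HARTREE

__all__ = [
    "ReferenceOccupation",
    "FractionalOccupation",
    "make_state",
    "fermi_level",
    "smear",
    "parse_excitation",
    "DEFAULT_T_EL",
]

#: Default electronic temperature (K) for fractional occupations.
DEFAULT_T_EL = 3000.0


class OccupationError(ValueError):
    """Invalid occupation specification."""


class FermiLevelError(RuntimeError):
    """Particle-number equation for the Fermi level could not be solved."""


@dataclass(frozen=True)
class ReferenceOccupation:
    """Per-spin 0/1 reference occupations defining one diabatic state."""

    label: str
    alpha_ref: np.ndarray
    beta_ref: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_ref, float)
        b = np.asarray(self.beta_ref, float)
        if a.shape != b.shape or a.ndim != 1:
            raise OccupationError("alpha/beta reference vectors must be equal-length 1-D")
        for v in (a, b):
            if not np.all((v == 0.0) | (v == 1.0)):
                raise OccupationError("reference occupations must be 0 or 1")
        object.__setattr__(self, "alpha_ref", a)
        object.__setattr__(self, "beta_ref", b)

    @property
    def n_alpha(self) -> int:
        return int(round(self.alpha_ref.sum()))

    @property
    def n_beta(self) -> int:
        return int(round(self.beta_ref.sum()))

    @property
    def n_orbitals(self) -> int:
        return self.alpha_ref.size

    @property
    def total_ref(self) -> np.ndarray:
        """Net per-orbital reference occupation (0, 1 or 2)."""
        return self.alpha_ref + self.beta_ref

    def has_holes(self) -> bool:
        """True if some orbital is empty below a filled one in either spin."""
        for v in (self.alpha_ref, self.beta_ref):
            filled = np.nonzero(v)[0]
            if filled.size and np.any(v[: filled[-1]] == 0.0):
                return True
        return False


@dataclass(frozen=True)
class FractionalOccupation:
    """Smeared per-spin occupations with the per-spin Fermi levels used."""

    n_alpha_prime: np.ndarray
    n_beta_prime: np.ndarray
    fermi_level_alpha: float
    fermi_level_beta: float
    t_el: float

    @property
    def total(self) -> np.ndarray:
        """n'_i = n'_{i,alpha} + n'_{i,beta} per spatial orbital."""
        return self.n_alpha_prime + self.n_beta_prime


def parse_excitation(spec: str | int, n_occ: int) -> int:
    """Resolve an orbital spec like ``"HOMO-1"`` or ``"LUMO+2"`` to a 0-based index.

    ``n_occ`` is the Aufbau electron count of the spin channel, so HOMO is
    index ``n_occ - 1`` and LUMO is ``n_occ``.  Plain integers pass through.
    """
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    s = spec.strip().upper().replace(" ", "")
    for anchor, base in (("HOMO", n_occ - 1), ("LUMO", n_occ)):
        if s.startswith(anchor):
            rest = s[len(anchor):]
            off = int(rest) if rest else 0
            return base + off
    raise OccupationError(f"cannot parse orbital spec {spec!r}")


def make_state(
    label: str,
    n_alpha: int,
    n_beta: int,
    excitation_spec=(),
    n_orbitals: int | None = None,
) -> ReferenceOccupation:
    """Build a reference occupation from the Aufbau filling plus excitations.

    ``excitation_spec`` is a sequence of moves ``(from, to, spin)`` applied in
    order to the Aufbau vector; ``from``/``to`` may be 0-based orbital indices
    or strings like ``"HOMO"``, ``"HOMO-1"``, ``"LUMO+1"`` resolved against
    the spin channel's Aufbau filling; ``spin`` is ``"alpha"`` or ``"beta"``.

    Examples: GS = no moves; OS1 = ``[("HOMO", "LUMO", "alpha")]``;
    CS1 = HOMO->LUMO in both spins; OS2 = ``[("HOMO-1", "LUMO", "alpha")]``.
    """
    if n_orbitals is None:
        raise OccupationError("n_orbitals is required to size the occupation vectors")
    if not (0 < n_alpha <= n_orbitals and 0 <= n_beta <= n_orbitals):
        raise OccupationError(
            f"electron counts ({n_alpha}, {n_beta}) incompatible with {n_orbitals} orbitals"
        )
    vecs = {
        "alpha": np.concatenate([np.ones(n_alpha), np.zeros(n_orbitals - n_alpha)]),
        "beta": np.concatenate([np.ones(n_beta), np.zeros(n_orbitals - n_beta)]),
    }
    counts = {"alpha": n_alpha, "beta": n_beta}
    for move in excitation_spec:
        src, dst, spin = move
        spin = spin.lower()
        if spin not in vecs:
            raise OccupationError(f"spin must be 'alpha' or 'beta', got {spin!r}")
        i = parse_excitation(src, counts[spin])
        j = parse_excitation(dst, counts[spin])
        v = vecs[spin]
        if not (0 <= i < n_orbitals and 0 <= j < n_orbitals):
            raise OccupationError(f"orbital index out of range in move {move}")
        if v[i] != 1.0:
            raise OccupationError(f"cannot excite from empty orbital {i} ({spin})")
        if v[j] != 0.0:
            raise OccupationError(f"cannot excite into filled orbital {j} ({spin})")
        v[i], v[j] = 0.0, 1.0
    return ReferenceOccupation(label=label, alpha_ref=vecs["alpha"], beta_ref=vecs["beta"])


# ---------------------------------------------------------------------------
# Smearing
# ---------------------------------------------------------------------------

def _h(z: np.ndarray) -> np.ndarray:
    """Two-sided Fermi factor h(z) = 1/(1+e^z) for z >= 0, overflow-safe."""
    ez = np.exp(-z)
    return ez / (1.0 + ez)


def _occupations_at(eps: np.ndarray, ref: np.ndarray, ef: float, kt: float) -> np.ndarray:
    z = np.abs(eps - ef) / kt
    h = _h(z)
    return ref + (1.0 - 2.0 * ref) * h


def _frontier_midpoint(eps: np.ndarray, ref: np.ndarray) -> float:
    """Midpoint of the highest reference-filled and lowest reference-empty level."""
    filled = np.nonzero(ref == 1.0)[0]
    empty = np.nonzero(ref == 0.0)[0]
    if empty.size == 0:
        return float(eps[-1])
    if filled.size == 0:
        return float(eps[0])
    return 0.5 * (float(eps[filled[-1]]) + float(eps[empty[0]]))


def fermi_level(
    orbital_energies: np.ndarray,
    ref_occ_sigma: np.ndarray,
    n_sigma: int,
    t_el: float,
    tol: float = 1e-10,
    guess: float | None = None,
) -> float:
    """Fermi level of one spin channel, adjusted to conserve its electron count.

    The initial guess is the midpoint of the channel's frontier orbital
    energies; the particle-number residual sum_i n'_i(eps_F) - n_sigma is then
    solved on the sign change nearest that guess within the bracket
    [eps_min - 10 k_B T, eps_max + 10 k_B T].
    """
    eps = np.asarray(orbital_energies, float)
    ref = np.asarray(ref_occ_sigma, float)
    if t_el < 0:
        raise ValueError("electronic temperature must be non-negative")
    if not (0 < n_sigma <= eps.size):
        raise OccupationError(f"n_sigma={n_sigma} out of range for {eps.size} orbitals")
    if int(round(ref.sum())) != n_sigma:
        raise OccupationError("reference occupation does not sum to n_sigma")
    warm = guess is not None
    if guess is None:
        guess = _frontier_midpoint(eps, ref)
    if t_el == 0.0 or n_sigma == eps.size:
        return guess
    kt = KB_HARTREE * t_el

    def residual(ef: float) -> float:
        return float(np.sum(_occupations_at(eps, ref, ef, kt)) - n_sigma)

    def residual_grid(grid: np.ndarray) -> np.ndarray:
        z = np.abs(eps[None, :] - grid[:, None]) / kt
        ez = np.exp(-z)
        occ = ref[None, :] + (1.0 - 2.0 * ref[None, :]) * (ez / (1.0 + ez))
        return occ.sum(axis=1) - n_sigma

    if abs(residual(guess)) <= tol:
        return guess

    if warm:
        # warm start (e.g. finite-difference displacements): the root moved
        # only slightly, try a tight bracket around the guess first
        for w in (5e-4, 5e-3):
            a, b = guess - w, guess + w
            ra, rb = residual(a), residual(b)
            if ra == 0.0:
                return a
            if rb == 0.0:
                return b
            if ra * rb < 0:
                ef = float(brentq(residual, a, b, xtol=1e-14, maxiter=200))
                if abs(residual(ef)) <= tol:
                    return ef
                break

    def solve_on(grid: np.ndarray) -> float | None:
        vals = residual_grid(grid)
        sign = np.sign(vals)
        crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        if crossings.size:
            mids = 0.5 * (grid[crossings] + grid[crossings + 1])
            k = int(np.argmin(np.abs(mids - guess)))
            a, b = grid[crossings[k]], grid[crossings[k] + 1]
            ef = float(brentq(residual, a, b, xtol=1e-14, maxiter=200))
            if abs(residual(ef)) <= tol:
                return ef
        zeros = np.nonzero(np.abs(vals) <= tol)[0]
        if zeros.size:
            k = int(np.argmin(np.abs(grid[zeros] - guess)))
            return float(grid[zeros[k]])
        return None

    # the balancing root lies in the frontier region; try a narrow window
    # first and fall back to the full bracket
    w = 20.0 * kt
    ef = solve_on(np.linspace(guess - w, guess + w, 101))
    if ef is None:
        lo = float(eps.min()) - 10.0 * kt
        hi = float(eps.max()) + 10.0 * kt
        ef = solve_on(np.linspace(lo, hi, 2001))
    if ef is None:
        raise FermiLevelError(
            f"no Fermi level conserves n_sigma={n_sigma} within {tol} electrons"
        )
    return ef


def _smear_channel(eps: np.ndarray, ref: np.ndarray, n_sig: int, t_el: float,
                   guess: float | None = None):
    """Smeared occupations and Fermi level for one spin channel.

    Primary route: solve the particle-number equation for eps_F.  For exotic
    hole references the folded distribution's residual may never cross zero
    (e.g. a single filled orbital below several empties: every eps_F gains
    more into the empties than it releases); then a balanced construction is
    used instead: eps_F stays at the frontier midpoint and the loss side and
    gain side of the smearing are rescaled to the smaller of the two, which
    conserves the electron count exactly and keeps the T->0 limit.
    """
    if n_sig == 0:
        return np.zeros_like(eps), float(eps[0])
    try:
        ef = fermi_level(eps, ref, n_sig, t_el, guess=guess)
        if t_el == 0.0 or n_sig == eps.size:
            return ref.copy(), ef
        return _occupations_at(eps, ref, ef, KB_HARTREE * t_el), ef
    except FermiLevelError:
        ef = _frontier_midpoint(eps, ref)
        h = _h(np.abs(eps - ef) / (KB_HARTREE * t_el))
        loss = float(np.sum(h[ref == 1.0]))
        gain = float(np.sum(h[ref == 0.0]))
        t = min(loss, gain)
        n = ref.copy()
        if t > 0.0:
            n[ref == 1.0] -= h[ref == 1.0] * (t / loss)
            n[ref == 0.0] += h[ref == 0.0] * (t / gain)
        return n, ef


def smear(
    orbital_energies: np.ndarray,
    reference_occ: ReferenceOccupation,
    t_el: float = DEFAULT_T_EL,
    guesses: tuple[float, float] | None = None,
) -> FractionalOccupation:
    """Fractional occupations for one reference at electronic temperature T_el.

    Per-spin electron counts are conserved to 1e-10; at ``t_el == 0`` the
    reference is returned exactly.  Orbitals above a predefined hole smear
    partially back into the hole at finite temperature.
    """
    eps = np.asarray(orbital_energies, float)
    if reference_occ.n_orbitals != eps.size:
        raise OccupationError(
            f"reference has {reference_occ.n_orbitals} orbitals, energies {eps.size}"
        )
    # closed-shell shortcut: identical alpha/beta channels share one solve
    ga, gb = guesses if guesses is not None else (None, None)
    if reference_occ.n_alpha == reference_occ.n_beta and np.array_equal(
        reference_occ.alpha_ref, reference_occ.beta_ref
    ):
        n, ef = _smear_channel(eps, reference_occ.alpha_ref, reference_occ.n_alpha,
                               t_el, guess=ga)
        return FractionalOccupation(
            n_alpha_prime=n,
            n_beta_prime=n.copy(),
            fermi_level_alpha=ef,
            fermi_level_beta=ef,
            t_el=t_el,
        )
    out = {}
    levels = {}
    for spin, ref, n_sig, g in (
        ("alpha", reference_occ.alpha_ref, reference_occ.n_alpha, ga),
        ("beta", reference_occ.beta_ref, reference_occ.n_beta, gb),
    ):
        out[spin], levels[spin] = _smear_channel(eps, ref, n_sig, t_el, guess=g)
    return FractionalOccupation(
        n_alpha_prime=out["alpha"],
        n_beta_prime=out["beta"],
        fermi_level_alpha=levels["alpha"],
        fermi_level_beta=levels["beta"],
        t_el=t_el,
    )
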
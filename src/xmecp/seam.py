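"""The artificial seam potential-energy surface and its gradient.

A minimum-energy crossing point between diabatic states is found by
minimizing, instead of any single state,

    E_seam = E_avg + sum_{(i,j) in pairs} V_gap(E_i - E_j),

where ``E_avg`` is the arithmetic mean over the states being made degenerate
and ``V_gap`` is a smooth, even, non-negative penalty on each listed pair's
energy gap.  The penalty is zero at the seam and grows linearly far from it:

    V_gap(dE) = sigma * [ dE^2 / (|dE| + alpha) + k * (sqrt(dE^2 + alpha^2) - alpha) ]

with interaction strength ``sigma`` (dimensionless), smoothing ``alpha``
(hartree) and far-field bias ``k`` (dimensionless).  At ``k = 0`` this is the
classic smoothed gap penalty of derivative-coupling-free crossing-point
searches; the ``k`` term adds an extra linearly growing bias far from the
seam (asymptotic slope ``sigma * (1 + k)``), which prevents artificial maxima
from forming around the crossing point when the state surfaces separate
steeply.  System-dependent adjustment should be done mainly through sigma.

Because no electronic entropy enters the state energies, the gap of a listed
pair genuinely reaches zero at the converged crossing point (up to the finite
penalty strength), and there E_seam equals E_avg exactly.

Seam gradients follow by the chain rule over per-state gradients:

    dE_seam/dR = (1/n) sum_i g_i + sum_(i,j) V_gap'(E_i - E_j) (g_i - g_j),

so no derivative coupling vectors are ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occupations import DEFAULT_T_EL

__all__ = [
    "SeamParams",
    "energy_average",
    "gap_penalty",
    "gap_penalty_derivative",
    "seam_energy",
    "seam_energy_from_energies",
    "seam_gradient_from_parts",
]


@dataclass(frozen=True)
class SeamParams:
    """Penalty parameters and the list of state pairs to be made degenerate.

    Defaults (sigma 10.0, alpha 0.005, k 0.25) work well across typical
    organic systems.
    """

    sigma: float = 10.0
    alpha: float = 0.005
    k: float = 0.25
    pairs: tuple[tuple[int, int], ...] = ((0, 1),)
    t_el: float = DEFAULT_T_EL

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.alpha <= 0 or self.k <= 0:
            raise ValueError("sigma, alpha and k must all be positive")
        pairs = tuple(tuple(int(x) for x in p) for p in self.pairs)
        if not pairs:
            raise ValueError("at least one state pair is required")
        for p in pairs:
            if len(p) != 2 or p[0] == p[1]:
                raise ValueError(f"invalid state pair {p}")
        object.__setattr__(self, "pairs", pairs)

    @property
    def states_involved(self) -> tuple[int, ...]:
        """Sorted indices of all states appearing in a penalized pair."""
        return tuple(sorted({i for p in self.pairs for i in p}))


def energy_average(energies) -> float:
    """Arithmetic mean of the considered state energies."""
    e = np.asarray(energies, float)
    if e.size == 0:
        raise ValueError("energy_average of an empty state list")
    return float(e.mean())


def gap_penalty(de: float, params: SeamParams) -> float:
    """Gap penalty V_gap(dE): zero at dE=0, even, asymptotically linear."""
    x = abs(float(de))
    a = params.alpha
    return params.sigma * (
        x * x / (x + a) + params.k * (np.hypot(x, a) - a)
    )


def gap_penalty_derivative(de: float, params: SeamParams) -> float:
    """dV_gap/d(dE); evaluated analytically, 0 at dE = 0 by parity."""
    de = float(de)
    if de == 0.0:
        return 0.0
    x = abs(de)
    a = params.alpha
    mag = params.sigma * (
        (x * x + 2.0 * a * x) / (x + a) ** 2 + params.k * x / np.hypot(x, a)
    )
    return mag if de > 0 else -mag


def seam_energy_from_energies(energies, params: SeamParams) -> float:
    """E_seam from a vector of state energies.

    The average runs over the states involved in penalized pairs; for exactly
    degenerate listed pairs the result is E_avg exactly.
    """
    e = np.asarray(energies, float)
    idx = params.states_involved
    if idx[-1] >= e.size:
        raise IndexError(f"pair index {idx[-1]} out of range for {e.size} states")
    e_avg = energy_average(e[list(idx)])
    v = sum(gap_penalty(e[i] - e[j], params) for i, j in params.pairs)
    return e_avg + v


def seam_energy(state_energies, params: SeamParams) -> float:
    """E_seam from a :class:`~xmecp.states.StateEnergies` result."""
    return seam_energy_from_energies(state_energies.energies, params)


def seam_gradient_from_parts(
    energies, gradients: np.ndarray, params: SeamParams
) -> np.ndarray:
    """Chain-rule seam gradient from per-state energies and gradients.

    ``gradients`` has shape (n_states, ...); the result has the trailing
    shape of one state gradient.
    """
    e = np.asarray(energies, float)
    g = np.asarray(gradients, float)
    idx = list(params.states_involved)
    out = g[idx].mean(axis=0)
    for i, j in params.pairs:
        dv = gap_penalty_derivative(e[i] - e[j], params)
        out = out + dv * (g[i] - g[j])
    return out
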
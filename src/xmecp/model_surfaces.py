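"""Analytic multi-state quadratic test surfaces with recoverable crossing points.

Each state is a paraboloid E_i(x) = offset_i + 1/2 (x - x_i)^T H_i (x - x_i)
with a symmetric positive-definite Hessian.  These surfaces serve as an
oracle backend for the seam-search machinery: the exact constrained minimizer
(minimum of the state average subject to degeneracy) is available either in
closed form or from an independent constrained solver certified by its KKT
residual, and the finite-penalty optimum is available from brute-force
minimization of the same penalty surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

from .seam import SeamParams, seam_energy_from_energies, seam_gradient_from_parts

__all__ = [
    "QuadraticStateSurface",
    "QuadraticModel",
    "model_energies",
    "oracle_mecp",
    "penalty_reference_minimum",
    "symmetric_two_state_model",
    "equilateral_three_state_model",
    "random_model",
]


class NoSeamError(RuntimeError):
    """The requested degeneracy region is empty within the search box."""


@dataclass(frozen=True)
class QuadraticStateSurface:
    """One quadratic state: minimum position, Hessian, energy offset."""

    minimum: np.ndarray
    hessian: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        x0 = np.atleast_1d(np.asarray(self.minimum, float))
        h = np.asarray(self.hessian, float)
        if h.shape != (x0.size, x0.size):
            raise ValueError("Hessian shape does not match dimension")
        if not np.allclose(h, h.T, atol=1e-12):
            raise ValueError("Hessian must be symmetric")
        if np.linalg.eigvalsh(h)[0] <= 0:
            raise ValueError("Hessian must be positive definite")
        object.__setattr__(self, "minimum", x0)
        object.__setattr__(self, "hessian", h)

    def energy(self, x: np.ndarray) -> float:
        d = np.asarray(x, float) - self.minimum
        return float(self.offset + 0.5 * d @ self.hessian @ d)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.hessian @ (np.asarray(x, float) - self.minimum)


class QuadraticModel:
    """A set of quadratic states over a common d-dimensional coordinate."""

    def __init__(self, surfaces):
        self.surfaces = tuple(surfaces)
        if not self.surfaces:
            raise ValueError("at least one surface required")
        self.dim = self.surfaces[0].minimum.size
        for s in self.surfaces:
            if s.minimum.size != self.dim:
                raise ValueError("surfaces have inconsistent dimensions")

    @property
    def n_states(self) -> int:
        return len(self.surfaces)

    def energies(self, x: np.ndarray) -> np.ndarray:
        return np.array([s.energy(x) for s in self.surfaces])

    def gradients(self, x: np.ndarray) -> np.ndarray:
        return np.stack([s.gradient(x) for s in self.surfaces])


def model_energies(point: np.ndarray, surfaces) -> tuple[np.ndarray, np.ndarray]:
    """Energies and analytic gradients of all states at ``point``."""
    model = surfaces if isinstance(surfaces, QuadraticModel) else QuadraticModel(surfaces)
    x = np.atleast_1d(np.asarray(point, float))
    if x.size != model.dim:
        raise ValueError(f"point has dimension {x.size}, surfaces {model.dim}")
    return model.energies(x), model.gradients(x)


# ---------------------------------------------------------------------------
# Reference (oracle) solvers
# ---------------------------------------------------------------------------

def _closed_form_two_state_isotropic(model: QuadraticModel, pair) -> np.ndarray | None:
    """Lagrange closed form for two states with equal isotropic Hessians.

    With H_i = h I the constrained minimizer of the average lies on the
    straight line between the two minima: the constraint
    E_i(x) = E_j(x) is affine, and minimizing the average over that
    hyperplane gives the orthogonal projection of the midpoint onto it.
    """
    i, j = pair
    a, b = model.surfaces[i], model.surfaces[j]
    ha = a.hessian
    h = ha[0, 0]
    if not (
        np.allclose(ha, h * np.eye(model.dim), atol=1e-12)
        and np.allclose(b.hessian, h * np.eye(model.dim), atol=1e-12)
    ):
        return None
    # constraint: h (x - xa)^2/2 + oa = h (x - xb)^2/2 + ob  ->  w.x = c
    w = b.minimum - a.minimum
    if np.linalg.norm(w) < 1e-14:
        return None
    c = (
        (np.dot(b.minimum, b.minimum) - np.dot(a.minimum, a.minimum)) / 2.0
        + (b.offset - a.offset) / h
    )
    mid = 0.5 * (a.minimum + b.minimum)
    # minimize |x - mid|^2 s.t. w.x = c  (average is isotropic about mid)
    return mid + (c - w @ mid) / (w @ w) * w


def oracle_mecp(
    surfaces,
    pair=None,
    tol: float = 1e-10,
    n_starts: int = 12,
    seed: int = 0,
) -> np.ndarray:
    """Exact constrained minimizer: min E_avg subject to degeneracy.

    For two states sharing an isotropic Hessian the Lagrange closed form is
    used; otherwise a multi-start SLSQP solve with analytic Jacobians.  The
    result is certified by its KKT residual (stationarity of the Lagrangian
    and constraint violation both < 1e-8), independent of the penalty-based
    seam machinery this package optimizes with.
    """
    model = surfaces if isinstance(surfaces, QuadraticModel) else QuadraticModel(surfaces)
    if pair is None:
        pairs = list(combinations(range(model.n_states), 2))
    elif isinstance(pair[0], (int, np.integer)):
        pairs = [tuple(pair)]
    else:
        pairs = [tuple(p) for p in pair]
    idx = sorted({i for p in pairs for i in p})
    # equality constraints E_i = E_j are transitive: keep a spanning tree of
    # the degeneracy graph so SLSQP sees an independent constraint set
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree_pairs = []
    for (i, j) in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree_pairs.append((i, j))
    pairs = tree_pairs

    if len(pairs) == 1 and len(idx) == 2:
        x = _closed_form_two_state_isotropic(model, pairs[0])
        if x is not None:
            return x

    def favg(x):
        return float(np.mean([model.surfaces[i].energy(x) for i in idx]))

    def gavg(x):
        return np.mean([model.surfaces[i].gradient(x) for i in idx], axis=0)

    cons = []
    for (i, j) in pairs:
        si, sj = model.surfaces[i], model.surfaces[j]
        cons.append(
            dict(
                type="eq",
                fun=lambda x, si=si, sj=sj: si.energy(x) - sj.energy(x),
                jac=lambda x, si=si, sj=sj: si.gradient(x) - sj.gradient(x),
            )
        )

    rng = np.random.default_rng(seed)
    centers = np.stack([model.surfaces[i].minimum for i in idx])
    spread = max(1.0, float(np.max(np.abs(centers))))
    best = None
    for t in range(n_starts):
        x0 = centers.mean(axis=0) if t == 0 else rng.normal(
            centers.mean(axis=0), 0.7 * spread
        )
        res = minimize(
            favg, x0, jac=gavg, constraints=cons, method="SLSQP",
            options=dict(maxiter=500, ftol=1e-14),
        )
        if not res.success:
            continue
        viol = max(abs(c["fun"](res.x)) for c in cons)
        if viol > 1e-7:
            continue
        if best is None or res.fun < best[0] - 1e-12:
            best = (res.fun, res.x, viol)
    if best is None:
        raise NoSeamError("no feasible degeneracy point found within the search")
    _, x, viol = best
    # KKT certification: project average gradient onto constraint normals
    normals = np.stack([c["jac"](x) for c in cons])
    lam, *_ = np.linalg.lstsq(normals.T, gavg(x), rcond=None)
    kkt = np.linalg.norm(gavg(x) - normals.T @ lam)
    if kkt > 1e-6 or viol > 1e-7:
        raise NoSeamError(
            f"constrained solve uncertified (KKT {kkt:.2e}, violation {viol:.2e})"
        )
    return x


def penalty_reference_minimum(
    surfaces,
    params: SeamParams,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Brute-force minimizer of the matched-alpha penalty seam surface.

    Uses scipy BFGS with the analytic chain-rule gradient, polished by
    Nelder-Mead; independent of the package's own quasi-Newton optimizer and
    used to validate it at identical penalty parameters.
    """
    model = surfaces if isinstance(surfaces, QuadraticModel) else QuadraticModel(surfaces)

    def f(x):
        return seam_energy_from_energies(model.energies(x), params)

    def g(x):
        return seam_energy_gradient(model, x, params)

    if x0 is None:
        idx = list(params.states_involved)
        x0 = np.mean([model.surfaces[i].minimum for i in idx], axis=0)
    res = minimize(f, x0, jac=g, method="BFGS", options=dict(gtol=1e-10, maxiter=2000))
    res2 = minimize(f, res.x, method="Nelder-Mead",
                    options=dict(xatol=1e-10, fatol=1e-14, maxiter=5000))
    return res2.x if res2.fun <= res.fun else res.x


def seam_energy_gradient(model: QuadraticModel, x: np.ndarray, params: SeamParams) -> np.ndarray:
    """Analytic chain-rule gradient of the penalty seam energy on a model."""
    return seam_gradient_from_parts(model.energies(x), model.gradients(x), params)


# ---------------------------------------------------------------------------
# Standard instances
# ---------------------------------------------------------------------------

def symmetric_two_state_model(dim: int = 2, offset_second: float = 0.0) -> QuadraticModel:
    """Two unit-Hessian states with minima at -e1 and +e1."""
    e1 = np.zeros(dim)
    e1[0] = 1.0
    eye = np.eye(dim)
    return QuadraticModel([
        QuadraticStateSurface(-e1, eye, 0.0),
        QuadraticStateSurface(+e1, eye, offset_second),
    ])


def equilateral_three_state_model(scale: float = 1.0) -> QuadraticModel:
    """Three unit-Hessian 2-D states at the vertices of an equilateral triangle."""
    eye = np.eye(2)
    verts = scale * np.array(
        [[1.0, 0.0], [-0.5, np.sqrt(3) / 2], [-0.5, -np.sqrt(3) / 2]]
    )
    return QuadraticModel([QuadraticStateSurface(v, eye, 0.0) for v in verts])


def random_model(
    rng: np.random.Generator,
    n_states: int = 2,
    dim: int = 3,
    offset_scale: float = 0.3,
) -> QuadraticModel:
    """A random well-conditioned multi-state quadratic model.

    Hessian eigenvalues are kept in [0.5, 2.0] and minima inside the unit
    box so the seam is non-empty and the penalty surface single-basined for
    reproducible comparisons.
    """
    surfaces = []
    for _ in range(n_states):
        q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
        lam = rng.uniform(0.5, 2.0, size=dim)
        h = q @ np.diag(lam) @ q.T
        h = 0.5 * (h + h.T)
        x0 = rng.uniform(-1.0, 1.0, size=dim)
        off = rng.uniform(-offset_scale, offset_scale)
        surfaces.append(QuadraticStateSurface(x0, h, off))
    return QuadraticModel(surfaces)
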
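"""Geometry optimization on the seam surface and constrained torsional scans.

The workhorse is a limited-memory quasi-Newton (L-BFGS two-loop) minimizer
with a backtracking Armijo line search and a bounded initial step, written to
guarantee descent on the once-differentiable penalty seam surface and to
expose a full per-iteration trace.  Convergence requires both an RMS and a
maximum gradient-component criterion, mirroring common tight-binding
optimizer defaults.  Non-convergence is reported as a flagged result, never
an exception.

Two backends are supported: the tight-binding backend, in which the
coordinates are atomic Cartesians (bohr) and state energies come from one
diagonalization per geometry, and the model-surface backend of analytic
quadratic states used for oracle validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model_surfaces import QuadraticModel
from .occupations import ReferenceOccupation
from .seam import SeamParams, seam_energy_from_energies, seam_gradient_from_parts
from .states import MultiStateEvaluator
from .structures import Geometry, dihedral_from_points
from .params import ParameterTable

__all__ = [
    "OptimizationResult",
    "ScanResult",
    "ScanPoint",
    "optimize_mecp",
    "relaxed_scan",
    "relaxed_scan_segments",
    "minimize_lbfgs",
]

#: Default convergence thresholds, hartree/bohr.
RMS_GRAD_TOL = 1e-4
MAX_GRAD_TOL = 2e-4

#: Harmonic dihedral restraint force constant, hartree/rad^2.  Stiff enough
#: that typical torsional forces (a few 0.01 hartree/rad) track the grid to
#: a fraction of a degree, soft enough not to dominate the relaxation.
DIHEDRAL_FORCE_CONSTANT = 5.0


@dataclass
class TraceStep:
    iteration: int
    energy: float
    grad_rms: float
    grad_max: float
    gaps: tuple[float, ...]


@dataclass
class OptimizationResult:
    """Outcome of a seam (or single-state) minimization."""

    point: np.ndarray                 # final coordinates (flat)
    energies: np.ndarray              # final per-state energies, hartree
    gaps: dict[tuple[int, int], float]  # final listed-pair gaps, hartree
    converged: bool
    reason: str
    trace: list[TraceStep] = field(default_factory=list)
    geometry: Geometry | None = None  # tight-binding backend only

    @property
    def gaps_ev(self) -> dict[tuple[int, int], float]:
        from .constants import HARTREE_TO_EV
        return {p: g * HARTREE_TO_EV for p, g in self.gaps.items()}

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


# ---------------------------------------------------------------------------
# L-BFGS with Armijo backtracking
# ---------------------------------------------------------------------------

def minimize_lbfgs(
    fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    fun: Callable[[np.ndarray], float] | None = None,
    rms_tol: float = RMS_GRAD_TOL,
    max_tol: float = MAX_GRAD_TOL,
    max_iter: int = 500,
    max_step: float = 0.2,
    memory: int = 12,
    armijo_c: float = 1e-4,
    shrink: float = 0.5,
    callback: Callable[[int, np.ndarray, float, np.ndarray], None] | None = None,
) -> tuple[np.ndarray, float, np.ndarray, bool, str, int]:
    """Limited-memory quasi-Newton descent with guaranteed Armijo decrease.

    ``fun``, when given, is a cheap value-only evaluation used for line-search
    trials (for the tight-binding backend the gradient costs ~150 energy
    evaluations, the value one).  ``max_step`` bounds the infinity norm
    (per-coordinate) of every step.  After three consecutive failed line
    searches the history is dropped and a steepest-descent trust step is
    taken.  Returns ``(x, f, g, converged, reason, n_iter)``.
    """
    if fun is None:
        fun = lambda x: fun_grad(x)[0]
    x = np.asarray(x0, float).copy()
    f, g = fun_grad(x)
    s_list: list[np.ndarray] = []
    y_list: list[np.ndarray] = []
    rho: list[float] = []
    fails = 0
    for it in range(1, max_iter + 1):
        rms = float(np.sqrt(np.mean(g * g)))
        gmax = float(np.max(np.abs(g)))
        if callback is not None:
            callback(it - 1, x, f, g)
        if rms < rms_tol and gmax < max_tol:
            return x, f, g, True, "gradient criteria met", it - 1
        # two-loop recursion
        q = g.copy()
        alphas = []
        for s, y, r in zip(reversed(s_list), reversed(y_list), reversed(rho)):
            a = r * (s @ q)
            alphas.append(a)
            q -= a * y
        if y_list:
            gamma = (s_list[-1] @ y_list[-1]) / (y_list[-1] @ y_list[-1])
            q *= gamma
        for (s, y, r), a in zip(zip(s_list, y_list, rho), reversed(alphas)):
            b = r * (y @ q)
            q += (a - b) * s
        d = -q
        if d @ g >= 0:  # not a descent direction: reset
            d = -g
            s_list, y_list, rho = [], [], []
        # bound the initial step
        dmax = float(np.max(np.abs(d)))
        t = min(1.0, max_step / dmax) if dmax > 0 else 1.0
        slope = d @ g
        accepted = False
        for _ in range(30):
            x_new = x + t * d
            f_new = fun(x_new)
            if f_new <= f + armijo_c * t * slope:
                accepted = True
                break
            t *= shrink
        if not accepted:
            fails += 1
            s_list, y_list, rho = [], [], []
            if fails > 3:
                return x, f, g, False, "line search failed repeatedly", it
            # small steepest-descent trust step
            t = max_step / max(float(np.max(np.abs(g))), 1e-8) * 0.01
            x_new = x - t * g
            f_new = fun(x_new)
            if f_new > f:
                return x, f, g, False, "no descent possible", it
        else:
            fails = 0
        f_new, g_new = fun_grad(x_new)
        s = x_new - x
        y = g_new - g
        sy = s @ y
        if sy > 1e-12 * np.linalg.norm(s) * np.linalg.norm(y):
            s_list.append(s)
            y_list.append(y)
            rho.append(1.0 / sy)
            if len(s_list) > memory:
                s_list.pop(0)
                y_list.pop(0)
                rho.pop(0)
        x, f, g = x_new, f_new, g_new
    return x, f, g, False, "maximum iterations reached", max_iter


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class _TightBindingSeam:
    """fun/grad of the seam energy over flattened Cartesians (bohr)."""

    def __init__(self, geometry, states, params: SeamParams, table=None):
        self.ev = MultiStateEvaluator(geometry, tuple(states), params.t_el, table)
        self.params = params

    def energies(self, x: np.ndarray) -> np.ndarray:
        return self.ev.energies_only(x.reshape(-1, 3))

    def value(self, x: np.ndarray) -> float:
        return seam_energy_from_energies(self.energies(x), self.params)

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        es = self.energies(x)
        grads = self.ev.gradients(x.reshape(-1, 3)).reshape(len(es), -1)
        f = seam_energy_from_energies(es, self.params)
        g = seam_gradient_from_parts(es, grads, self.params)
        return f, g


class _ModelSeam:
    def __init__(self, model: QuadraticModel, params: SeamParams):
        self.model = model
        self.params = params

    def energies(self, x: np.ndarray) -> np.ndarray:
        return self.model.energies(x)

    def value(self, x: np.ndarray) -> float:
        return seam_energy_from_energies(self.model.energies(x), self.params)

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        es = self.model.energies(x)
        gs = self.model.gradients(x)
        return (
            seam_energy_from_energies(es, self.params),
            seam_gradient_from_parts(es, gs, self.params),
        )


def optimize_mecp(
    start,
    states=None,
    seam_params: SeamParams | None = None,
    backend: str = "tight-binding",
    max_iter: int = 500,
    table: ParameterTable | None = None,
    rms_tol: float = RMS_GRAD_TOL,
    max_tol: float = MAX_GRAD_TOL,
) -> OptimizationResult:
    """Minimize the penalty seam surface to locate an MECP.

    ``backend="tight-binding"``: ``start`` is a :class:`Geometry` and
    ``states`` a sequence of :class:`ReferenceOccupation`.
    ``backend="model-surface"``: ``start`` is a coordinate vector and
    ``states`` a :class:`QuadraticModel` (or sequence of quadratic states).

    Deterministic: no random initialization anywhere.  On reaching
    ``max_iter`` a flagged non-converged result is returned.
    """
    params = seam_params or SeamParams()
    if backend == "tight-binding":
        if not isinstance(start, Geometry):
            raise TypeError("tight-binding backend expects a Geometry start")
        obj = _TightBindingSeam(start, states, params, table)
        x0 = start.coords.ravel()
    elif backend == "model-surface":
        model = states if isinstance(states, QuadraticModel) else QuadraticModel(states)
        obj = _ModelSeam(model, params)
        x0 = np.atleast_1d(np.asarray(start, float))
    else:
        raise ValueError(f"unknown backend {backend!r}")

    trace: list[TraceStep] = []

    def cb(it, x, f, g):
        es = obj.energies(x)
        gaps = tuple(float(es[i] - es[j]) for i, j in params.pairs)
        trace.append(
            TraceStep(
                iteration=it,
                energy=f,
                grad_rms=float(np.sqrt(np.mean(g * g))),
                grad_max=float(np.max(np.abs(g))),
                gaps=gaps,
            )
        )

    x, f, g, ok, reason, _ = minimize_lbfgs(
        obj, x0, fun=obj.value, rms_tol=rms_tol, max_tol=max_tol,
        max_iter=max_iter, callback=cb,
    )
    es = obj.energies(x)
    gaps = {tuple(p): float(es[p[0]] - es[p[1]]) for p in params.pairs}
    geom = None
    if backend == "tight-binding":
        geom = start.with_coords(x.reshape(-1, 3))
    return OptimizationResult(
        point=x,
        energies=np.asarray(es, float),
        gaps=gaps,
        converged=ok,
        reason=reason,
        trace=trace,
        geometry=geom,
    )


# ---------------------------------------------------------------------------
# Relaxed torsional scan
# ---------------------------------------------------------------------------

def _distal_fragment(geometry: Geometry, j: int, k: int, table) -> np.ndarray:
    """Atom indices on the ``k`` side when the j-k bond is cut.

    Connectivity by the covalent-radius criterion (d < 1.3 (r_i + r_j)); if
    the bond is part of a ring (both endpoints stay connected) only atom
    ``k`` itself is returned, which degrades to a no-op warm start.
    """
    coords = geometry.coords
    n = geometry.n_atoms
    rc = np.array([table[el].r_cov for el in geometry.elements])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cutoff = 1.3 * (rc[:, None] + rc[None, :])
    bonded = (d < cutoff) & ~np.eye(n, dtype=bool)
    bonded[j, k] = bonded[k, j] = False
    seen = {k}
    stack = [k]
    while stack:
        a = stack.pop()
        for b in np.nonzero(bonded[a])[0]:
            if b not in seen:
                seen.add(int(b))
                stack.append(int(b))
    if j in seen:  # ring bond: no clean fragment
        return np.array([k])
    return np.array(sorted(seen))


def _rotate_about(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                  angle: float) -> np.ndarray:
    """Rodrigues rotation of points about an axis through ``origin``."""
    p = points - origin
    c, s = np.cos(angle), np.sin(angle)
    return (
        p * c
        + np.cross(axis, p) * s
        + np.outer(p @ axis, axis) * (1.0 - c)
        + origin
    )

@dataclass
class ScanPoint:
    target_angle: float          # degrees, requested grid value
    measured_angle: float        # degrees, dihedral of the relaxed geometry
    geometry: Geometry
    energies: np.ndarray         # per reported state, hartree
    converged: bool


@dataclass
class ScanResult:
    dihedral_indices: tuple[int, int, int, int]
    points: list[ScanPoint]
    state_labels: tuple[str, ...]

    @property
    def angles(self) -> np.ndarray:
        return np.array([p.target_angle for p in self.points])

    def energy_table(self) -> np.ndarray:
        """(n_points, n_states) array of reported energies."""
        return np.stack([p.energies for p in self.points])

    def gap(self, i: int = 1, j: int = 0) -> np.ndarray:
        t = self.energy_table()
        return t[:, i] - t[:, j]


def relaxed_scan(
    geometry: Geometry,
    dihedral_spec: Sequence[int],
    start_deg: float,
    stop_deg: float,
    step_deg: float,
    relax_state: ReferenceOccupation,
    report_states: Sequence[ReferenceOccupation],
    seam_params: SeamParams | None = None,
    table: ParameterTable | None = None,
    force_constant: float = DIHEDRAL_FORCE_CONSTANT,
    relax_rms_tol: float = 3e-4,
    relax_max_iter: int = 60,
    first_max_iter: int | None = None,
    angle_tol: float = 0.5,
    fd_scheme: str = "central",
) -> ScanResult:
    """Relaxed scan of one dihedral: restrain, relax one state, report many.

    At every grid angle the ``relax_state`` energy plus a harmonic restraint
    on the scanned dihedral is minimized (warm-started from the previous
    relaxed geometry), after which all ``report_states`` are evaluated at the
    relaxed geometry from a single diagonalization.  Non-convergence at a
    grid point is recorded in the per-point flag and the scan continues.
    """
    if step_deg == 0:
        raise ValueError("step must be nonzero")
    params = seam_params or SeamParams()
    i, j, k, l = (int(v) for v in dihedral_spec)
    relax_ev = MultiStateEvaluator(geometry, (relax_state,), params.t_el, table)
    report_ev = MultiStateEvaluator(geometry, tuple(report_states), params.t_el, table)

    n_steps = int(round((stop_deg - start_deg) / step_deg))
    angles = [start_deg + m * step_deg for m in range(n_steps + 1)]

    # Warm-start helper: rotate the fragment on the far side of the scanned
    # bond rigidly about the j-k axis so each grid point starts with the
    # dihedral already on target and zero restraint force.
    rotate_set = _distal_fragment(geometry, j, k, relax_ev.calc.table)

    def rotate_to(x: np.ndarray, current: float, target: float) -> np.ndarray:
        delta = np.radians((target - current + 180.0) % 360.0 - 180.0)
        x3 = x.reshape(-1, 3).copy()
        axis = x3[k] - x3[j]
        axis = axis / np.linalg.norm(axis)
        for sign in (1.0, -1.0):
            cand = x3.copy()
            cand[rotate_set] = _rotate_about(
                x3[rotate_set], x3[j], axis, sign * delta
            )
            phi = dihedral_from_points(cand[i], cand[j], cand[k], cand[l])
            if abs((phi - target + 180.0) % 360.0 - 180.0) < 1e-6:
                return cand.ravel()
        return x  # fall back to the unrotated warm start

    def make_objective(theta0_rad: float):
        def fun(x: np.ndarray) -> float:
            x3 = x.reshape(-1, 3)
            e = float(relax_ev.energies_only(x3)[0])
            phi = np.radians(dihedral_from_points(x3[i], x3[j], x3[k], x3[l]))
            d = (phi - theta0_rad + np.pi) % (2.0 * np.pi) - np.pi
            return e + 0.5 * force_constant * d * d

        def restraint(x3: np.ndarray) -> float:
            phi = np.radians(dihedral_from_points(x3[i], x3[j], x3[k], x3[l]))
            d = (phi - theta0_rad + np.pi) % (2.0 * np.pi) - np.pi
            return 0.5 * force_constant * d * d

        def fun_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
            # state-energy part via the fast displaced-overlap gradient;
            # the restraint term is differenced separately (pure geometry,
            # no electronic structure)
            from .eht import FD_STEP
            x3 = x.reshape(-1, 3)
            g = relax_ev.gradients(x3, scheme=fd_scheme).reshape(-1)
            xl = x.copy()
            for atom in (i, j, k, l):  # only these move the dihedral
                for ax in range(3):
                    m = 3 * atom + ax
                    orig = xl[m]
                    xl[m] = orig + FD_STEP
                    rp = restraint(xl.reshape(-1, 3))
                    xl[m] = orig - FD_STEP
                    rm = restraint(xl.reshape(-1, 3))
                    xl[m] = orig
                    g[m] += (rp - rm) / (2.0 * FD_STEP)
            return fun(x), g

        return fun, fun_grad

    points: list[ScanPoint] = []
    x = geometry.coords.ravel().copy()
    for m_pt, theta in enumerate(angles):
        x3 = x.reshape(-1, 3)
        current = dihedral_from_points(x3[i], x3[j], x3[k], x3[l])
        x = rotate_to(x, current, theta)
        fn, fg = make_objective(np.radians(theta))
        # the first point starts cold from the input geometry and may need a
        # much larger budget than the warm-started rest
        budget = (first_max_iter or relax_max_iter) if m_pt == 0 else relax_max_iter
        x, f, g, ok, reason, _ = minimize_lbfgs(
            fg, x, fun=fn, rms_tol=relax_rms_tol, max_tol=2.0 * relax_rms_tol,
            max_iter=budget,
        )
        x3 = x.reshape(-1, 3)
        measured = dihedral_from_points(x3[i], x3[j], x3[k], x3[l])
        dev = abs((measured - theta + 180.0) % 360.0 - 180.0)
        es = report_ev.energies_only(x3)
        points.append(
            ScanPoint(
                target_angle=float(theta),
                measured_angle=float(measured),
                geometry=geometry.with_coords(x3),
                energies=np.asarray(es, float),
                converged=bool(ok and dev <= angle_tol),
            )
        )
    return ScanResult(
        dihedral_indices=(i, j, k, l),
        points=points,
        state_labels=tuple(s.label for s in report_states),
    )


def relaxed_scan_segments(
    geometry_builder: Callable[[float], Geometry],
    dihedral_spec: Sequence[int],
    segments: Sequence[tuple[float, float, float]],
    relax_state: ReferenceOccupation,
    report_states: Sequence[ReferenceOccupation],
    seam_params: SeamParams | None = None,
    max_rmsd_from_path: float | None = None,
    **scan_kwargs,
) -> ScanResult:
    """Hysteresis-robust scan: sweep several (possibly overlapping) segments
    and keep, per grid angle, the lowest-energy relaxed point.

    ``max_rmsd_from_path`` optionally rejects candidates whose heavy-atom
    Kabsch RMSD (Angstrom) to ``geometry_builder(angle)`` exceeds the bound:
    a warm-started sweep that has collapsed out of the torsional valley
    (e.g. into a stacked conformation) otherwise wins the energy merge with
    a structure that no longer belongs to the scanned path.  If every
    candidate at an angle violates the bound the lowest-energy one is kept
    and flagged unconverged.

    A warm-started sweep can fall into a metastable electronic/geometric
    branch after it passes a state crossing and then drag that branch across
    the rest of the grid.  Sweeping the grid in segments that each *approach*
    the crossings from a cold anchor (``geometry_builder(start)``) and
    merging by the first reported state's energy (by convention the relaxed
    state) keeps the minimum-energy branch everywhere.  For a full torsional
    period the canonical choice is four quarter-sweeps anchored at both
    period ends and the midpoint.
    """
    from .structures import kabsch_rmsd

    candidates: dict[float, list[ScanPoint]] = {}
    labels = None
    idx = tuple(int(v) for v in dihedral_spec)
    for (a, b, s) in segments:
        res = relaxed_scan(
            geometry_builder(a), dihedral_spec, a, b, s, relax_state,
            report_states, seam_params, **scan_kwargs,
        )
        labels = res.state_labels
        for p in res.points:
            candidates.setdefault(round(p.target_angle, 6), []).append(p)

    def on_path(p: ScanPoint) -> bool:
        if max_rmsd_from_path is None:
            return True
        ref = geometry_builder(p.target_angle)
        return kabsch_rmsd(p.geometry, ref, heavy_only=True) <= max_rmsd_from_path

    points = []
    for key in sorted(candidates):
        cands = candidates[key]
        valid = [p for p in cands if on_path(p)]
        if valid:
            points.append(min(valid, key=lambda p: p.energies[0]))
        else:
            best = min(cands, key=lambda p: p.energies[0])
            best.converged = False
            points.append(best)
    return ScanResult(dihedral_indices=idx, points=points, state_labels=labels)
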
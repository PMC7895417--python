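"""Population models of the form R_j = x_j * phi_j(x, a), and their dynamics.

A :class:`PopulationModel` bundles one per-capita growth function ``phi_j``
per population — either an :class:`~ecoimpact.algebra.ImpactExpression`
evaluated against a per-population parameter table, or a raw callable
``phi(x) -> float``.  The structural factorization through ``x_j`` makes
extinction absorbing by construction.

Models built by the zoo/case-study constructors also carry enough raw
parameter arrays to support population splitting (clone tests): ``raw``
maps names to ``(array, population_axes)`` pairs and ``rebuild`` turns a
modified raw dict back into a model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .algebra import ImpactExpression, ParameterTable
from .errors import (
    ConvergenceError,
    DomainEvaluationError,
    EcoimpactError,
    ShapeError,
    SimulationError,
    SingularMatrixError,
)

__all__ = [
    "PopulationModel",
    "Trajectory",
    "FixedPoint",
    "rhs",
    "simulate",
    "interior_fixed_point_linear",
    "refine_fixed_point",
    "classify_trajectory",
]

CONTINUOUS = "continuous"
DISCRETE = "discrete"


@dataclass
class PopulationModel:
    """n coupled populations with right-hand sides x_j * phi_j(x)."""

    n: int
    phis: Sequence  # per j: (ImpactExpression, ParameterTable) | callable(x)->float
    time_mode: str = CONTINUOUS
    frozen: frozenset = field(default_factory=frozenset)
    family: str = "custom"
    raw: dict | None = None  # name -> (ndarray, tuple of population axes)
    rebuild: Callable | None = None  # rebuild(raw) -> PopulationModel

    def __post_init__(self):
        if len(self.phis) != self.n:
            raise ShapeError("need exactly one phi per population")
        if self.time_mode not in (CONTINUOUS, DISCRETE):
            raise ValueError(f"unknown time_mode {self.time_mode!r}")
        self.frozen = frozenset(self.frozen)

    def phi(self, j: int, x) -> float:
        """Per-capita growth of population j at state x."""
        x = np.asarray(x, dtype=float)
        spec = self.phis[j]
        try:
            if isinstance(spec, tuple):
                expr, table = spec
                return expr.evaluate(x, table)
            return float(spec(x))
        except DomainEvaluationError as exc:
            exc.population = j
            raise
        except ValueError as exc:
            raise DomainEvaluationError(str(exc), population=j) from exc

    def is_expression_built(self) -> bool:
        return all(isinstance(spec, tuple) for spec in self.phis)

    def with_frozen(self, indices) -> "PopulationModel":
        return PopulationModel(
            n=self.n,
            phis=self.phis,
            time_mode=self.time_mode,
            frozen=frozenset(indices),
            family=self.family,
            raw=self.raw,
            rebuild=self.rebuild,
        )

    def split(self, j: int) -> "PopulationModel":
        """Clone population j at the parameter level (n -> n + 1).

        Every raw parameter array gets index j duplicated (appended last)
        along each of its population axes; for pairwise matrices this sets
        all four clone-block entries to the original diagonal entry.
        """
        if not 0 <= j < self.n:
            raise IndexError(f"population index {j} outside 0..{self.n - 1}")
        if self.raw is None or self.rebuild is None:
            raise TypeError(
                f"model family {self.family!r} does not support splitting"
            )
        raw2 = {
            name: (duplicate_index(arr, j, axes), axes)
            for name, (arr, axes) in self.raw.items()
        }
        out = self.rebuild(raw2)
        out.frozen = self.frozen
        return out


def duplicate_index(arr: np.ndarray, j: int, axes: tuple) -> np.ndarray:
    """Append a duplicate of index j along each listed axis (done in order)."""
    out = np.asarray(arr)
    for ax in axes:
        out = np.insert(out, out.shape[ax], np.take(out, j, axis=ax), axis=ax)
    return out


def rhs(model: PopulationModel, state) -> np.ndarray:
    """(x_j * phi_j)_j with frozen entries zeroed."""
    x = np.asarray(state, dtype=float)
    if x.size != model.n:
        raise ShapeError("state length does not match model size")
    out = np.empty(model.n)
    for j in range(model.n):
        if j in model.frozen:
            out[j] = 0.0
        elif x[j] == 0.0:
            out[j] = 0.0  # extinction absorbing; avoids needless phi calls
        else:
            out[j] = x[j] * model.phi(j, x)
    return out


@dataclass
class Trajectory:
    """Times, a times x n abundance matrix, and solver metadata."""

    times: np.ndarray
    abundances: np.ndarray
    method: str = ""
    rtol: float = np.nan
    atol: float = np.nan

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.abundances.shape[0] != self.times.size:
            raise ShapeError("abundances must have one row per time point")

    @property
    def final(self) -> np.ndarray:
        return self.abundances[-1]

    def to_tidy_frame(self):
        import pandas as pd

        n = self.abundances.shape[1]
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "population_id": np.tile(np.arange(1, n + 1), self.times.size),
                "abundance": self.abundances.reshape(-1),
            }
        )

    def to_wide_frame(self):
        import pandas as pd

        n = self.abundances.shape[1]
        df = pd.DataFrame(self.abundances, columns=[f"x{j + 1}" for j in range(n)])
        df.insert(0, "time", self.times)
        return df


def simulate(
    model: PopulationModel,
    x0,
    t_grid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "DOP853",
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate (continuous) or iterate (discrete) the model over t_grid.

    Continuous mode uses an adaptive explicit Runge-Kutta scheme at tight
    default tolerances so that integration error stays well below the
    consistency checker's verdict threshold.  Frozen populations keep their
    initial abundance throughout.
    """
    x0 = np.asarray(x0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if x0.size != model.n:
        raise ShapeError("x0 length does not match model size")
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be ascending with at least two points")

    if model.time_mode == DISCRETE:
        steps = np.round(t_grid).astype(int)
        if not np.allclose(t_grid, steps):
            raise ValueError("discrete mode needs an integer-step t_grid")
        x = x0.copy()
        want = dict(zip(steps.tolist(), range(steps.size)))
        out = np.empty((t_grid.size, model.n))
        for t in range(steps[0], steps[-1] + 1):
            if t in want:
                out[want[t]] = x
            x = x + rhs(model, x)
        return Trajectory(t_grid, out, method="map", rtol=np.nan, atol=np.nan)

    if np.any(x0 < 0):
        raise ValueError("continuous mode needs non-negative x0")

    def f(t, x):
        return rhs(model, x)

    try:
        sol = solve_ivp(
            f,
            (t_grid[0], t_grid[-1]),
            x0,
            t_eval=t_grid,
            method=method,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
        )
    except DomainEvaluationError as exc:
        raise SimulationError(
            f"model not evaluable during integration: {exc}"
        ) from exc
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}",
            last_time=sol.t[-1] if sol.t.size else t_grid[0],
            last_state=sol.y[:, -1] if sol.t.size else x0,
        )
    return Trajectory(sol.t, sol.y.T, method=method, rtol=rtol, atol=atol)


@dataclass
class FixedPoint:
    x: np.ndarray
    residual: float
    classification: str  # interior-linear | numeric | boundary

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)


def interior_fixed_point_linear(b: np.ndarray) -> FixedPoint:
    """Solve 0 = 1 + b @ x for the interior fixed point of a linear phi.

    Caller convention: the diagonal of ``b`` is -1 (self-limitation), so the
    condition reads x_j = 1 + sum_{i != j} b_ji x_i.
    """
    b = np.asarray(b, dtype=float)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ShapeError("b must be square")
    if np.linalg.cond(b) > 1e12:
        raise SingularMatrixError("fixed-point system is singular/ill-conditioned")
    x = np.linalg.solve(b, -np.ones(b.shape[0]))
    residual = float(np.max(np.abs(1.0 + b @ x)))
    return FixedPoint(x, residual, "interior-linear")


def refine_fixed_point(
    model: PopulationModel,
    x_guess,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FixedPoint:
    """Root-find R(x) = 0 restricted to the support of x_guess."""
    x_guess = np.asarray(x_guess, dtype=float)
    if np.any(x_guess < 0):
        raise ValueError("x_guess must be non-negative")
    support = x_guess > 0
    if not np.any(support):
        return FixedPoint(np.zeros(model.n), 0.0, "boundary")
    idx = np.flatnonzero(support)

    def embed(xs):
        full = np.zeros(model.n)
        full[idx] = xs
        return full

    def reduced_phi(xs):
        # roots of the per-capita rates: excludes the trivial root at 0 and
        # the singular Jacobian that R = x * phi has near extinction
        full = embed(xs)
        try:
            return np.array([model.phi(j, full) for j in idx])
        except EcoimpactError:
            return np.full(idx.size, 1e6)  # push the solver back in-domain

    def reduced_rhs(xs):
        try:
            return rhs(model, embed(xs))[idx]
        except EcoimpactError:
            return np.full(idx.size, 1e6)

    # perturbed restarts guard against starts with a singular Jacobian
    best = None
    opts = {"maxfev": max_iter * (idx.size + 1) * 10}
    for fn in (reduced_phi, reduced_rhs):
        for scale in (1.0, 0.9, 1.1, 0.5, 1.5, 2.0):
            sol = root(fn, scale * x_guess[idx], method="hybr", options=opts)
            full = embed(sol.x)
            if np.any(full < 0):
                continue
            residual = float(np.max(np.abs(rhs(model, full))))
            if best is None or residual < best[1]:
                best = (full, residual)
            if residual <= tol:
                break
        if best is not None and best[1] <= tol:
            break
    if best is None:
        raise ConvergenceError("fixed-point refinement found no admissible root")
    full, residual = best
    if residual > tol:
        raise ConvergenceError(
            f"fixed-point refinement stalled at residual {residual:.3e}"
        )
    kind = "numeric" if np.all(support) else "boundary"
    return FixedPoint(full, residual, kind)


def classify_trajectory(
    model: PopulationModel,
    traj: Trajectory,
    focal: int = 0,
    aggregate: Sequence[Sequence[int]] | None = None,
    converge_tol: float = 1e-3,
    prominence: float = 0.05,
) -> dict:
    """Label a trajectory as converged / oscillating / undetermined.

    Converged: the endpoint sits within ``converge_tol`` of a refined fixed
    point (aggregated over clone groups if ``aggregate`` is given) and the
    envelope of deviations decreases over the last 20% of the horizon.
    Oscillating: the focal population shows at least three local maxima of
    the given prominence.  The two tests are checked in that order.
    """
    final = traj.final
    try:
        fp = refine_fixed_point(model, np.maximum(final, 1e-12))
        fp_x = fp.x
    except ConvergenceError:
        fp_x = None

    details: dict = {}
    if fp_x is not None:
        if aggregate:
            agg = lambda v: np.array([sum(v[i] for i in grp) for grp in aggregate])
        else:
            agg = lambda v: v
        dist = float(np.linalg.norm(agg(final) - agg(fp_x)))
        details["final_distance"] = dist
        tail = traj.times >= traj.times[0] + 0.8 * (traj.times[-1] - traj.times[0])
        dev = np.linalg.norm(
            np.apply_along_axis(agg, 1, traj.abundances[tail]) - agg(fp_x), axis=1
        )
        env_decreasing = bool(np.max(dev) <= max(dev[0], converge_tol) + 1e-12)
        if dist < converge_tol and env_decreasing:
            details["label"] = "converged"
            details["fixed_point"] = fp_x
            return details
    peaks, _ = find_peaks(traj.abundances[:, focal], prominence=prominence)
    details["n_local_maxima"] = int(peaks.size)
    details["label"] = "oscillating" if peaks.size >= 3 else "undetermined"
    return details
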
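"""Numeric and structural clone-consistency checks.

Black-box functions of ``(x, params)`` are probed against four criteria:

* **I1** commutativity — swapping two (abundance, parameter-row) pairs
  leaves the value unchanged;
* **I2** absent populations — with ``x_1 = 0``, population 1's parameters
  are irrelevant;
* **I3** zero parameters — with all of population 1's parameters zero, its
  abundance is irrelevant;
* **I4** clone consistency — with tied parameter rows, only the summed
  abundance of the tied populations matters.

Probing can only falsify; :func:`certify_structure` gives the complementary
positive answer for expression trees built entirely from the generating
blocks (linear-combination leaves and constants).  Whole models are tested
by cloning one population at the parameter level and comparing aggregate
right-hand sides and trajectories against the unsplit system.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .algebra import (
    BasicImpact,
    Const,
    ImpactExpression,
    Opaque,
    PairwiseImpact,
    ParameterTable,
)
from .dynamics import PopulationModel, Trajectory, duplicate_index, rhs, simulate
from .errors import EcoimpactError, ShapeError, SimulationError

__all__ = [
    "ProbeConfig",
    "Witness",
    "CriterionResult",
    "ConsistencyReport",
    "check_impact_criteria",
    "certify_structure",
    "split_population",
    "split_state",
    "check_model_consistency",
    "CONSISTENT_BY_CONSTRUCTION",
    "UNDECIDABLE",
]

log = logging.getLogger(__name__)

CONSISTENT_BY_CONSTRUCTION = "consistent-by-construction"
UNDECIDABLE = "undecidable"

_EPS = 1e-12  # floor of the relative-deviation denominator


@dataclass
class ProbeConfig:
    """Sampling plan for the numeric checker."""

    n_probes: int = 100
    seed: int = 0
    abundance_low: float = 0.0
    abundance_high: float = 2.0
    parameter_low: float = -1.0
    parameter_high: float = 1.0
    tie_fraction: float = 1.0  # I4 ties must be constructed, not sampled
    tolerance: float = 1e-6

    def __post_init__(self):
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not 0.0 <= self.tie_fraction <= 1.0:
            raise ValueError("tie_fraction must be in [0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def sample_state(self, rng, n):
        return rng.uniform(self.abundance_low, self.abundance_high, size=n)

    def sample_params(self, rng, n, m):
        return rng.uniform(self.parameter_low, self.parameter_high, size=(n, m))


def relative_deviation(u: float, v: float) -> float:
    return abs(u - v) / max(abs(u), abs(v), _EPS)


@dataclass
class Witness:
    """A concrete probe pair demonstrating (or bounding) a deviation."""

    criterion: str
    state: list
    params: list
    transformed_state: list
    transformed_params: list
    value: float
    transformed_value: float
    abs_deviation: float
    rel_deviation: float
    extra: dict = field(default_factory=dict)

    def recomputed_deviation(self) -> float:
        return relative_deviation(self.value, self.transformed_value)


@dataclass
class CriterionResult:
    criterion: str
    verdict: str  # pass | fail | skipped
    worst: Witness | None
    n_evaluated: int
    n_skipped: int
    skip_reason: str | None = None


@dataclass
class ConsistencyReport:
    results: dict
    n_probes: int
    seed: int
    tolerance: float

    @property
    def passed(self) -> bool:
        return all(r.verdict == "pass" for r in self.results.values())

    @property
    def failed(self) -> bool:
        return any(r.verdict == "fail" for r in self.results.values())

    def worst_deviation(self) -> float:
        devs = [
            r.worst.rel_deviation for r in self.results.values() if r.worst is not None
        ]
        return max(devs) if devs else 0.0

    def to_dict(self) -> dict:
        out = {
            "n_probes": self.n_probes,
            "seed": self.seed,
            "tolerance": self.tolerance,
            "passed": self.passed,
            "criteria": {},
        }
        for name, r in self.results.items():
            entry = {
                "verdict": r.verdict,
                "n_evaluated": r.n_evaluated,
                "n_skipped": r.n_skipped,
            }
            if r.skip_reason:
                entry["skip_reason"] = r.skip_reason
            if r.worst is not None:
                entry["worst"] = asdict(r.worst)
            out["criteria"][name] = entry
        return out

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonable, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [f"{'criterion':<12} {'verdict':<8} {'worst rel. deviation':>20}"]
        for name, r in self.results.items():
            dev = f"{r.worst.rel_deviation:.3e}" if r.worst else "-"
            lines.append(f"{name:<12} {r.verdict:<8} {dev:>20}")
        return "\n".join(lines)

    def log_summary(self) -> None:
        log.info("consistency report (seed=%d):\n%s", self.seed, self.summary())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# the numeric criteria checker
# ---------------------------------------------------------------------------


class _Tracker:
    """Accumulates the worst witness and skip count for one criterion."""

    def __init__(self, criterion):
        self.criterion = criterion
        self.worst: Witness | None = None
        self.n_eval = 0
        self.n_skipped = 0
        self.skip_reason: str | None = None

    def record(self, x0, p0, x1, p1, v0, v1, extra=None):
        self.n_eval += 1
        w = Witness(
            criterion=self.criterion,
            state=np.asarray(x0).tolist(),
            params=np.asarray(p0.a).tolist(),
            transformed_state=np.asarray(x1).tolist(),
            transformed_params=np.asarray(p1.a).tolist(),
            value=float(v0),
            transformed_value=float(v1),
            abs_deviation=abs(float(v0) - float(v1)),
            rel_deviation=relative_deviation(v0, v1),
            extra=extra or {},
        )
        if self.worst is None or w.rel_deviation > self.worst.rel_deviation:
            self.worst = w

    def skip(self, reason):
        self.n_skipped += 1
        if self.skip_reason is None:
            self.skip_reason = reason

    def result(self, tolerance) -> CriterionResult:
        if self.n_eval == 0:
            verdict = "skipped"
        elif self.worst is not None and self.worst.rel_deviation > tolerance:
            verdict = "fail"
        else:
            verdict = "pass"
        return CriterionResult(
            criterion=self.criterion,
            verdict=verdict,
            worst=self.worst,
            n_evaluated=self.n_eval,
            n_skipped=self.n_skipped,
            skip_reason=self.skip_reason,
        )


def _call(f, x, params):
    value = f(np.asarray(x, dtype=float), params)
    value = float(value)
    if not np.isfinite(value):
        raise EcoimpactError(f"non-finite value {value}")
    return value


def _make_table(rng, cfg, n, m, n_pairwise):
    a = cfg.sample_params(rng, n, m)
    pairwise = {
        f"P{k + 1}": cfg.sample_params(rng, n, n) for k in range(n_pairwise)
    }
    return ParameterTable(a, pairwise=pairwise)


def _swap_rows(table: ParameterTable, i, j) -> ParameterTable:
    a = table.a.copy()
    a[[i, j]] = a[[j, i]]
    pw = {}
    for name, mat in table.pairwise.items():
        m2 = mat.copy()
        m2[[i, j], :] = m2[[j, i], :]
        m2[:, [i, j]] = m2[:, [j, i]]
        pw[name] = m2
    return ParameterTable(a, list(table.column_names), pw)


def _rerandomize_row(table: ParameterTable, i, rng, cfg) -> ParameterTable:
    a = table.a.copy()
    a[i] = cfg.sample_params(rng, 1, a.shape[1])[0]
    pw = {}
    for name, mat in table.pairwise.items():
        m2 = mat.copy()
        m2[i, :] = cfg.sample_params(rng, 1, m2.shape[1])[0]
        m2[:, i] = cfg.sample_params(rng, 1, m2.shape[0])[0]
        m2[i, i] = rng.uniform(cfg.parameter_low, cfg.parameter_high)
        pw[name] = m2
    return ParameterTable(a, list(table.column_names), pw)


def _zero_row(table: ParameterTable, i) -> ParameterTable:
    a = table.a.copy()
    a[i] = 0.0
    pw = {}
    for name, mat in table.pairwise.items():
        m2 = mat.copy()
        m2[i, :] = 0.0
        m2[:, i] = 0.0
        pw[name] = m2
    return ParameterTable(a, list(table.column_names), pw)


def _tie_rows(table: ParameterTable, i, j) -> ParameterTable:
    """Make populations i and j clones parameter-wise (j copies i)."""
    a = table.a.copy()
    a[j] = a[i]
    pw = {}
    for name, mat in table.pairwise.items():
        m2 = mat.copy()
        m2[j, :] = m2[i, :]
        m2[:, j] = m2[:, i]
        m2[i, j] = m2[j, i] = m2[j, j] = m2[i, i]
        pw[name] = m2
    return ParameterTable(a, list(table.column_names), pw)


def check_impact_criteria(
    f: Callable,
    n: int,
    m: int,
    cfg: ProbeConfig | None = None,
    n_pairwise: int = 0,
) -> ConsistencyReport:
    """Probe a black-box ``f(x, params) -> float`` against criteria I1-I4.

    ``params`` is a :class:`ParameterTable` with ``m`` columns (and
    ``n_pairwise`` sampled pairwise matrices named ``P1..``).  Evaluation
    failures (exceptions, non-finite values) mark the probe skipped for the
    affected criterion rather than aborting the run.
    """
    if cfg is None:
        cfg = ProbeConfig()
    if n < 2:
        raise ValueError("criteria probing needs n >= 2")
    rng = np.random.default_rng(cfg.seed)
    trackers = {c: _Tracker(c) for c in ("I1", "I2", "I3", "I4")}

    for _ in range(cfg.n_probes):
        x = cfg.sample_state(rng, n)
        table = _make_table(rng, cfg, n, m, n_pairwise)
        i, j = rng.choice(n, size=2, replace=False)

        # I1: swap (x_i, a_i) <-> (x_j, a_j)
        t = trackers["I1"]
        x_sw = x.copy()
        x_sw[[i, j]] = x_sw[[j, i]]
        tab_sw = _swap_rows(table, i, j)
        try:
            t.record(x, table, x_sw, tab_sw, _call(f, x, table), _call(f, x_sw, tab_sw))
        except EcoimpactError as exc:
            t.skip(str(exc))
        except Exception as exc:
            t.skip(f"{type(exc).__name__}: {exc}")

        # I2: absent population's parameters are irrelevant
        t = trackers["I2"]
        x0 = x.copy()
        x0[0] = 0.0
        tab_re = _rerandomize_row(table, 0, rng, cfg)
        try:
            t.record(x0, table, x0, tab_re, _call(f, x0, table), _call(f, x0, tab_re))
        except EcoimpactError as exc:
            t.skip(str(exc))
        except Exception as exc:
            t.skip(f"{type(exc).__name__}: {exc}")

        # I3: zero-parameter population's abundance is irrelevant
        t = trackers["I3"]
        tab0 = _zero_row(table, 0)
        x_re = x.copy()
        x_re[0] = cfg.sample_state(rng, 1)[0]
        try:
            t.record(x, tab0, x_re, tab0, _call(f, x, tab0), _call(f, x_re, tab0))
        except EcoimpactError as exc:
            t.skip(str(exc))
        except Exception as exc:
            t.skip(f"{type(exc).__name__}: {exc}")

        # I4: tied parameters -> only the summed abundance matters
        t = trackers["I4"]
        if rng.uniform() <= cfg.tie_fraction:
            tab_tie = _tie_rows(table, 0, 1)
        else:
            tab_tie = table  # ties essentially never occur for sampled reals
        z = rng.uniform(-x[0], x[1])
        x_mv = x.copy()
        x_mv[0] += z
        x_mv[1] -= z
        try:
            t.record(
                x,
                tab_tie,
                x_mv,
                tab_tie,
                _call(f, x, tab_tie),
                _call(f, x_mv, tab_tie),
                extra={"z": float(z)},
            )
        except EcoimpactError as exc:
            t.skip(str(exc))
        except Exception as exc:
            t.skip(f"{type(exc).__name__}: {exc}")

    results = {c: t.result(cfg.tolerance) for c, t in trackers.items()}
    report = ConsistencyReport(
        results=results, n_probes=cfg.n_probes, seed=cfg.seed, tolerance=cfg.tolerance
    )
    report.log_summary()
    return report


# ---------------------------------------------------------------------------
# structural certification
# ---------------------------------------------------------------------------


def certify_structure(e: ImpactExpression) -> str:
    """Certify an expression tree by inspection of its leaves.

    Returns :data:`CONSISTENT_BY_CONSTRUCTION` when every leaf is a
    linear-combination block or a constant (the generating set of the
    impact-function algebra) or :data:`UNDECIDABLE` when the tree contains
    an opaque black-box leaf.  Structure alone can never prove
    *in*consistency, so there is no third verdict.
    """
    if not isinstance(e, ImpactExpression):
        raise TypeError(f"not an expression node: {e!r}")
    if isinstance(e, Opaque):
        return UNDECIDABLE
    if isinstance(e, (BasicImpact, PairwiseImpact, Const)):
        return CONSISTENT_BY_CONSTRUCTION
    verdicts = [certify_structure(c) for c in e.children()]
    if any(v == UNDECIDABLE for v in verdicts):
        return UNDECIDABLE
    return CONSISTENT_BY_CONSTRUCTION


def certify_model(model: PopulationModel) -> str:
    """A model is certified when every per-capita phi is a certified tree."""
    verdicts = []
    for spec in model.phis:
        if isinstance(spec, tuple):
            verdicts.append(certify_structure(spec[0]))
        else:
            verdicts.append(UNDECIDABLE)
    if all(v == CONSISTENT_BY_CONSTRUCTION for v in verdicts):
        return CONSISTENT_BY_CONSTRUCTION
    return UNDECIDABLE


# ---------------------------------------------------------------------------
# population splitting
# ---------------------------------------------------------------------------


def split_state(x, j: int, theta: float) -> np.ndarray:
    """Replace x_j by theta*x_j and append a clone with (1-theta)*x_j."""
    x = np.asarray(x, dtype=float)
    if not 0 <= j < x.size:
        raise IndexError(f"population index {j} outside 0..{x.size - 1}")
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie strictly between 0 and 1")
    out = np.append(x, (1.0 - theta) * x[j])
    out[j] = theta * x[j]
    return out


def split_population(state, params: ParameterTable, j: int, theta: float):
    """Clone population j: duplicate its parameter row (and pairwise
    rows/columns, with the whole clone block equal to the original a_jj)
    and divide its abundance theta : 1-theta between the clones."""
    x = split_state(state, j, theta)
    a = duplicate_index(params.a, j, (0,))
    pw = {
        name: duplicate_index(mat, j, (0, 1)) for name, mat in params.pairwise.items()
    }
    return x, ParameterTable(a, list(params.column_names), pw)


# ---------------------------------------------------------------------------
# whole-model clone-split test
# ---------------------------------------------------------------------------


def check_model_consistency(
    model: PopulationModel,
    cfg: ProbeConfig | None = None,
    horizon: float = 10.0,
    theta: float = 0.5,
    n_grid: int = 101,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    state_sampler: Callable | None = None,
) -> ConsistencyReport:
    """Clone-split test: simulate original vs split systems and compare.

    For each probe state and each population j the model is split at j; the
    instantaneous right-hand sides at t=0 (clone sum vs original, plus all
    untouched populations) and the trajectories on a fixed ``n_grid``-point
    time grid (aggregated over the clone pair) are compared.  The worst
    relative deviation across probes is reported under criterion label
    ``model-split``.
    """
    if cfg is None:
        cfg = ProbeConfig(n_probes=10)
    rng = np.random.default_rng(cfg.seed)
    tracker = _Tracker("model-split")
    t_grid = np.linspace(0.0, horizon, n_grid)

    for _ in range(cfg.n_probes):
        x = (
            state_sampler(rng, model.n)
            if state_sampler is not None
            else cfg.sample_state(rng, model.n)
        )
        for j in range(model.n):
            try:
                split_model = model.split(j)
            except TypeError:
                raise
            xs = split_state(x, j, theta)

            # (i) instantaneous right-hand sides at t = 0
            try:
                r_orig = rhs(model, x)
                r_split = rhs(split_model, xs)
            except EcoimpactError as exc:
                tracker.skip(f"rhs evaluation failed: {exc}")
                continue
            agg = r_split[: model.n].copy()
            agg[j] += r_split[model.n]
            dev_idx = int(np.argmax([relative_deviation(u, v) for u, v in zip(r_orig, agg)]))
            tracker.record(
                x,
                ParameterTable(np.zeros((model.n, 1))),
                xs,
                ParameterTable(np.zeros((model.n + 1, 1))),
                r_orig[dev_idx],
                agg[dev_idx],
                extra={"split_index": j, "theta": theta, "stage": "rhs",
                       "population": dev_idx},
            )

            # (ii) trajectories over the horizon on a fixed grid
            try:
                traj_o = simulate(model, x, t_grid, rtol=rtol, atol=atol)
                traj_s = simulate(split_model, xs, t_grid, rtol=rtol, atol=atol)
            except (SimulationError, EcoimpactError) as exc:
                tracker.skip(f"integration failed: {exc}")
                continue
            agg_y = traj_s.abundances[:, : model.n].copy()
            agg_y[:, j] += traj_s.abundances[:, model.n]
            devs = np.abs(traj_o.abundances - agg_y) / np.maximum(
                np.maximum(np.abs(traj_o.abundances), np.abs(agg_y)), _EPS
            )
            k = np.unravel_index(np.argmax(devs), devs.shape)
            tracker.record(
                x,
                ParameterTable(np.zeros((model.n, 1))),
                xs,
                ParameterTable(np.zeros((model.n + 1, 1))),
                traj_o.abundances[k],
                agg_y[k],
                extra={
                    "split_index": j,
                    "theta": theta,
                    "stage": "trajectory",
                    "time": float(t_grid[k[0]]),
                    "population": int(k[1]),
                },
            )

    results = {"model-split": tracker.result(cfg.tolerance)}
    report = ConsistencyReport(
        results=results, n_probes=cfg.n_probes, seed=cfg.seed, tolerance=cfg.tolerance
    )
    report.log_summary()
    return report
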
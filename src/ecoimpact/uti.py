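"""Microbial-community case study on conditioned-medium observables.

A high-throughput protocol measures, per strain j, the monoculture growth
rate g_j and carrying capacity c_j (abundances normalized so c_j = 1), and,
per ordered pair (j, k), the growth rate g_jk and capacity c_jk of strain j
in medium partially conditioned (fraction v of supernatant) by strain k.
The conditioning footprint is represented as strain k frozen at abundance
v: the cells are removed but what they produced and depleted persists.

Two models consume such a dataset: the *existing* model (growth and
capacity terms with incomplete sums and a solitary x_j inside the
per-capita rate — clone-inconsistent) and the *new* model built from two
complete linear combinations under clamped transforms (consistent by
construction).  A synthetic experiment generator closes the loop: it runs
the protocol on a ground-truth model and recovers the new model's
parameters from the resulting observables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .algebra import Apply, BasicImpact, Const, ParameterTable, Product, Sum
from .dynamics import PopulationModel, rhs, simulate
from .errors import (
    DomainEvaluationError,
    PlateauError,
    ShapeError,
    SingularityError,
)

__all__ = [
    "ConditionedMediumDataset",
    "UTIExistingParams",
    "UTINewParams",
    "SyntheticTruth",
    "make_existing_model",
    "derive_new_params",
    "make_new_model",
    "new_model_from_dataset",
    "validate_constraints",
    "make_synthetic_truth",
    "simulate_experiment",
    "recover_parameters",
    "approximation_bound",
    "RecoveryReport",
]

DEFAULT_V = 0.4
DEFAULT_Q = 10.0
PLATEAU_RATE_TOL = 1e-10
DEFAULT_HORIZON = 1e3


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


@dataclass
class ConditionedMediumDataset:
    """Observables g_j, c_j (= 1), g_jk, c_jk and the conditioning fraction v.

    Matrix convention: row = focal strain j, column = conditioning strain k.
    The self-conditioning diagonal follows c_jj = 1 - v (a strain growing in
    its own conditioned medium can only fill the unconditioned fraction).
    """

    g: np.ndarray
    c: np.ndarray
    g_pair: np.ndarray
    c_pair: np.ndarray
    v: float = DEFAULT_V

    def __post_init__(self):
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.g_pair = np.atleast_2d(np.asarray(self.g_pair, dtype=float))
        self.c_pair = np.atleast_2d(np.asarray(self.c_pair, dtype=float))
        self.v = float(self.v)
        n = self.g.size
        if self.c.size != n or self.g_pair.shape != (n, n) or self.c_pair.shape != (n, n):
            raise ShapeError("dataset array shapes disagree")
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        if not 0.0 < self.v < 1.0:
            raise ValueError("conditioning fraction v must lie in (0, 1)")
        if np.any(self.g <= 0.0):
            raise ValueError("monoculture growth rates must be positive")
        if np.max(np.abs(self.c - 1.0)) > tol:
            raise ValueError("capacities must be normalized to 1")
        if np.max(np.abs(np.diag(self.c_pair) - (1.0 - self.v))) > tol:
            raise ValueError("self-conditioning diagonal must equal 1 - v")

    @property
    def n(self) -> int:
        return self.g.size

    def clone_strain(self, j: int) -> "ConditionedMediumDataset":
        """Duplicate strain j's rows and columns (clone appended last)."""
        from .dynamics import duplicate_index

        return ConditionedMediumDataset(
            g=duplicate_index(self.g, j, (0,)),
            c=duplicate_index(self.c, j, (0,)),
            g_pair=duplicate_index(self.g_pair, j, (0, 1)),
            c_pair=duplicate_index(self.c_pair, j, (0, 1)),
            v=self.v,
        )

    # -- delimited I/O ------------------------------------------------------

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "g.csv", self.g, delimiter=",")
        np.savetxt(path / "c.csv", self.c, delimiter=",")
        np.savetxt(path / "g_pair.csv", self.g_pair, delimiter=",")
        np.savetxt(path / "c_pair.csv", self.c_pair, delimiter=",")
        (path / "meta.json").write_text(json.dumps({"v": self.v}))

    @classmethod
    def from_dir(cls, path) -> "ConditionedMediumDataset":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        return cls(
            g=np.loadtxt(path / "g.csv", delimiter=","),
            c=np.loadtxt(path / "c.csv", delimiter=","),
            g_pair=np.atleast_2d(np.loadtxt(path / "g_pair.csv", delimiter=",")),
            c_pair=np.atleast_2d(np.loadtxt(path / "c_pair.csv", delimiter=",")),
            v=meta["v"],
        )


# ---------------------------------------------------------------------------
# existing model
# ---------------------------------------------------------------------------


@dataclass
class UTIExistingParams:
    """Interaction coefficients of the existing model, derived from data:
    a_ji = g_ji/g_j - 1 and b_ji = c_ji - 1 (c_ji >= 1) or (c_ji - 1)/v."""

    a: np.ndarray
    b: np.ndarray

    @classmethod
    def from_dataset(cls, d: ConditionedMediumDataset) -> "UTIExistingParams":
        if np.any(d.g == 0.0):
            raise ValueError("a_ji undefined for g_j = 0")
        a = d.g_pair / d.g[:, None] - 1.0
        b = np.where(d.c_pair >= 1.0, d.c_pair - 1.0, (d.c_pair - 1.0) / d.v)
        return cls(a=a, b=b)


def make_existing_model(d: ConditionedMediumDataset) -> PopulationModel:
    """phi_j = g_j * clamp(1 + sum_{i!=j} a_ji x_i)
                  * (1 - x_j / clamp(1 + sum_{i!=j} b_ji x_i)).

    Logistic growth whose rate and capacity are both modified by the
    interaction sums; the interior fixed points therefore satisfy
    x_j = 1 + sum_{i!=j} b_ji x_i.  The sums skip i = j and x_j appears
    bare inside phi, so the model cannot be written over the generating
    blocks; it is kept as raw callables and fails the clone-split test.
    """
    p = UTIExistingParams.from_dataset(d)
    g = d.g

    def make_phi(j):
        arow = p.a[j].copy()
        brow = p.b[j].copy()
        arow[j] = 0.0
        brow[j] = 0.0

        def phi(x):
            x = np.asarray(x, dtype=float)
            growth = max(0.0, 1.0 + float(arow @ x))
            cap_limit = max(0.0, 1.0 + float(brow @ x))
            if x[j] > 0.0 and cap_limit <= 0.0:
                raise DomainEvaluationError(
                    "modified capacity is non-positive", population=j
                )
            cap = 1.0 - (x[j] / cap_limit if x[j] > 0.0 else 0.0)
            return g[j] * growth * cap

        return phi

    raw = {
        "g": (d.g, (0,)),
        "g_pair": (d.g_pair, (0, 1)),
        "c_pair": (d.c_pair, (0, 1)),
    }

    def rebuild(raw2):
        g2 = raw2["g"][0]
        return make_existing_model(
            ConditionedMediumDataset(
                g=g2,
                c=np.ones(g2.size),
                g_pair=raw2["g_pair"][0],
                c_pair=raw2["c_pair"][0],
                v=d.v,
            )
        )

    return PopulationModel(
        n=d.n,
        phis=[make_phi(j) for j in range(d.n)],
        family="uti_existing",
        raw=raw,
        rebuild=rebuild,
    )


# ---------------------------------------------------------------------------
# new model
# ---------------------------------------------------------------------------


@dataclass
class UTINewParams:
    """Coefficients of the clone-consistent model: growth interactions r_jk,
    niche coefficients s_jk = (1 - c_jk)/v (diagonal 1), saturation
    exponent q, and the derivation variant used for r."""

    r: np.ndarray
    s: np.ndarray
    q: float = DEFAULT_Q
    variant: str = "approx"  # approx | full

    def __post_init__(self):
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        self.s = np.atleast_2d(np.asarray(self.s, dtype=float))
        if self.r.shape != self.s.shape or self.r.shape[0] != self.r.shape[1]:
            raise ShapeError("r and s must be square and of equal shape")
        if self.q <= 0:
            raise ValueError("saturation exponent q must be positive")
        if self.variant not in ("approx", "full"):
            raise ValueError(f"unknown variant {self.variant!r}")


def derive_new_params(
    d: ConditionedMediumDataset,
    q: float = DEFAULT_Q,
    variant: str = "approx",
) -> UTINewParams:
    """Derive (r, s) from the observables.

    s_jk = (1 - c_jk)/v always.  The growth coefficients come from
    r_jk = (g_jk / sigma(1 - c_jk) - g_j)/v with sigma(z) = 1 - max(0, z)^q
    for the ``full`` variant (singular as c_jk -> 0), or from the large-q
    approximation sigma(1 - c_jk) ~ 1, giving r_jk = (g_jk - g_j)/v.
    """
    s = (1.0 - d.c_pair) / d.v
    if variant == "approx":
        r = (d.g_pair - d.g[:, None]) / d.v
    elif variant == "full":
        bad = np.argwhere(d.c_pair <= 0.0)
        if bad.size:
            j, k = bad[0]
            raise SingularityError(
                f"c_pair[{j},{k}] <= 0: growth coefficient singular as "
                "the conditioned capacity vanishes",
                indices=(int(j), int(k)),
            )
        small = np.argwhere(d.c_pair < 0.05)
        for j, k in small:
            warnings.warn(
                f"c_pair[{j},{k}] = {d.c_pair[j, k]:.3g} < 0.05: derived "
                "growth coefficient may blow up",
                stacklevel=2,
            )
        sigma = 1.0 - np.maximum(0.0, 1.0 - d.c_pair) ** q
        r = (d.g_pair / sigma - d.g[:, None]) / d.v
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return UTINewParams(r=r, s=s, q=q, variant=variant)


def make_new_model(p: UTINewParams, g) -> PopulationModel:
    """phi_j = clamp(g_j + sum_i r_ji x_i) * clamp(1 - clamp(sum_i s_ji x_i)^q).

    Both factors are clamped transforms of complete linear combinations, so
    the model is consistent by construction, and the right-hand side is
    non-negative everywhere: populations never decline (no dilution here).
    """
    g = np.atleast_1d(np.asarray(g, dtype=float))
    n = p.r.shape[0]
    if g.size != n:
        raise ShapeError("growth-rate vector length disagrees with r/s")
    phis = []
    for j in range(n):
        table = ParameterTable(
            np.column_stack([p.r[j], p.s[j]]), ["r", "s"]
        )
        growth = Apply("clamp", [Sum(Const(float(g[j])), BasicImpact("r"))])
        capacity = Apply("capacity", [BasicImpact("s")], {"q": p.q})
        phis.append((Product(growth, capacity), table))
    raw = {"g": (g, (0,)), "r": (p.r, (0, 1)), "s": (p.s, (0, 1))}

    def rebuild(raw2):
        return make_new_model(
            UTINewParams(raw2["r"][0], raw2["s"][0], q=p.q, variant=p.variant),
            raw2["g"][0],
        )

    return PopulationModel(
        n=n, phis=phis, family="uti_new", raw=raw, rebuild=rebuild
    )


def new_model_from_dataset(
    d: ConditionedMediumDataset,
    q: float = DEFAULT_Q,
    variant: str = "approx",
) -> PopulationModel:
    return make_new_model(derive_new_params(d, q=q, variant=variant), d.g)


# ---------------------------------------------------------------------------
# experimental-constraint validation
# ---------------------------------------------------------------------------


def validate_constraints(model: PopulationModel, d: ConditionedMediumDataset) -> dict:
    """Residuals of the four experimental constraints.

    Because R_j = x_j * phi_j structurally, the derivative constraints at
    x_j -> 0 reduce to evaluations of phi_j, so no finite differencing is
    involved:

    * ``growth``: phi_j(0) - g_j                              (n,)
    * ``capacity``: R_j at x = e_j                            (n,)
    * ``conditioned_growth``: phi_j(x_k = v, x_j = 0) - g_jk  (n, n), j != k
    * ``conditioned_capacity``: R_j at (x_j = c_jk, x_k = v)  (n, n), j != k

    Diagonal entries of the pair residuals are NaN (a strain cannot be both
    the grower at abundance 0 and its own frozen footprint in one state).
    """
    n = model.n
    growth = np.empty(n)
    capacity = np.empty(n)
    cond_growth = np.full((n, n), np.nan)
    cond_capacity = np.full((n, n), np.nan)
    zero = np.zeros(n)
    for j in range(n):
        growth[j] = model.phi(j, zero) - d.g[j]
        e_j = zero.copy()
        e_j[j] = 1.0
        capacity[j] = e_j[j] * model.phi(j, e_j)
        for k in range(n):
            if k == j:
                continue
            probe = zero.copy()
            probe[k] = d.v
            cond_growth[j, k] = model.phi(j, probe) - d.g_pair[j, k]
            probe[j] = d.c_pair[j, k]
            cond_capacity[j, k] = probe[j] * model.phi(j, probe)
    return {
        "growth": growth,
        "capacity": capacity,
        "conditioned_growth": cond_growth,
        "conditioned_capacity": cond_capacity,
    }


# ---------------------------------------------------------------------------
# synthetic experiment
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth for the synthetic protocol: the generating model plus
    the parameter tables it was built from and the sampling seed."""

    model: PopulationModel
    g: np.ndarray
    r: np.ndarray
    s: np.ndarray
    q: float
    v: float
    seed: int
    sparsity: float


def make_synthetic_truth(
    seed: int,
    n: int,
    sparsity: float = 0.5,
    v: float = DEFAULT_V,
    q: float = DEFAULT_Q,
) -> SyntheticTruth:
    """Sample a ground-truth model of the new-model form.

    g ~ U[0.5, 1.5]; off-diagonal r ~ U[-0.5, 0.5] and s ~ U[-0.5, 1.2],
    each kept with probability ``sparsity`` (zero otherwise); diagonals are
    pinned to r_jj = 0 and s_jj = 1.  These ranges keep every monoculture
    and pairwise run viable (positive growth up to the capacity root).
    """
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.5, 1.5, size=n)
    r = rng.uniform(-0.5, 0.5, size=(n, n))
    s = rng.uniform(-0.5, 1.2, size=(n, n))
    mask = rng.uniform(size=(n, n)) < sparsity
    r = np.where(mask, r, 0.0)
    s = np.where(mask, s, 0.0)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(s, 1.0)
    model = make_new_model(UTINewParams(r=r, s=s, q=q), g)
    return SyntheticTruth(
        model=model, g=g, r=r, s=s, q=q, v=v, seed=seed, sparsity=sparsity
    )


def _plateau(model, x0, j, horizon, frozen=(), x0_rel=1e-3):
    """Integrate strain j to its growth plateau; return the plateau abundance."""
    m = model.with_frozen(frozen)
    t_grid = np.array([0.0, 0.5 * horizon, horizon])
    traj = simulate(m, x0, t_grid)
    final = traj.final
    rate = rhs(m, final)[j]
    if final[j] <= 0 or abs(rate) / final[j] > PLATEAU_RATE_TOL:
        raise PlateauError(
            f"strain {j} did not plateau within horizon {horizon}", strain=j
        )
    return float(final[j])


def simulate_experiment(
    truth: SyntheticTruth,
    v: float | None = None,
    horizon: float = DEFAULT_HORIZON,
    inoculum: float = 1e-3,
) -> ConditionedMediumDataset:
    """Run the conditioned-medium protocol on a ground-truth model.

    Monocultures give g_j (phi_j at the empty community — exact, since
    R_j = x_j phi_j) and the plateau c_j; abundances are then normalized so
    c_j = 1.  Conditioning by strain k is represented by freezing strain k
    at abundance v * c_k: g_jk is phi_j at that state with x_j = 0, and
    c_jk is strain j's plateau with k frozen.  Self-conditioning (j = k)
    freezes a parameter-level clone of strain j instead, and the diagonal
    capacity follows the convention c_jj = 1 - v.
    """
    model = truth.model
    if v is None:
        v = truth.v
    n = model.n
    zero = np.zeros(n)

    g = np.array([model.phi(j, zero) for j in range(n)])
    if np.any(g <= 0.0):
        raise ValueError("truth model must have positive monoculture growth")

    c_raw = np.empty(n)
    for j in range(n):
        x0 = zero.copy()
        x0[j] = inoculum
        c_raw[j] = _plateau(model, x0, j, horizon)

    g_pair = np.empty((n, n))
    c_pair = np.empty((n, n))
    for k in range(n):
        for j in range(n):
            if j == k:
                clone = model.split(j)  # clone carries j's footprint
                probe = np.zeros(n + 1)
                probe[n] = v * c_raw[j]
                g_pair[j, j] = clone.with_frozen({n}).phi(j, probe)
                c_pair[j, j] = 1.0 - v
                continue
            probe = zero.copy()
            probe[k] = v * c_raw[k]
            g_pair[j, k] = model.with_frozen({k}).phi(j, probe)
            x0 = probe.copy()
            x0[j] = inoculum * c_raw[j]
            plateau = _plateau(model, x0, j, horizon, frozen={k})
            c_pair[j, k] = plateau / c_raw[j]

    return ConditionedMediumDataset(
        g=g, c=np.ones(n), g_pair=g_pair, c_pair=c_pair, v=v
    )


# ---------------------------------------------------------------------------
# end-to-end parameter recovery
# ---------------------------------------------------------------------------


def approximation_bound(d: ConditionedMediumDataset, q: float = DEFAULT_Q) -> np.ndarray:
    """Elementwise bound on |r_recovered - r_true| under the approx variant.

    Exact for ground truths of the new-model form:
    g_jk * max(0, 1-c_jk)^q / (v * (1 - max(0, 1-c_jk)^q)); zero wherever
    c_jk >= 1 (the inner clamp kills the correction entirely).
    """
    t = np.maximum(0.0, 1.0 - d.c_pair) ** q
    with np.errstate(divide="ignore"):
        return np.abs(d.g_pair) * t / (d.v * (1.0 - t))


@dataclass
class RecoveryReport:
    truth: SyntheticTruth
    dataset: ConditionedMediumDataset
    recovered: UTINewParams
    s_error: float
    r_error: np.ndarray
    r_bound: np.ndarray

    @property
    def within_bound(self) -> bool:
        slack = 1e-9
        return bool(np.all(self.r_error <= self.r_bound + slack))

    def to_dict(self) -> dict:
        return {
            "seed": self.truth.seed,
            "n": self.truth.model.n,
            "sparsity": self.truth.sparsity,
            "variant": self.recovered.variant,
            "q": self.recovered.q,
            "s_max_abs_error": self.s_error,
            "r_max_abs_error": float(np.max(self.r_error)),
            "r_bound_max": float(np.max(self.r_bound)),
            "within_bound": self.within_bound,
        }


def recover_parameters(
    seed: int,
    n: int,
    sparsity: float = 0.5,
    v: float = DEFAULT_V,
    q: float = DEFAULT_Q,
    variant: str = "approx",
    horizon: float = DEFAULT_HORIZON,
) -> RecoveryReport:
    """Generate a synthetic truth, run the protocol, re-derive parameters.

    The niche coefficients s come back exactly (up to plateau tolerance);
    the growth coefficients r carry the documented closed-form error of the
    large-q approximation (zero for the ``full`` variant).
    """
    if n > 8:
        raise ValueError("recovery is a desk-scale check; use n <= 8")
    truth = make_synthetic_truth(seed, n, sparsity=sparsity, v=v, q=q)
    dataset = simulate_experiment(truth, v=v, horizon=horizon)
    recovered = derive_new_params(dataset, q=q, variant=variant)
    s_error = float(np.max(np.abs(recovered.s - truth.s)))
    r_error = np.abs(recovered.r - truth.r)
    r_bound = (
        approximation_bound(dataset, q=q)
        if variant == "approx"
        else np.zeros_like(r_error)
    )
    return RecoveryReport(
        truth=truth,
        dataset=dataset,
        recovered=recovered,
        s_error=s_error,
        r_error=r_error,
        r_bound=r_bound,
    )


def simulate_with_dilutions(
    model: PopulationModel,
    x0,
    t_grid,
    dilutions: list[tuple[float, float]] = (),
    **solver_opts,
):
    """Piecewise integration with multiplicative state rescales.

    ``dilutions`` is a list of (time, factor) events; at each event the
    whole state is multiplied by ``factor``.  Off by default everywhere —
    provided for exploring voiding-style scenarios.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    events = sorted((t, f) for t, f in dilutions if t_grid[0] < t < t_grid[-1])
    times = [t_grid[0], *(t for t, _ in events), t_grid[-1]]
    x = np.asarray(x0, dtype=float).copy()
    out_t, out_y = [], []
    for seg, (t0, t1) in enumerate(zip(times[:-1], times[1:])):
        inner = t_grid[(t_grid >= t0) & (t_grid <= t1)]
        seg_grid = np.unique(np.concatenate([[t0], inner, [t1]]))
        traj = simulate(model, x, seg_grid, **solver_opts)
        keep = np.isin(traj.times, t_grid)
        if out_t:  # avoid duplicating the seam point
            keep &= traj.times > out_t[-1]
        out_t.extend(traj.times[keep].tolist())
        out_y.extend(traj.abundances[keep].tolist())
        x = traj.final.copy()
        if seg < len(events):
            x *= events[seg][1]
    from .dynamics import Trajectory

    return Trajectory(np.array(out_t), np.array(out_y))
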
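"""Ready-made model constructors and demonstration terms.

Families: generalized Lotka-Volterra (consistent by construction), the
logarithmic predator-prey model (the stock inconsistent example, with its
printed two/three-population fixture), a pollination-grazing toy community,
the niche / saturating-mutualism demonstration terms, and a seeded sampler
for the general product-of-transformed-linear-combinations ensemble.

Sign convention for the Lotka-Volterra family: per-capita growth is
``g_j * (c_j + sum_i a_ji x_i)`` with ``a_jj = -1`` by default, so a
monoculture reduces to logistic growth with capacity c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import registry
from .algebra import (
    Apply,
    BasicImpact,
    Const,
    ImpactExpression,
    ParameterTable,
    Scale,
    Sum,
    Product,
)
from .dynamics import PopulationModel
from .errors import DomainEvaluationError, ShapeError

__all__ = [
    "GLVParams",
    "LogModelParams",
    "PollinationGrazingParams",
    "ExampleTermParams",
    "GeneralEnsembleSpec",
    "make_glv",
    "make_log_model",
    "fig1_fixture",
    "make_pollination_grazing",
    "make_uim_terms",
    "unique_interaction_expansion",
    "sample_general_model",
]


# ---------------------------------------------------------------------------
# generalized Lotka-Volterra
# ---------------------------------------------------------------------------


@dataclass
class GLVParams:
    g: np.ndarray  # growth rates, 1/time
    c: np.ndarray  # capacities
    A: np.ndarray  # interaction matrix a_ji, diagonal -1 by default

    def __post_init__(self):
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = self.g.size
        if self.c.size != n or self.A.shape != (n, n):
            raise ShapeError("GLV parameter shapes disagree")

    @classmethod
    def default_diagonal(cls, g, c, offdiag):
        """Build A from an off-diagonal matrix, forcing the -1 diagonal."""
        A = np.atleast_2d(np.asarray(offdiag, dtype=float)).copy()
        np.fill_diagonal(A, -1.0)
        return cls(g, c, A)

    @property
    def n(self):
        return self.g.size


def make_glv(p: GLVParams) -> PopulationModel:
    """phi_j = g_j * (c_j + sum_i a_ji x_i); consistent by construction."""
    phis = []
    for j in range(p.n):
        table = ParameterTable(p.A[j][:, None], ["a"])
        expr = Scale(p.g[j], Sum(Const(p.c[j]), BasicImpact("a")))
        phis.append((expr, table))
    raw = {"g": (p.g, (0,)), "c": (p.c, (0,)), "A": (p.A, (0, 1))}
    return PopulationModel(
        n=p.n,
        phis=phis,
        family="glv",
        raw=raw,
        rebuild=lambda raw2: make_glv(
            GLVParams(raw2["g"][0], raw2["c"][0], raw2["A"][0])
        ),
    )


# ---------------------------------------------------------------------------
# logarithmic predator-prey model (clone-inconsistent)
# ---------------------------------------------------------------------------


@dataclass
class LogModelParams:
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        if self.b.shape != (self.a.size, self.a.size):
            raise ShapeError("log-model parameter shapes disagree")

    @property
    def n(self):
        return self.a.size


def make_log_model(p: LogModelParams) -> PopulationModel:
    """phi_j = a_j + sum_i b_ji log(x_i).

    The logarithm of an abundance is not additive over clones, so this model
    is the canonical inconsistent example.  phis are raw callables (the term
    cannot be written as an expression over the generating blocks); strictly
    positive states are required.
    """

    def make_phi(j):
        brow = p.b[j]
        aj = p.a[j]

        def phi(x):
            if np.any(x <= 0.0):
                raise DomainEvaluationError(
                    "log model needs strictly positive abundances", population=j
                )
            return aj + float(brow @ np.log(x))

        return phi

    raw = {"a": (p.a, (0,)), "b": (p.b, (0, 1))}
    return PopulationModel(
        n=p.n,
        phis=[make_phi(j) for j in range(p.n)],
        family="log",
        raw=raw,
        rebuild=lambda raw2: make_log_model(LogModelParams(raw2["a"][0], raw2["b"][0])),
    )


def fig1_fixture():
    """The printed predator-prey fixture: unsplit and split parameter sets
    plus the matching initial conditions (2, 6) and (2, 3, 3)."""
    unsplit = LogModelParams(
        a=np.array([0.3, -0.3]),
        b=np.array([[0.5, -1.0], [0.8, -0.5]]),
    )
    split = LogModelParams(
        a=np.array([0.3, -0.3, -0.3]),
        b=np.array(
            [[0.5, -1.0, -1.0], [0.8, -0.5, -0.5], [0.8, -0.5, -0.5]]
        ),
    )
    return unsplit, split, (np.array([2.0, 6.0]), np.array([2.0, 3.0, 3.0]))


def log_interaction_sum(x, params: ParameterTable) -> float:
    """The bare interaction term sum_i a_i log(x_i) as a checker probe."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise DomainEvaluationError("log undefined at non-positive abundance")
    return float(params.a[:, 0] @ np.log(x))


# ---------------------------------------------------------------------------
# pollination-grazing toy community
# ---------------------------------------------------------------------------


@dataclass
class PollinationGrazingParams:
    g_max: float
    a: np.ndarray  # grazing rates, >= 0
    b: np.ndarray  # pollination contributions, >= 0
    plant_index: int = 0

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.size != self.b.size:
            raise ShapeError("grazing and pollination vectors disagree in length")
        if np.any(self.a < 0) or np.any(self.b < 0):
            raise ValueError("grazing and pollination rates must be >= 0")
        if not 0 <= self.plant_index < self.a.size:
            raise IndexError("plant index out of range")

    @property
    def n(self):
        return self.a.size


def pollination_grazing_expression(g_max: float) -> ImpactExpression:
    """g_max / (1 + (sum b_i x_i)^-1) - sum a_i x_i, as an expression.

    The saturating factor is the type-II response of the pollination sum,
    which handles sum b_i x_i = 0 as the limit value 0.
    """
    return Sum(
        Scale(g_max, Apply("holling2", [BasicImpact("poll")], {"h": 1.0})),
        Scale(-1.0, BasicImpact("graze")),
    )


def make_pollination_grazing(p: PollinationGrazingParams) -> PopulationModel:
    """A plant population driven by insect pollination and grazing.

    The plant's own grazing/pollination entries must be zero (plants neither
    graze nor pollinate themselves).  Applied stringently, the *same*
    per-capita rate governs every population — what makes a plant a plant is
    only its zero rates — which keeps the model fully symmetric and
    expression-built, so clone-splitting any population is harmless.
    """
    if p.a[p.plant_index] != 0.0 or p.b[p.plant_index] != 0.0:
        raise ValueError("plant population must have zero grazing/pollination rates")
    table = ParameterTable(
        np.column_stack([p.a, p.b]), ["graze", "poll"]
    )
    expr = pollination_grazing_expression(p.g_max)
    phis = [(expr, table) for _ in range(p.n)]
    raw = {"a": (p.a, (0,)), "b": (p.b, (0,))}

    def rebuild(raw2):
        return make_pollination_grazing(
            PollinationGrazingParams(
                p.g_max, raw2["a"][0], raw2["b"][0], p.plant_index
            )
        )

    return PopulationModel(
        n=p.n, phis=phis, family="pollination_grazing", raw=raw, rebuild=rebuild
    )


# ---------------------------------------------------------------------------
# niche and saturating-interaction demonstration terms
# ---------------------------------------------------------------------------


@dataclass
class ExampleTermParams:
    u: float  # total niche size
    d: np.ndarray | None = None  # niche-occupancy matrix; default exclusive
    h: float = 1.0  # half-saturation constant
    a_uim: np.ndarray | None = None  # interaction strengths (rows = focal)
    n: int = 2

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("half-saturation constant h must be positive")
        if self.d is None:
            self.d = np.eye(self.n)
        self.d = np.atleast_2d(np.asarray(self.d, dtype=float))
        self.n = self.d.shape[0]
        if self.a_uim is None:
            self.a_uim = np.ones((self.n, self.n))
        self.a_uim = np.atleast_2d(np.asarray(self.a_uim, dtype=float))


def make_uim_terms(p: ExampleTermParams):
    """Return (saturating mutualism term, expanded niche term) for a focal row.

    The mutualism term ``sum_i a_i x_i / (h + x_i)`` is a raw black box and
    is expected to fail clone consistency (each abundance saturates
    separately).  The niche term ``u - sum_i d_i x_i`` is returned as an
    expression over the occupancy column and is consistent by construction.
    """

    def mutualism(x, params: ParameterTable) -> float:
        x = np.asarray(x, dtype=float)
        a = params.a[:, 0]
        return float(np.sum(a * x / (p.h + x)))

    niche = Sum(Const(p.u), Scale(-1.0, BasicImpact("occupancy")))
    return mutualism, niche


def unique_interaction_expansion(h: float = 1.0) -> ImpactExpression:
    """One saturating summand expanded to an impact function.

    Under the unique-interaction assumption only one parameter a_i is
    nonzero, and ``a_i x_i / (h + x_i)`` can be written as
    ``(sum a_i x_i) / (h + sum 1[a_i != 0] x_i)`` — two linear-combination
    blocks (the second with the indicator transform, a valid zeta since
    indicator(0) = 0) under a saturating combiner.
    """
    return Apply(
        "saturating_ratio",
        [BasicImpact("a"), BasicImpact("a", zeta="indicator")],
        {"h": h},
    )


# ---------------------------------------------------------------------------
# general ensemble sampler
# ---------------------------------------------------------------------------


@dataclass
class GeneralEnsembleSpec:
    """Spec for sampling models x'_j = x_j g_j prod_k eta_k(sum_i a_jik x_i)."""

    n: int
    m: int = 2
    sparsity: float = 0.3  # probability that a coefficient is nonzero
    coefficient_low: float = -0.5
    coefficient_high: float = 0.5
    growth_low: float = 0.5
    growth_high: float = 1.5
    etas: tuple = ()  # registry names, one per factor; default all "one_plus"
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if not self.etas:
            self.etas = ("one_plus",) * self.m
        if len(self.etas) != self.m:
            raise ShapeError("need one eta name per factor")


def _check_eta(name: str) -> None:
    fn = registry.get(name)  # raises UnknownTransformError for bad names
    if abs(fn(0.0) - 1.0) > registry.ZETA_ZERO_TOL:
        raise ValueError(
            f"eta {name!r} must satisfy eta(0) = 1 so that absent "
            "interactions are neutral under the product"
        )


def _build_ensemble(g, coef, etas):
    n = g.size
    m = coef.shape[2]
    names = [f"k{k + 1}" for k in range(m)]
    phis = []
    for j in range(n):
        table = ParameterTable(coef[j], list(names))
        factors = [Apply(etas[k], [BasicImpact(names[k])]) for k in range(m)]
        phis.append((Scale(float(g[j]), Product(*factors)), table))
    raw = {"g": (g, (0,)), "coef": (coef, (0, 1))}
    return PopulationModel(
        n=n,
        phis=phis,
        family="ensemble",
        raw=raw,
        rebuild=lambda raw2: _build_ensemble(raw2["g"][0], raw2["coef"][0], etas),
    )


def sample_general_model(spec: GeneralEnsembleSpec) -> PopulationModel:
    """Seeded, reproducible sample of the product-form ensemble.

    Interaction coefficients a_jik are drawn from a sparse distribution
    (zero with probability 1 - sparsity); every eta must map 0 to 1.
    """
    for name in spec.etas:
        _check_eta(name)
    rng = np.random.default_rng(spec.seed)
    g = rng.uniform(spec.growth_low, spec.growth_high, size=spec.n)
    coef = rng.uniform(
        spec.coefficient_low, spec.coefficient_high, size=(spec.n, spec.n, spec.m)
    )
    mask = rng.uniform(size=coef.shape) < spec.sparsity
    coef = np.where(mask, coef, 0.0)
    return _build_ensemble(g, coef, spec.etas)
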
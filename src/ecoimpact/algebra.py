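"""Community states, parameter tables and the impact-function algebra.

The central idea: community-level effects that are invariant under merging
or splitting populations of identical individuals ("clone consistency") are
exactly those built from *basic* building blocks — linear combinations

    sum_i zeta(a_i) * x_i          (per-population parameters)
    sum_i sum_j zeta(a_ij) x_i x_j (pairwise parameters)

with ``zeta(0) == 0`` — combined through sums, products, scalar multiples
and arbitrary scalar wrappers.  This module provides those building blocks
as an expression tree (:class:`ImpactExpression` nodes), their evaluation,
JSON-compatible (de)serialization, and the canonical-form reduction that
underlies clone equivalence: drop zero-abundance and zero-parameter
populations and lump populations with exactly equal parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import registry
from .errors import (
    DomainEvaluationError,
    InvalidTransformError,
    ShapeError,
)

__all__ = [
    "CommunityState",
    "ParameterTable",
    "BasicImpact",
    "PairwiseImpact",
    "Const",
    "Sum",
    "Product",
    "Scale",
    "Apply",
    "Opaque",
    "ImpactExpression",
    "CanonicalForm",
    "as_state",
    "eval_basic",
    "eval_pairwise",
    "eval_expression",
    "canonicalize",
    "power_sums",
    "expression_to_dict",
    "expression_from_dict",
    "save_expression",
    "load_expression",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityState:
    """Vector of n >= 1 non-negative population abundances."""

    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size < 1:
            raise ShapeError("abundance vector must be 1-D with length >= 1")
        if np.any(x < 0):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return self.x.size


def as_state(x) -> np.ndarray:
    """Coerce a CommunityState or array-like into a validated 1-D array."""
    if isinstance(x, CommunityState):
        return x.x
    return CommunityState(np.asarray(x, dtype=float)).x


@dataclass
class ParameterTable:
    """n x m matrix of per-population parameters plus optional pairwise matrices.

    Rows index populations (order-preserving, 1-based in files), columns are
    named parameter kinds.  ``pairwise`` maps names to n x n matrices of
    second-order parameters a_ij.
    """

    a: np.ndarray
    column_names: list[str] | None = None
    pairwise: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if a.ndim != 2 or a.shape[1] < 1:
            raise ShapeError("parameter table must be n x m with m >= 1")
        self.a = a
        if self.column_names is None:
            self.column_names = [f"a{k + 1}" for k in range(a.shape[1])]
        if len(self.column_names) != a.shape[1]:
            raise ShapeError("column_names length must equal column count")
        n = a.shape[0]
        for name, mat in self.pairwise.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (n, n):
                raise ShapeError(f"pairwise matrix {name!r} must be {n}x{n}")
            self.pairwise[name] = mat

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def m(self) -> int:
        return self.a.shape[1]

    def column(self, key: int | str) -> np.ndarray:
        """Column by name or 1-based index (matching on-disk convention)."""
        if isinstance(key, str):
            try:
                k = self.column_names.index(key)
            except ValueError:
                raise KeyError(f"no parameter column named {key!r}") from None
        else:
            if not 1 <= key <= self.m:
                raise IndexError(f"column index {key} outside 1..{self.m}")
            k = key - 1
        return self.a[:, k]

    # -- delimited I/O ------------------------------------------------------

    def to_csv(self, path, sep=",") -> None:
        df = pd.DataFrame(self.a, columns=self.column_names)
        df.insert(0, "population", np.arange(1, self.n + 1))
        df.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path, sep=",") -> "ParameterTable":
        df = pd.read_csv(path, sep=sep)
        if "population" in df.columns:
            df = df.sort_values("population").drop(columns="population")
        return cls(df.to_numpy(dtype=float), list(df.columns))

    def save_pairwise(self, name: str, path, sep=",") -> None:
        np.savetxt(path, self.pairwise[name], delimiter=sep)

    def load_pairwise(self, name: str, path, sep=",") -> None:
        mat = np.atleast_2d(np.loadtxt(path, delimiter=sep))
        self.pairwise[name] = mat
        self.__post_init__()


# ---------------------------------------------------------------------------
# expression tree
# ---------------------------------------------------------------------------


class ImpactExpression:
    """Base class for expression-tree nodes.

    Subclasses implement ``evaluate(x, params)`` and ``to_dict()``.
    """

    kind: str = "?"

    def evaluate(self, x, params: ParameterTable) -> float:
        raise NotImplementedError

    def children(self) -> Sequence["ImpactExpression"]:
        return ()

    def to_dict(self) -> dict:
        raise NotImplementedError

    # operator sugar keeps hand-built trees readable in tests and the zoo
    def __add__(self, other):
        return Sum(self, _coerce(other))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Scale(float(other), self)
        return Product(self, _coerce(other))

    __radd__ = __add__
    __rmul__ = __mul__


def _coerce(value) -> ImpactExpression:
    if isinstance(value, ImpactExpression):
        return value
    return Const(float(value))


def _check_zeta(zeta: Callable, name: str) -> None:
    try:
        at_zero = zeta(0.0)
    except Exception as exc:  # pragma: no cover - defensive
        raise InvalidTransformError(f"zeta {name!r} not evaluable at 0: {exc}")
    if abs(at_zero) > registry.ZETA_ZERO_TOL:
        raise InvalidTransformError(
            f"zeta {name!r} violates zeta(0)=0 (got {at_zero!r})"
        )


@dataclass
class BasicImpact(ImpactExpression):
    """Leaf: sum_i zeta(a_ik) x_i over parameter column k (name or 1-based)."""

    column: int | str
    zeta: str = "identity"
    zeta_args: dict | None = None
    kind = "basic"

    def evaluate(self, x, params):
        x = np.asarray(x, dtype=float)
        col = params.column(self.column)
        if col.size != x.size:
            raise ShapeError("state length does not match parameter rows")
        fn = registry.resolve(self.zeta, self.zeta_args)
        _check_zeta(fn, self.zeta)
        return float(sum(fn(a) * xi for a, xi in zip(col, x)))

    def to_dict(self):
        d = {"kind": "basic", "column": self.column, "zeta": self.zeta}
        if self.zeta_args:
            d["zeta_args"] = self.zeta_args
        return d


@dataclass
class PairwiseImpact(ImpactExpression):
    """Leaf: sum_i sum_j zeta(a_ij) x_i x_j over a named pairwise matrix."""

    name: str
    zeta: str = "identity"
    zeta_args: dict | None = None
    kind = "pairwise"

    def evaluate(self, x, params):
        x = np.asarray(x, dtype=float)
        try:
            mat = params.pairwise[self.name]
        except KeyError:
            raise DomainEvaluationError(
                f"missing pairwise matrix {self.name!r}", node=self
            ) from None
        if mat.shape != (x.size, x.size):
            raise ShapeError("pairwise matrix does not match state length")
        fn = registry.resolve(self.zeta, self.zeta_args)
        _check_zeta(fn, self.zeta)
        zmat = np.vectorize(fn, otypes=[float])(mat)
        return float(x @ zmat @ x)

    def to_dict(self):
        d = {"kind": "pairwise", "name": self.name, "zeta": self.zeta}
        if self.zeta_args:
            d["zeta_args"] = self.zeta_args
        return d


@dataclass
class Const(ImpactExpression):
    value: float
    kind = "const"

    def evaluate(self, x, params):
        return float(self.value)

    def to_dict(self):
        return {"kind": "const", "value": float(self.value)}


class _Nary(ImpactExpression):
    def __init__(self, *terms):
        self.terms = [_coerce(t) for t in terms]

    def children(self):
        return self.terms

    def to_dict(self):
        return {"kind": self.kind, "terms": [t.to_dict() for t in self.terms]}


class Sum(_Nary):
    kind = "sum"

    def evaluate(self, x, params):
        return float(sum(t.evaluate(x, params) for t in self.terms))


class Product(_Nary):
    kind = "product"

    def evaluate(self, x, params):
        out = 1.0
        for t in self.terms:
            out *= t.evaluate(x, params)
        return float(out)


@dataclass
class Scale(ImpactExpression):
    factor: float
    term: ImpactExpression
    kind = "scale"

    def evaluate(self, x, params):
        return float(self.factor) * self.term.evaluate(x, params)

    def children(self):
        return (self.term,)

    def to_dict(self):
        return {
            "kind": "scale",
            "factor": float(self.factor),
            "term": self.term.to_dict(),
        }


class Apply(ImpactExpression):
    """Internal node: named scalar function chi applied to child values."""

    kind = "apply"

    def __init__(self, func: str, terms, args: dict | None = None):
        self.func = func
        self.terms = [_coerce(t) for t in (terms if isinstance(terms, (list, tuple)) else [terms])]
        self.args = dict(args) if args else {}

    def evaluate(self, x, params):
        values = [t.evaluate(x, params) for t in self.terms]
        fn = registry.resolve(self.func, self.args)
        try:
            out = fn(*values)
        except (ValueError, ZeroDivisionError, OverflowError) as exc:
            raise DomainEvaluationError(
                f"chi {self.func!r} failed at {values}: {exc}", node=self
            ) from exc
        return float(out)

    def children(self):
        return self.terms

    def to_dict(self):
        d = {
            "kind": "apply",
            "func": self.func,
            "terms": [t.to_dict() for t in self.terms],
        }
        if self.args:
            d["args"] = self.args
        return d


class Opaque(ImpactExpression):
    """Black-box leaf wrapping a raw callable ``f(x, params) -> float``.

    Trees containing this node cannot be certified consistent by structure
    and do not serialize.
    """

    kind = "opaque"

    def __init__(self, fn: Callable, label: str = "blackbox"):
        self.fn = fn
        self.label = label

    def evaluate(self, x, params):
        return float(self.fn(np.asarray(x, dtype=float), params))

    def to_dict(self):
        raise TypeError(f"opaque node {self.label!r} is not serializable")


def expression_from_dict(d: dict) -> ImpactExpression:
    kind = d.get("kind")
    if kind == "const":
        return Const(d["value"])
    if kind == "basic":
        return BasicImpact(d["column"], d.get("zeta", "identity"), d.get("zeta_args"))
    if kind == "pairwise":
        return PairwiseImpact(d["name"], d.get("zeta", "identity"), d.get("zeta_args"))
    if kind == "sum":
        return Sum(*[expression_from_dict(t) for t in d["terms"]])
    if kind == "product":
        return Product(*[expression_from_dict(t) for t in d["terms"]])
    if kind == "scale":
        return Scale(d["factor"], expression_from_dict(d["term"]))
    if kind == "apply":
        return Apply(
            d["func"], [expression_from_dict(t) for t in d["terms"]], d.get("args")
        )
    raise ValueError(f"unknown expression node kind {kind!r}")


def expression_to_dict(e: ImpactExpression) -> dict:
    return e.to_dict()


def save_expression(e: ImpactExpression, path) -> None:
    with open(path, "w") as fh:
        json.dump(e.to_dict(), fh, indent=2)


def load_expression(path) -> ImpactExpression:
    with open(path) as fh:
        return expression_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# evaluation entry points (operation-style API)
# ---------------------------------------------------------------------------


def eval_basic(b: BasicImpact, state, params: ParameterTable) -> float:
    return b.evaluate(as_state(state), params)


def eval_pairwise(p: PairwiseImpact, state, params: ParameterTable) -> float:
    return p.evaluate(as_state(state), params)


def eval_expression(e: ImpactExpression, state, params: ParameterTable) -> float:
    return e.evaluate(as_state(state), params)


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------


@dataclass
class CanonicalForm:
    """Reduced clone-equivalent representation of (x, a).

    ``values`` holds the distinct non-zero parameter values (or tuples for
    m > 1) in ascending (lexicographic) order; ``masses`` the corresponding
    summed abundances.  Populations with zero abundance or all-zero
    parameters are dropped.
    """

    values: np.ndarray  # (s,) for m=1, else (s, m)
    masses: np.ndarray  # (s,)
    n: int
    s: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.size != self.s or self.s > self.n:
            raise ShapeError("inconsistent canonical form sizes")
        if np.any(self.masses <= 0):
            raise ValueError("canonical masses must be positive")

    def to_state_params(self, n: int | None = None):
        """Zero-pad back to an n-vector state and n x m table (trailing zeros)."""
        n = self.n if n is None else n
        if n < self.s:
            raise ShapeError("target length smaller than reduced size")
        vals = self.values if self.values.ndim == 2 else self.values[:, None]
        m = vals.shape[1]
        x = np.zeros(n)
        a = np.zeros((n, m))
        x[: self.s] = self.masses
        a[: self.s] = vals
        return x, ParameterTable(a)


def canonicalize(state, params: ParameterTable | np.ndarray) -> CanonicalForm:
    """Reduce (x, a) to canonical form.

    Lumping uses *exact* equality of parameter values (full tuples for
    m > 1); populations with zero abundance or all-zero parameters are
    dropped.  Values come out sorted ascending (lexicographically over
    tuples for m > 1).
    """
    x = as_state(state)
    if not isinstance(params, ParameterTable):
        params = ParameterTable(np.asarray(params, dtype=float))
    if params.n != x.size:
        raise ShapeError("state length does not match parameter rows")
    a = params.a
    keep = (x > 0) & np.any(a != 0.0, axis=1)
    xk, ak = x[keep], a[keep]
    groups: dict[tuple, float] = {}
    for row, xi in zip(ak, xk):
        key = tuple(row)
        groups[key] = groups.get(key, 0.0) + xi
    keys = sorted(groups)
    masses = np.array([groups[k] for k in keys])
    values = np.array(keys) if keys else np.empty((0, params.m))
    if params.m == 1:
        values = values.reshape(-1)
    return CanonicalForm(values=values, masses=masses, n=x.size, s=len(keys))


def power_sums(state, params, p_max: int) -> np.ndarray:
    """Return (sum_i a_i^p x_i) for p = 1..p_max; scalar parameters only."""
    x = as_state(state)
    if isinstance(params, ParameterTable):
        if params.m != 1:
            raise ShapeError("power_sums requires scalar parameters (m=1)")
        a = params.a[:, 0]
    else:
        a = np.asarray(params, dtype=float).reshape(-1)
    if a.size != x.size:
        raise ShapeError("state length does not match parameter rows")
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    return np.array([np.sum(a**p * x) for p in range(1, p_max + 1)])
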
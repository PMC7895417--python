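"""Named scalar transforms used by expression trees and model constructors.

Three informal roles share one registry:

* parameter transforms ``zeta`` applied inside linear-combination leaves —
  these must satisfy ``zeta(0) == 0``;
* combining functions ``chi`` applied to the values of child expressions;
* ensemble factor transforms ``eta`` — these must satisfy ``eta(0) == 1`` so
  that absent interactions are neutral under a product.

Entries are plain callables taking one or more float arguments plus keyword
parameters (e.g. ``power`` takes ``p``).  User code can add its own entries
with :func:`register`; registry names are what expression config files refer
to, so registered callables round-trip through serialization by name.
"""

from __future__ import annotations

import math
from typing import Callable

from .errors import UnknownTransformError

__all__ = ["register", "get", "resolve", "names", "ZETA_ZERO_TOL"]

#: tolerance used when asserting zeta(0) == 0 or eta(0) == 1 by evaluation
ZETA_ZERO_TOL = 1e-12

_REGISTRY: dict[str, Callable] = {}


def register(name: str, fn: Callable | None = None, *, overwrite: bool = False):
    """Register ``fn`` under ``name``; usable as a decorator."""

    def _do(f):
        if name in _REGISTRY and not overwrite:
            raise ValueError(f"transform {name!r} already registered")
        _REGISTRY[name] = f
        return f

    return _do(fn) if fn is not None else _do


def get(name: str) -> Callable:
    """Return the raw registered callable for ``name``."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownTransformError(
            f"unknown transform {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def resolve(name: str, args: dict | None = None) -> Callable:
    """Return a unary/variadic callable with keyword ``args`` bound."""
    fn = get(name)
    if not args:
        return fn
    bound = dict(args)
    return lambda *values: fn(*values, **bound)


def names() -> list[str]:
    return sorted(_REGISTRY)


# --- built-ins --------------------------------------------------------------

register("identity", lambda z: z)
register("power", lambda z, p: z**p)
register("affine", lambda z, slope=1.0, intercept=0.0: slope * z + intercept)
register("clamp", lambda z: max(0.0, z))
register("exp", math.exp)
register("one_plus", lambda z: 1.0 + z)


@register("log")
def _log(z):
    if z <= 0.0:
        raise ValueError(f"log undefined for argument {z}")
    return math.log(z)


@register("indicator")
def _indicator(z):
    """1 where z != 0, else 0.  A valid zeta: indicator(0) == 0."""
    return 0.0 if z == 0.0 else 1.0


@register("holling2")
def _holling2(z, h=1.0):
    """Saturating type-II response z/(h+z); 0 at z <= 0 (limit convention)."""
    if z <= 0.0:
        return 0.0
    return z / (h + z)


@register("saturating_ratio")
def _saturating_ratio(u, w, h=1.0):
    """Binary combiner u/(h+w), the per-mechanism saturating interaction."""
    return u / (h + w)


@register("capacity")
def _capacity(z, q=10.0):
    """Clamped capacity factor max(0, 1 - max(0, z)^q)."""
    return max(0.0, 1.0 - max(0.0, z) ** q)


@register("saturation")
def _saturation(z, q=10.0):
    """Capacity factor family 1 - max(0, z)^q (unclamped outer value)."""
    return 1.0 - max(0.0, z) ** q
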
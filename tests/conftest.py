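import numpy as np
import pytest

from ecoimpact import uti, zoo


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def glv_2pop():
    return zoo.make_glv(
        zoo.GLVParams(
            g=[1.0, 1.0], c=[1.0, 1.0], A=[[-1.0, 0.2], [0.3, -1.0]]
        )
    )


@pytest.fixture
def fig1():
    """Unsplit/split predator-prey models plus their initial conditions."""
    unsplit, split, (x0_u, x0_s) = zoo.fig1_fixture()
    return {
        "unsplit": zoo.make_log_model(unsplit),
        "split": zoo.make_log_model(split),
        "x0_unsplit": x0_u,
        "x0_split": x0_s,
        "params_unsplit": unsplit,
        "params_split": split,
    }


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One shared synthetic conditioned-medium dataset (n=3, seeded)."""
    truth = uti.make_synthetic_truth(seed=7, n=3, sparsity=0.6)
    return uti.simulate_experiment(truth), truth


def positive_sampler(rng, n):
    """Abundance sampler bounded away from zero (log-model probes)."""
    return rng.uniform(0.2, 2.0, size=n)


def random_certified_expression(rng, depth=3, column=1, allow_pairwise=False):
    """Seeded random expression over the generating blocks.

    Leaves are constants and linear-combination blocks (optionally pairwise);
    internal nodes are sums, products, scalar multiples and bounded scalar
    wrappers, so every generated tree certifies consistent-by-construction.
    """
    from ecoimpact.algebra import (
        Apply,
        BasicImpact,
        Const,
        PairwiseImpact,
        Product,
        Scale,
        Sum,
    )

    def leaf():
        kind = rng.choice(["const", "basic", "basic", "pairwise" if allow_pairwise else "basic"])
        if kind == "const":
            return Const(float(rng.uniform(-2, 2)))
        if kind == "pairwise":
            return PairwiseImpact("P1")
        zeta = rng.choice(["identity", "power", "clamp", "indicator"])
        args = {"p": int(rng.integers(1, 4))} if zeta == "power" else None
        return BasicImpact(column, zeta=zeta, zeta_args=args)

    def node(d):
        if d == 0:
            return leaf()
        kind = rng.choice(["sum", "product", "scale", "apply", "leaf"])
        if kind == "leaf":
            return leaf()
        if kind == "sum":
            return Sum(node(d - 1), node(d - 1))
        if kind == "product":
            return Product(node(d - 1), node(d - 1))
        if kind == "scale":
            return Scale(float(rng.uniform(-2, 2)), node(d - 1))
        func = rng.choice(["one_plus", "holling2", "clamp"])
        return Apply(func, [node(d - 1)])

    return node(depth)
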
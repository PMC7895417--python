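# ecoimpact

Build ecosystem models that are *clone-consistent by construction*, detect
clone inconsistency in arbitrary population models, and run a full
conditioned-medium microbial case study.

**Clone consistency**: if two populations contain identical individuals
(identical parameters), a model's outcome must depend only on their summed
abundance — repainting half the predators a different color must not change
the dynamics. Community-level effects with this invariance are exactly
those built from *basic impact functions* — linear combinations
`Σ_i ζ(a_i) x_i` with `ζ(0) = 0` (and their pairwise analogues
`Σ_ij ζ(a_ij) x_i x_j`) — combined through sums, products, scalar multiples
and arbitrary scalar wrappers. Whole population models must additionally
factor as `ẋ_j = x_j · φ_j(x, a)` with `φ_j` such a function.

## What's here

| module | contents |
|---|---|
| `ecoimpact.algebra` | community states, parameter tables (CSV I/O), the expression-tree algebra over basic/pairwise blocks (JSON I/O), canonical-form reduction, power sums |
| `ecoimpact.consistency` | numeric probing of the four impact-function criteria (I1 commutativity, I2 absent populations, I3 zero parameters, I4 clone consistency), structural certification, population splitting, whole-model clone-split tests with witnesses |
| `ecoimpact.dynamics` | `PopulationModel` (`R_j = x_j·φ_j`), tight-tolerance ODE/map simulation, linear interior fixed points, fixed-point refinement, oscillation/convergence classification |
| `ecoimpact.zoo` | generalized Lotka–Volterra, the logarithmic predator–prey model (the stock inconsistent example, with its printed two/three-population fixture), a pollination–grazing toy community, niche/saturating-interaction demonstration terms, a seeded sampler for product-form ensembles |
| `ecoimpact.uti` | conditioned-medium datasets, the existing (inconsistent) and new (consistent-by-construction) community models, parameter derivation `s = (1−c)/v`, `r = (g_jk − g_j)/v` (or the full variant with its singularity guard), constraint validation, a synthetic experiment generator and end-to-end parameter recovery |
| `ecoimpact.cli` | the `ecoimpact` command |

## Quick tour

```python
import numpy as np
from ecoimpact import zoo, consistency, dynamics

# the classic demonstration: splitting the predator population changes the outcome
unsplit, split, (x0u, x0s) = zoo.fig1_fixture()
model = zoo.make_log_model(unsplit)
report = consistency.check_model_consistency(
    model,
    consistency.ProbeConfig(n_probes=5, seed=0),
    state_sampler=lambda rng, n: rng.uniform(0.2, 2.0, n),
)
print(report.summary())          # model-split fail, with a concrete witness

# a Lotka–Volterra model passes, and is certified without any probing
glv = zoo.make_glv(zoo.GLVParams([1, 1], [1, 1], [[-1, 0.2], [0.3, -1]]))
print(consistency.certify_model(glv))   # consistent-by-construction
```

Black-box terms can be probed directly against the four criteria:

```python
from ecoimpact.consistency import check_impact_criteria, ProbeConfig
bad = lambda x, params: float(params.a[:, 0] @ x**2)   # saturates clones separately
rep = check_impact_criteria(bad, n=3, m=1, cfg=ProbeConfig(seed=1))
print(rep.results["I4"].verdict)   # fail
```

## CLI

```sh
ecoimpact check --family glv                         # exit 0: consistent
ecoimpact check --family log                         # exit 1: witnessed inconsistency
ecoimpact simulate --family log --x0 2,6 --t-max 100 --out runs/fig1
ecoimpact fixed-point --family glv --guess 0.5,0.5

# case study, end to end
ecoimpact synth-experiment --seed 1 --n 4 --out data/
ecoimpact build-uti --data data/ --variant approx --out params/
ecoimpact validate --data data/ --model new
ecoimpact recover --seed 1 --n 4
```

`check` exits 0 when the model is consistent/certified, 1 when an
inconsistency is witnessed, 2 on errors. Model families can also be given
as a JSON/YAML config via `--config` (see `ecoimpact.cli.build_model`).

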
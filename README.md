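# cibscen — cross-impact balance scenario analysis

`cibscen` implements the cross-impact balance (CIB) method for
qualitative scenario discovery, aimed at systems-oriented public-health
and policy analysts.  Given a set of discrete factors (e.g. *physical
activity*: low/high) and expert judgments of how each factor state
promotes or restricts every other factor's states on an integer scale
from −2 to +2, the package finds the internally consistent combinations
of factor states — the plausible "futures" of the system — and analyses
how fixing individual factor states (external interventions such as
enacting transport subsidies) reshapes that set of futures.

The package ships with a default 11-factor binary (low/high) urban
food-and-transportation system: three health outcomes (chronic disease
prevalence, physical activity, highly processed food consumption), three
intermediaries (car use, free time, street safety) and five
structural/policy levers (food marketing regulations, SSB/processed-food
taxes, healthy food prices, public transportation subsidies, political
will for social change).

## The model

For a scenario *s* assigning one state to every factor, the **impact
balance** of state *t* of factor *k* is

```
B_k(t | s) = Σ_{j ≠ k}  C[j, s_j → k, t]
```

where `C` is the cross-impact matrix of judgment scores.  A scenario is
**consistent** when every factor's assigned state has maximal balance:

* weak mode: `B_k(s_k) ≥ B_k(t)` for all states `t` (ties allowed);
* strict mode: `B_k(s_k) > B_k(t)` for all `t ≠ s_k`.

Equivalently, the weakly consistent scenarios are exactly the fixed
points of the succession operator (each factor moves to a state of
maximal balance, keeping its current state on ties) — a property the
test suite verifies by brute force.  Enumeration is exhaustive over the
full state space (2^11 = 2048 scenarios for the default system) with a
hard guard at 2^24 candidates.

Scenarios are classified from a **promoting map** (which state of each
factor is health-promoting): *healthy* scenarios have all three outcome
factors in promoting states, *unhealthy* scenarios have none, *mixed*
the rest; a *salubrious system* scenario is a non-unhealthy scenario
with at least 8 of the 11 factors (>70 %) in promoting states.
**Interventions** fix one factor state at a time (the fixed factor is
exempted from the consistency condition) and summarise the resulting
consistent set by the percentage of factor slots in promoting states,
the category mix and the per-outcome promoting proportions.

## Worked example

Real elicitation matrices are rarely published, so the package includes
seeded generators that emulate a three-region elicitation round (39, 53
and 60 of the 110 possible directed relationships, with 87 %, 81 % and
77 % nonlinear shapes).  These fixtures reproduce the *statistical
structure* of such a study, not any particular study's matrices, so the
scenarios below are synthetic:

```python
import cibscen as cib

fixture = cib.make_multiregion_fixture(seed=1)
pmap = cib.default_promoting_map()

sets = {region: cib.enumerate_consistent(fx.matrix)
        for region, fx in fixture.items()}
for region, scenarios in sets.items():
    print(region, len(scenarios), "consistent scenarios")

pooled = cib.pool_scenario_sets(sets)
print("pooled", pooled.total, "unique", pooled.unique)
props = cib.category_proportions(pooled.scenarios, pmap)
print({k: round(v, 1) for k, v in props.items()})
print("promoting slots:", round(cib.pct_factors_promoting(pooled.scenarios, pmap), 1), "%")
```

prints

```
Brazil 7 consistent scenarios
Peru 3 consistent scenarios
Guatemala 0 consistent scenarios
pooled 10 unique 10
{'healthy': 0.0, 'mixed': 80.0, 'unhealthy': 20.0, 'salubrious': 0.0}
promoting slots: 45.5 %
```

i.e. at this seed the three synthetic regional matrices admit 10 weakly
consistent scenarios in total (none shared between regions), 80 % of
which have a mix of promoting and restricting health outcomes, and
45.5 % of all factor slots across those scenarios are health-promoting.
A region with zero consistent scenarios is a legitimate outcome (its
judgment network has no equilibrium) and is always surfaced explicitly.

The same pipeline is available from the shell:

```sh
cibscen run --seed 1 --out out/          # simulate → encode → solve → intervene → report
cibscen solve --factors out/factors.yaml --matrix out/matrix_peru.csv \
              --mode strict --out strict.csv
cibscen intervene --factors out/factors.yaml --matrix out/matrix_peru.csv \
                  --fix political_will=high --out sweep/
```

`out/scenario_table.txt` holds the scenario table (factors as rows,
scenarios as numbered columns grouped healthy / mixed / unhealthy, `L`/`H`
cells, `*` marking salubrious-system scenarios), and each `sweep_*/`
directory the intervention sweep as tidy CSV and JSON.

## Documentation

`docs/methods.md` describes the model, the default encoding table and
promoting map, the synthetic-data generators and the package's numerical
and design choices in detail.
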
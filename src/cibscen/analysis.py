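"""Scenario classification, pooling and intervention analysis.

Once consistent scenarios have been enumerated, this layer answers the
health-oriented questions: which scenarios are healthy, which system-wide
configurations are salubrious, and what happens when an external
intervention holds one factor in a chosen state.

Classification hinges on the *promoting map*: for every factor, which of
its states is health-promoting (e.g. low chronic disease prevalence, high
physical activity, low processed-food consumption).  Three designated
*outcome* factors drive the category:

healthy
    all outcome factors in their promoting state;
unhealthy
    all outcome factors in their restricting state;
mixed
    anything in between.

Independently, a scenario is a *salubrious system* when it is not
unhealthy and at least ``threshold`` of its factors (default 8 of 11,
i.e. >70%) sit in promoting states — a whole-system quality bar that
overlaps the healthy and mixed categories.

Intervention analysis fixes one factor state at a time, re-derives the
consistent scenarios (the fixed factor is exempt from the consistency
condition), and summarises each resulting set with three metric families:
the percentage of all factor slots in promoting states, the category mix,
and the per-outcome promoting proportions.  The reported frequencies
describe the composition of the consistent-scenario set; they are not
probabilities.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .core import (
    CrossImpactMatrix,
    FactorDef,
    Scenario,
    _canon,
    enumerate_consistent,
)
from .errors import EmptyScenarioSetError, ValidationError

CATEGORY_ORDER = ("healthy", "mixed", "unhealthy")

#: smallest promoting-factor count qualifying as salubrious for 11 factors (>70%)
DEFAULT_SALUBRIOUS_THRESHOLD = 8


def salubrious_threshold(n_factors: int, fraction: float = 0.70) -> int:
    """Smallest integer count strictly exceeding ``fraction`` of ``n_factors``.

    For the canonical 11-factor system with the >70% rule this is 8.
    """
    import math

    return math.floor(n_factors * fraction) + 1


@dataclass(frozen=True)
class PromotingMap:
    """Per-factor health-promoting state plus the designated outcome subset."""

    promoting: Mapping[str, str]
    outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "promoting",
            {k.strip(): v.strip() for k, v in self.promoting.items()},
        )
        object.__setattr__(self, "outcomes", tuple(o.strip() for o in self.outcomes))
        if not self.outcomes:
            raise ValidationError("the outcome subset must be non-empty")
        missing = [o for o in self.outcomes if o not in self.promoting]
        if missing:
            raise ValidationError(
                f"outcome factors missing from the promoting map: {missing!r}"
            )

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.promoting)

    def is_promoting(self, factor: str, state: str) -> bool:
        try:
            promoting_state = self.promoting[factor.strip()]
        except KeyError:
            raise ValidationError(
                f"factor {factor!r} not covered by the promoting map"
            ) from None
        return _canon(state) == _canon(promoting_state)

    def check_scenario(self, scenario: Mapping[str, str]) -> None:
        scen_keys = {k.strip() for k in scenario}
        map_keys = set(self.promoting)
        if scen_keys != map_keys:
            raise ValidationError(
                "scenario and promoting map cover different factors: "
                f"only in scenario {sorted(scen_keys - map_keys)!r}, "
                f"only in map {sorted(map_keys - scen_keys)!r}"
            )

    def inverted(self, factors: Sequence[FactorDef]) -> "PromotingMap":
        """Flip every promoting state to the factor's other state (binary
        factors only); used for sensitivity and symmetry checks."""
        flipped: dict[str, str] = {}
        by_name = {f.name: f for f in factors}
        for name, state in self.promoting.items():
            f = by_name[name]
            if f.n_states != 2:
                raise ValidationError(
                    f"inversion needs binary factors; {name!r} has {f.n_states} states"
                )
            i = f.state_index(state)
            flipped[name] = f.states[1 - i]
        return PromotingMap(promoting=flipped, outcomes=self.outcomes)


@dataclass(frozen=True)
class ScenarioClassification:
    scenario: Scenario
    category: str  # healthy | mixed | unhealthy
    salubrious: bool
    promoting_count: int


def classify_scenario(
    scenario: Mapping[str, str],
    promoting_map: PromotingMap,
    threshold: int = DEFAULT_SALUBRIOUS_THRESHOLD,
) -> ScenarioClassification:
    """Assign the health category and the salubrious flag to one scenario."""
    promoting_map.check_scenario(scenario)
    n = len(promoting_map.promoting)
    if not (0 < threshold <= n):
        raise ValidationError(
            f"salubrious threshold must be in 1..{n}, got {threshold}"
        )
    outcome_flags = [
        promoting_map.is_promoting(o, scenario[o]) for o in promoting_map.outcomes
    ]
    if all(outcome_flags):
        category = "healthy"
    elif not any(outcome_flags):
        category = "unhealthy"
    else:
        category = "mixed"
    promoting_count = sum(
        promoting_map.is_promoting(f, scenario[f]) for f in promoting_map.promoting
    )
    salubrious = category != "unhealthy" and promoting_count >= threshold
    scen = scenario if isinstance(scenario, Scenario) else Scenario(scenario)
    return ScenarioClassification(
        scenario=scen,
        category=category,
        salubrious=salubrious,
        promoting_count=promoting_count,
    )


@dataclass(frozen=True)
class PooledScenarios:
    """Concatenation of per-region scenario sets with provenance tags.

    ``total`` counts scenarios with multiplicity (a scenario found in two
    regions counts twice); ``unique`` is the size of the deduplicated
    assignment set.
    """

    records: tuple[tuple[str, Scenario], ...]

    @property
    def total(self) -> int:
        return len(self.records)

    @property
    def unique(self) -> int:
        return len({s for _, s in self.records})

    @property
    def scenarios(self) -> list[Scenario]:
        """Pooled scenario list, duplicates retained."""
        return [s for _, s in self.records]

    def deduplicated(self) -> list[Scenario]:
        """First occurrence of each distinct scenario, pool order preserved."""
        seen: set[Scenario] = set()
        out: list[Scenario] = []
        for _, s in self.records:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out


def pool_scenario_sets(
    sets: Mapping[str, Sequence[Scenario]] | Sequence[Sequence[Scenario]],
) -> PooledScenarios:
    """Pool scenario sets from several regions, keeping provenance.

    ``sets`` is either a mapping region name -> scenario list, or a plain
    sequence of lists (tagged ``set1``, ``set2``, ...).  All sets must
    cover the same factor space.
    """
    if isinstance(sets, Mapping):
        named = list(sets.items())
    else:
        named = [(f"set{i + 1}", lst) for i, lst in enumerate(sets)]
    records: list[tuple[str, Scenario]] = []
    factor_space: frozenset[str] | None = None
    for tag, scenarios in named:
        for s in scenarios:
            scen = s if isinstance(s, Scenario) else Scenario(s)
            space = frozenset(scen)
            if factor_space is None:
                factor_space = space
            elif space != factor_space:
                raise ValidationError(
                    f"scenario in set {tag!r} covers factors {sorted(space)!r}, "
                    f"expected {sorted(factor_space)!r}"
                )
            records.append((tag, scen))
    return PooledScenarios(records=tuple(records))


def _require_nonempty(scenarios: Sequence[Mapping[str, str]], what: str) -> None:
    if len(scenarios) == 0:
        raise EmptyScenarioSetError(
            f"{what} is undefined on an empty scenario set; "
            "no consistent scenarios were supplied"
        )


def pct_factors_promoting(
    scenarios: Sequence[Mapping[str, str]],
    promoting_map: PromotingMap,
    exclude: str | None = None,
) -> float:
    """Percentage of factor slots in promoting states across all scenarios.

    Counts every (scenario, factor) slot; ``exclude`` drops one factor
    (e.g. an intervention's fixed factor) from both numerator and
    denominator for sensitivity analysis.
    """
    _require_nonempty(scenarios, "pct_factors_promoting")
    factors = [f for f in promoting_map.promoting if f != (exclude or "").strip()]
    if not factors:
        raise ValidationError("no factors left after exclusion")
    promoting = 0
    for scenario in scenarios:
        promoting_map.check_scenario(scenario)
        promoting += sum(
            promoting_map.is_promoting(f, scenario[f]) for f in factors
        )
    return 100.0 * promoting / (len(scenarios) * len(factors))


def category_proportions(
    scenarios: Sequence[Mapping[str, str]],
    promoting_map: PromotingMap,
    threshold: int = DEFAULT_SALUBRIOUS_THRESHOLD,
) -> dict[str, float]:
    """Percentages of healthy / mixed / unhealthy scenarios, plus the
    (overlapping) salubrious percentage, over one scenario list.

    healthy + mixed + unhealthy sums to 100 up to floating-point error;
    salubrious is computed over the same list and may overlap healthy and
    mixed by design.
    """
    _require_nonempty(scenarios, "category_proportions")
    counts = {c: 0 for c in CATEGORY_ORDER}
    salubrious = 0
    for scenario in scenarios:
        cls = classify_scenario(scenario, promoting_map, threshold)
        counts[cls.category] += 1
        salubrious += cls.salubrious
    n = len(scenarios)
    out = {c: 100.0 * counts[c] / n for c in CATEGORY_ORDER}
    out["salubrious"] = 100.0 * salubrious / n
    return out


def outcome_proportions(
    scenarios: Sequence[Mapping[str, str]],
    promoting_map: PromotingMap,
) -> dict[str, float]:
    """For each outcome factor, the percentage of scenarios in which it is
    in its promoting state."""
    _require_nonempty(scenarios, "outcome_proportions")
    n = len(scenarios)
    out: dict[str, float] = {}
    for o in promoting_map.outcomes:
        hits = sum(promoting_map.is_promoting(o, s[o]) for s in scenarios)
        out[o] = 100.0 * hits / n
    return out


@dataclass(frozen=True)
class InterventionResult:
    """Consistent-scenario set and summary metrics under one fixed state.

    ``fixed_factor`` is ``None`` for the baseline (no intervention) entry.
    When the consistent set is empty the metric fields are ``None`` and
    ``empty`` is true — empty sets are surfaced explicitly, never dropped.
    """

    fixed_factor: str | None
    fixed_state: str | None
    scenarios: tuple[Scenario, ...]
    pct_promoting: float | None
    category_pcts: dict[str, float] | None
    outcome_pcts: dict[str, float] | None
    classifications: tuple[ScenarioClassification, ...] = field(default_factory=tuple)

    @property
    def n_scenarios(self) -> int:
        return len(self.scenarios)

    @property
    def empty(self) -> bool:
        return not self.scenarios

    @property
    def label(self) -> str:
        if self.fixed_factor is None:
            return "baseline"
        return f"{self.fixed_factor}={self.fixed_state}"


def _summarise(
    fixed_factor: str | None,
    fixed_state: str | None,
    scenarios: Sequence[Scenario],
    promoting_map: PromotingMap,
    threshold: int,
    include_fixed: bool,
) -> InterventionResult:
    scenarios = tuple(scenarios)
    if not scenarios:
        return InterventionResult(
            fixed_factor, fixed_state, scenarios, None, None, None
        )
    exclude = None if include_fixed else fixed_factor
    return InterventionResult(
        fixed_factor=fixed_factor,
        fixed_state=fixed_state,
        scenarios=scenarios,
        pct_promoting=pct_factors_promoting(scenarios, promoting_map, exclude=exclude),
        category_pcts=category_proportions(scenarios, promoting_map, threshold),
        outcome_pcts=outcome_proportions(scenarios, promoting_map),
        classifications=tuple(
            classify_scenario(s, promoting_map, threshold) for s in scenarios
        ),
    )


def intervention_sweep(
    matrix: CrossImpactMatrix,
    promoting_map: PromotingMap,
    mode: str = "weak",
    threshold: int = DEFAULT_SALUBRIOUS_THRESHOLD,
    tolerance: int = 0,
    include_fixed: bool = True,
) -> list[InterventionResult]:
    """Baseline plus one intervention per (factor, state).

    The first result is the baseline (no fixing); the rest fix each
    factor to each of its states in turn, ordered by factor declaration
    then state index, and re-enumerate the consistent scenarios.
    ``include_fixed`` controls whether the fixed factor's own slot counts
    in ``pct_promoting`` (it does by default: the metric reads "across all
    consistent scenarios" literally).
    """
    results = [
        _summarise(
            None,
            None,
            enumerate_consistent(matrix, None, mode=mode, tolerance=tolerance),
            promoting_map,
            threshold,
            include_fixed=True,
        )
    ]
    for f in matrix.factors:
        for state in f.states:
            scenarios = enumerate_consistent(
                matrix, {f.name: state}, mode=mode, tolerance=tolerance
            )
            results.append(
                _summarise(
                    f.name, state, scenarios, promoting_map, threshold, include_fixed
                )
            )
    return results


def plot_category_sweep(results: Sequence[InterventionResult], ax=None):
    """Plain grouped-bar chart of category percentages per intervention.

    A quick-look helper, not a publication figure.  Empty results are
    drawn as gaps.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.5 * len(results)), 4))
    labels = [r.label for r in results]
    x = np.arange(len(results))
    width = 0.2
    series = list(CATEGORY_ORDER) + ["salubrious"]
    colors = {"healthy": "tab:green", "mixed": "tab:olive",
              "unhealthy": "tab:red", "salubrious": "black"}
    for i, cat in enumerate(series):
        vals = [
            (r.category_pcts or {}).get(cat, float("nan")) for r in results
        ]
        ax.bar(x + (i - 1.5) * width, vals, width, label=cat, color=colors[cat])
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("% of consistent scenarios")
    ax.legend(fontsize=7)
    ax.figure.tight_layout()
    return ax
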
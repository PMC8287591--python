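"""Tests for scenario classification, pooling and intervention metrics."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cibscen import (
    PromotingMap,
    Scenario,
    category_proportions,
    classify_scenario,
    enumerate_consistent,
    intervention_sweep,
    outcome_proportions,
    pct_factors_promoting,
    pool_scenario_sets,
    salubrious_threshold,
)
from cibscen.errors import EmptyScenarioSetError, ValidationError
from cibscen.synthetic import generate_random_matrix

from conftest import make_toy_matrix


def scenario_promoting_in(pmap: PromotingMap, factors, promoting: set[str]) -> Scenario:
    """Scenario with exactly the named factors in their promoting state."""
    by_name = {f.name: f for f in factors}
    assignment = {}
    for name, state in pmap.promoting.items():
        f = by_name[name]
        if name in promoting:
            assignment[name] = state
        else:
            assignment[name] = f.states[1 - f.state_index(state)]
    return Scenario(assignment)


class TestSalubriousThreshold:
    def test_eleven_factors_over_seventy_percent_is_eight(self):
        assert salubrious_threshold(11) == 8

    @pytest.mark.parametrize("n,expected", [(10, 8), (7, 5), (4, 3)])
    def test_other_counts(self, n, expected):
        assert salubrious_threshold(n) == expected


class TestClassifyScenario:
    def test_all_promoting_is_healthy_and_salubrious(self, factors11, pmap11):
        scen = scenario_promoting_in(pmap11, factors11, set(pmap11.promoting))
        cls = classify_scenario(scen, pmap11)
        assert cls.category == "healthy"
        assert cls.salubrious
        assert cls.promoting_count == 11

    def test_healthy_below_threshold_not_salubrious(self, factors11, pmap11):
        # all 3 outcomes plus 4 other factors promoting: healthy, 7 < 8
        promoting = set(pmap11.outcomes) | {"car_use", "free_time", "street_safety",
                                            "political_will"}
        cls = classify_scenario(
            scenario_promoting_in(pmap11, factors11, promoting), pmap11
        )
        assert cls.category == "healthy"
        assert cls.promoting_count == 7
        assert not cls.salubrious

    def test_no_outcomes_promoting_is_unhealthy_never_salubrious(
        self, factors11, pmap11
    ):
        # 8 non-outcome... only 8 exist; all of them promoting but no outcome
        promoting = set(pmap11.promoting) - set(pmap11.outcomes)
        cls = classify_scenario(
            scenario_promoting_in(pmap11, factors11, promoting), pmap11
        )
        assert cls.category == "unhealthy"
        assert cls.promoting_count == 8
        assert not cls.salubrious  # salubrious requires a non-unhealthy category

    def test_partial_outcomes_is_mixed(self, factors11, pmap11):
        promoting = {"physical_activity"}
        cls = classify_scenario(
            scenario_promoting_in(pmap11, factors11, promoting), pmap11
        )
        assert cls.category == "mixed"

    def test_factor_mismatch_rejected(self, pmap11):
        with pytest.raises(ValidationError):
            classify_scenario({"only_one": "low"}, pmap11)


class TestPooling:
    def _scen(self, i):
        return Scenario({"A": "low" if i % 2 else "high", "B": "low" if i // 2 else "high"})

    def test_shared_scenario_counts_once_in_unique(self):
        shared = self._scen(0)
        pooled = pool_scenario_sets(
            {"r1": [shared, self._scen(1), self._scen(2)],
             "r2": [shared, self._scen(3)],
             "r3": [self._scen(1), self._scen(2)]}
        )
        assert pooled.total == 7
        assert pooled.unique == 4

    def test_single_duplicate_free_set(self):
        pooled = pool_scenario_sets([[self._scen(0), self._scen(1)]])
        assert pooled.total == pooled.unique == 2

    def test_three_identical_singletons(self):
        s = self._scen(0)
        pooled = pool_scenario_sets([[s], [s], [s]])
        assert pooled.total == 3 and pooled.unique == 1
        assert pooled.deduplicated() == [s]

    def test_provenance_tags_kept(self):
        pooled = pool_scenario_sets({"Peru": [self._scen(0)], "Brazil": [self._scen(1)]})
        assert [tag for tag, _ in pooled.records] == ["Peru", "Brazil"]

    def test_mismatched_factor_spaces_rejected(self):
        with pytest.raises(ValidationError):
            pool_scenario_sets([[self._scen(0)], [Scenario({"A": "low"})]])


class TestPctFactorsPromoting:
    def _pmap(self):
        return PromotingMap({"A": "high", "B": "high"}, outcomes=("A",))

    def test_all_promoting_is_100(self):
        pmap = self._pmap()
        assert pct_factors_promoting([Scenario({"A": "high", "B": "high"})], pmap) == 100

    def test_symmetric_pair_is_50(self):
        pmap = self._pmap()
        scen = [
            Scenario({"A": "high", "B": "high"}),
            Scenario({"A": "low", "B": "low"}),
        ]
        assert pct_factors_promoting(scen, pmap) == 50

    def test_hand_counted_slots(self):
        pmap = PromotingMap(
            {"A": "high", "B": "high", "C": "high", "D": "high"}, outcomes=("A",)
        )
        scen = [  # 3 + 2 + 1 = 6 promoting slots of 12
            Scenario({"A": "high", "B": "high", "C": "high", "D": "low"}),
            Scenario({"A": "high", "B": "high", "C": "low", "D": "low"}),
            Scenario({"A": "high", "B": "low", "C": "low", "D": "low"}),
        ]
        assert pct_factors_promoting(scen, pmap) == 50

    def test_empty_set_is_an_error_not_zero(self):
        with pytest.raises(EmptyScenarioSetError):
            pct_factors_promoting([], self._pmap())

    def test_duplicating_the_list_is_invariant(self):
        pmap = self._pmap()
        scen = [Scenario({"A": "high", "B": "low"}), Scenario({"A": "low", "B": "high"})]
        assert pct_factors_promoting(scen, pmap) == pct_factors_promoting(
            scen + scen, pmap
        )

    def test_inverted_map_complements_percentage(self, factors11, pmap11):
        scen = [
            scenario_promoting_in(pmap11, factors11, {"car_use", "free_time"}),
            scenario_promoting_in(pmap11, factors11, set(pmap11.outcomes)),
        ]
        p = pct_factors_promoting(scen, pmap11)
        q = pct_factors_promoting(scen, pmap11.inverted(factors11))
        assert p + q == pytest.approx(100)


class TestProportions:
    def test_all_promoting_scenarios(self, factors11, pmap11):
        scen = [scenario_promoting_in(pmap11, factors11, set(pmap11.promoting))] * 3
        props = category_proportions(scen, pmap11)
        assert props == {
            "healthy": 100.0, "mixed": 0.0, "unhealthy": 0.0, "salubrious": 100.0
        }
        assert all(v == 100.0 for v in outcome_proportions(scen, pmap11).values())

    def test_hand_counted_mixture(self, factors11, pmap11):
        all_p = set(pmap11.promoting)
        scen = (
            [scenario_promoting_in(pmap11, factors11, all_p)]  # healthy + salubrious
            + [scenario_promoting_in(pmap11, factors11, {"physical_activity"})]  # mixed
            + [scenario_promoting_in(pmap11, factors11, set())] * 2  # unhealthy
        )
        props = category_proportions(scen, pmap11)
        assert props == {
            "healthy": 25.0, "mixed": 25.0, "unhealthy": 50.0, "salubrious": 25.0
        }

    def test_partition_sums_to_100(self, factors11, pmap11):
        import itertools

        scen = [
            scenario_promoting_in(pmap11, factors11, set(combo))
            for combo in itertools.combinations(pmap11.promoting, 3)
        ][:40]
        props = category_proportions(scen, pmap11)
        total = props["healthy"] + props["mixed"] + props["unhealthy"]
        assert total == pytest.approx(100, abs=0.1)

    def test_outcome_proportions_hand_count(self, factors11, pmap11):
        scen = [
            scenario_promoting_in(pmap11, factors11, {"chronic_disease"}),
            scenario_promoting_in(pmap11, factors11, {"chronic_disease", "car_use"}),
            scenario_promoting_in(pmap11, factors11, set()),
            scenario_promoting_in(pmap11, factors11, {"physical_activity"}),
            scenario_promoting_in(pmap11, factors11, set()),
        ]
        props = outcome_proportions(scen, pmap11)
        assert props["chronic_disease"] == 40.0
        assert props["physical_activity"] == 20.0
        assert props["processed_food"] == 0.0

    def test_empty_sets_error(self, pmap11):
        with pytest.raises(EmptyScenarioSetError):
            category_proportions([], pmap11)
        with pytest.raises(EmptyScenarioSetError):
            outcome_proportions([], pmap11)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sets(st.sampled_from([
        "chronic_disease", "physical_activity", "processed_food",
        "car_use", "free_time", "street_safety", "marketing_regulations",
        "ssb_taxes", "healthy_food_prices", "transport_subsidies", "political_will",
    ])), min_size=1, max_size=15))
    def test_category_partition_property(self, promoting_sets):
        from cibscen import default_factors, default_promoting_map

        factors, pmap = default_factors(), default_promoting_map()
        scen = [scenario_promoting_in(pmap, factors, s) for s in promoting_sets]
        props = category_proportions(scen, pmap)
        assert props["healthy"] + props["mixed"] + props["unhealthy"] == pytest.approx(100)
        assert props["salubrious"] <= props["healthy"] + props["mixed"] + 1e-9


class TestInterventionSweep:
    def _toy_pmap(self):
        return PromotingMap({"A": "high", "B": "high", "C": "high"}, outcomes=("A",))

    def test_baseline_entry_equals_unfixed_enumeration(self):
        m = make_toy_matrix()
        results = intervention_sweep(m, self._toy_pmap(), threshold=2)
        baseline = results[0]
        assert baseline.fixed_factor is None
        assert list(baseline.scenarios) == enumerate_consistent(m, mode="weak")

    def test_ordering_and_entry_count(self):
        m = make_toy_matrix()
        results = intervention_sweep(m, self._toy_pmap(), threshold=2)
        assert len(results) == 1 + 3 * 2  # baseline + factor x state
        labels = [r.label for r in results[1:]]
        assert labels == ["A=low", "A=high", "B=low", "B=high", "C=low", "C=high"]

    def test_toy_fix_c_high_metrics(self):
        m = make_toy_matrix()
        results = intervention_sweep(m, self._toy_pmap(), threshold=2)
        by_label = {r.label: r for r in results}
        r = by_label["C=high"]
        assert [s.assignment for s in r.scenarios] == [
            {"A": "high", "B": "high", "C": "high"}
        ]
        assert r.pct_promoting == 100.0

    def test_superset_property_on_random_instances(self):
        for seed in range(15):
            m = generate_random_matrix(5, density=0.6, seed=seed)
            pmap = PromotingMap(
                {f.name: "high" for f in m.factors}, outcomes=(m.factors[0].name,)
            )
            results = intervention_sweep(m, pmap, threshold=3)
            baseline = set(results[0].scenarios)
            for r in results[1:]:
                kept = {s for s in baseline if s[r.fixed_factor] == r.fixed_state}
                assert kept <= set(r.scenarios)

    def test_all_zero_matrix_fixing_keeps_all_extensions(self):
        from cibscen import CrossImpactMatrix, FactorDef

        m = CrossImpactMatrix([FactorDef("A"), FactorDef("B")])
        pmap = PromotingMap({"A": "high", "B": "high"}, outcomes=("A",))
        results = intervention_sweep(m, pmap, threshold=1)
        by_label = {r.label: r for r in results}
        assert by_label["A=high"].n_scenarios == 2  # both B states tie

    def test_empty_sets_surface_explicitly(self):
        # a 2-cycle of mutual contradiction has no strict-consistent scenario
        from cibscen import CrossImpactMatrix, FactorDef

        m = CrossImpactMatrix([FactorDef("A"), FactorDef("B")])
        m.set_score("A", "high", "B", "high", -2)
        m.set_score("A", "high", "B", "low", 2)
        m.set_score("A", "low", "B", "high", 2)
        m.set_score("A", "low", "B", "low", -2)
        m.set_score("B", "high", "A", "high", 2)
        m.set_score("B", "high", "A", "low", -2)
        m.set_score("B", "low", "A", "high", -2)
        m.set_score("B", "low", "A", "low", 2)
        pmap = PromotingMap({"A": "high", "B": "high"}, outcomes=("A",))
        results = intervention_sweep(m, pmap, mode="strict", threshold=1)
        assert any(r.empty for r in results)
        for r in results:
            if r.empty:
                assert r.pct_promoting is None and r.category_pcts is None

    def test_exclude_fixed_slot_flag(self):
        from cibscen import CrossImpactMatrix, FactorDef

        m = CrossImpactMatrix([FactorDef("A"), FactorDef("B")])
        pmap = PromotingMap({"A": "high", "B": "high"}, outcomes=("A",))
        incl = intervention_sweep(m, pmap, threshold=1, include_fixed=True)
        excl = intervention_sweep(m, pmap, threshold=1, include_fixed=False)
        # fixing A=high on the all-tie matrix keeps both B states:
        # inclusive counts A's promoting slot (3 of 4), exclusive drops it (1 of 2)
        assert {r.label: r for r in incl}["A=high"].pct_promoting == 75.0
        assert {r.label: r for r in excl}["A=high"].pct_promoting == 50.0
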
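"""Default system configuration: the 11-factor urban food-and-transport system.

Eleven binary (low/high) factors spanning three categories: three health
outcomes, three behavioural/environmental intermediaries, and five
structural/policy levers.  The promoting map records which state of each
factor is considered health-promoting.

Note on ``healthy_food_prices``: whether low or high prices of healthy
food should count as promoting is genuinely ambiguous (low prices improve
access, yet high prices can coincide with thriving healthy-food markets);
this package designates *low* as promoting and treats the choice as a
documented configuration default that users can override in their factor
config file.
"""

from __future__ import annotations

from .analysis import PromotingMap
from .core import FactorDef

DEFAULT_FACTORS: tuple[FactorDef, ...] = (
    # health outcomes
    FactorDef("chronic_disease", "Chronic disease prevalence", ("low", "high"), "outcome"),
    FactorDef("physical_activity", "Physical activity", ("low", "high"), "outcome"),
    FactorDef("processed_food", "Highly processed food consumption", ("low", "high"), "outcome"),
    # intermediaries
    FactorDef("car_use", "Car use", ("low", "high"), "intermediary"),
    FactorDef("free_time", "Free time", ("low", "high"), "intermediary"),
    FactorDef("street_safety", "Street safety (from crime)", ("low", "high"), "intermediary"),
    # structural / policy
    FactorDef("marketing_regulations", "Food marketing regulations", ("low", "high"), "structural"),
    FactorDef("ssb_taxes", "SSB / processed food taxes", ("low", "high"), "structural"),
    FactorDef("healthy_food_prices", "Healthy food prices", ("low", "high"), "structural"),
    FactorDef("transport_subsidies", "Public transportation subsidies", ("low", "high"), "structural"),
    FactorDef("political_will", "Political will for social change", ("low", "high"), "structural"),
)

DEFAULT_OUTCOMES: tuple[str, ...] = (
    "chronic_disease",
    "physical_activity",
    "processed_food",
)

DEFAULT_PROMOTING_STATES: dict[str, str] = {
    "chronic_disease": "low",
    "physical_activity": "high",
    "processed_food": "low",
    "car_use": "low",
    "free_time": "high",
    "street_safety": "high",
    "marketing_regulations": "high",
    "ssb_taxes": "high",
    "healthy_food_prices": "low",
    "transport_subsidies": "high",
    "political_will": "high",
}


def default_factors() -> list[FactorDef]:
    """Fresh copy of the default 11-factor configuration."""
    return list(DEFAULT_FACTORS)


def default_promoting_map() -> PromotingMap:
    """Promoting map for the default 11-factor configuration."""
    return PromotingMap(
        promoting=dict(DEFAULT_PROMOTING_STATES), outcomes=DEFAULT_OUTCOMES
    )
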
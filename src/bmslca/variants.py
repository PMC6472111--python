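"""Scenario switches for the published sensitivity cases.

A variant is a (modified scenario, pipeline overrides) pair: packaging
and additive switches rewrite the scenario; allocation, GWP set,
sterilisation mode and land-use-change switches override pipeline
arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .types import CountryScenario, GWP_SETS

__all__ = [
    "VITAMIN_MASS_FRACTION",
    "CITED_ADDITIVE_EFS",
    "VARIANT_SWITCHES",
    "apply_variant",
]

#: Vitamins and minerals are ~2% of powder mass (excluded from the recipe
#: mass balance; added as a production-stage add-on in this variant).
VITAMIN_MASS_FRACTION = 0.02

#: Published CFP estimates for food/feed additives, kg CO2e per kg.
CITED_ADDITIVE_EFS = {
    "vitamin B2": 67.0,
    "vitamin B12": 4.8,
    "vitamin D2": 4.8,
    "ascorbic acid": 3.1,
    "feed vitamin blend": 1.1,
    "potassium carbonate": 0.3,
}

VARIANT_SWITCHES = (
    "identity",
    "tin_cans_only",
    "bag_in_box_only",
    "fat_protein_allocation",
    "energy_allocation",
    "economic_allocation",
    "steam_sterilisation",
    "no_sterilisation",
    "gwp_ar5",
    "gwp_ar5_feedback",
    "luc",
    "vitamins",
)


@dataclass
class Variant:
    scenario: CountryScenario
    overrides: dict[str, Any] = field(default_factory=dict)


def apply_variant(
    scenario: CountryScenario,
    switch: str,
    additive_ef: float | None = None,
) -> Variant:
    """Return a deep-modified scenario copy plus pipeline overrides.

    ``additive_ef`` (kg CO2e per kg additive) selects the vitamin-blend
    intensity for the ``vitamins`` switch; defaults to the highest cited
    additive value.
    """
    if switch == "identity":
        return Variant(scenario)
    if switch == "tin_cans_only":
        return Variant(scenario.with_updates(packaging_mix={"tin_can": 1.0}))
    if switch == "bag_in_box_only":
        return Variant(scenario.with_updates(packaging_mix={"bag_in_box": 1.0}))
    if switch == "fat_protein_allocation":
        return Variant(scenario, {"basis": "fat_protein"})
    if switch == "energy_allocation":
        return Variant(scenario, {"basis": "energy"})
    if switch == "economic_allocation":
        return Variant(scenario, {"basis": "economic"})
    if switch == "steam_sterilisation":
        return Variant(scenario, {"sterilisation_mode": "steam"})
    if switch == "no_sterilisation":
        return Variant(scenario, {"sterilisation_mode": "none"})
    if switch == "gwp_ar5":
        return Variant(scenario, {"gwp": GWP_SETS["AR5"]})
    if switch == "gwp_ar5_feedback":
        return Variant(scenario, {"gwp": GWP_SETS["AR5F"]})
    if switch == "luc":
        return Variant(scenario, {"include_luc": True})
    if switch == "vitamins":
        ef = max(CITED_ADDITIVE_EFS.values()) if additive_ef is None else additive_ef
        addons = dict(scenario.production_addons)
        addons["vitamins_minerals"] = VITAMIN_MASS_FRACTION * ef
        return Variant(scenario.with_updates(production_addons=addons))
    raise ValueError(f"unknown variant switch {switch!r}")
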
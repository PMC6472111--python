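"""Cradle-to-bottle footprint of 1 kg powdered BMS (CFP_Cons).

Adds to the production footprint: transport from plant to retail,
baby-bottle manufacture, and in-home sterilisation and preparation, with
heat supplied by the country's stove and fuel mix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .production import ProductionResult, _m, _packaging_mass
from .types import CountryScenario, GWPSet, REFERENCE_GWP, StageBreakdown, StoveFuel
from .types import FeedingParameters

WATER_SPECIFIC_HEAT = 4.186e-3  # MJ per kg per K
AMBIENT_TEMP_C = 20.0
BOILING_TEMP_C = 100.0

#: MJ needed to bring one litre of water from ambient to the boil.
HEAT_PER_LITRE = WATER_SPECIFIC_HEAT * (BOILING_TEMP_C - AMBIENT_TEMP_C)

STERILISATION_MODES = ("stovetop", "steam", "none")

__all__ = [
    "FeedingPlan",
    "feeding_plan",
    "stove_delivered_ef",
    "home_energy_cfp",
    "cfp_consumption",
    "STERILISATION_MODES",
]


@dataclass(frozen=True)
class FeedingPlan:
    """Per-kg-of-powder feeding quantities implied by infant energy needs."""

    servings_per_kg: int
    bottles_to_sterilise_per_kg: int
    sterilisation_batches_per_kg: float
    water_heated_for_prep: float  # L per kg BMS
    water_heated_for_sterilisation: float  # L per kg BMS
    bottles_manufactured_per_kg: float


def feeding_plan(
    p: FeedingParameters = FeedingParameters(),
    mult: Optional[Mapping[str, float]] = None,
) -> FeedingPlan:
    """Derive the feeding plan from the infant feeding parameters.

    One kg of powder at 18.6 g per serving gives 54 bottles, i.e. nine
    sterilisation batches of six bottles; bottle manufacture is amortised
    over the powder consumed in the six-month feeding period.
    """
    serving_mass = p.serving_mass * _m(mult, "serving_mass")
    if serving_mass <= 0:
        raise ValueError("serving mass must be positive")
    servings = round(1000.0 / serving_mass)
    batches = servings / p.bottles_per_batch
    return FeedingPlan(
        servings_per_kg=servings,
        bottles_to_sterilise_per_kg=servings,
        sterilisation_batches_per_kg=batches,
        water_heated_for_prep=servings * p.water_per_bottle,
        water_heated_for_sterilisation=batches
        * p.sterilisation_water
        * _m(mult, "sterilisation_water"),
        bottles_manufactured_per_kg=p.bottles_per_period / p.period_bms_mass,
    )


def stove_delivered_ef(
    stove_profile: Sequence[StoveFuel],
    gwp: GWPSet = REFERENCE_GWP,
    mult: Optional[Mapping[str, float]] = None,
) -> float:
    """kg CO2e per MJ of heat delivered to the pan, over the fuel mix.

    Each fuel's emission factor applies per MJ of fuel energy; dividing
    by stove efficiency converts delivered heat back to fuel burned.
    """
    total_share = sum(f.share for f in stove_profile)
    if abs(total_share - 1.0) > 1e-9:
        raise ValueError("stove fuel shares must sum to 1")
    out = 0.0
    for f in stove_profile:
        eff = f.efficiency * _m(mult, "stove_efficiency")
        if eff <= 0:
            raise ValueError(f"stove fuel {f.fuel!r} has zero efficiency")
        ef = f.ef_per_mj_fuel * _ef_scale(f.gas_shares, gwp)
        out += f.share * ef / eff
    return out


def _ef_scale(gas_shares: Mapping[str, float], gwp: GWPSet) -> float:
    ref = REFERENCE_GWP
    return (
        gas_shares.get("co2", 0.0)
        + gas_shares.get("ch4", 0.0) * gwp.ch4 / ref.ch4
        + gas_shares.get("n2o", 0.0) * gwp.n2o / ref.n2o
    )


def home_energy_cfp(
    plan: FeedingPlan,
    scenario: CountryScenario,
    gwp: GWPSet = REFERENCE_GWP,
    mult: Optional[Mapping[str, float]] = None,
) -> tuple[float, float]:
    """(sterilisation, preparation) kg CO2e per kg BMS on the stovetop.

    Heat demand is the water volume brought from ambient to the boil,
    plus a per-batch boil margin for sterilisation (holding the rolling
    boil); the stove mix converts delivered heat to fuel emissions.
    """
    ef_delivered = stove_delivered_ef(scenario.stove_profile, gwp, mult)
    sterilisation_heat = (
        plan.water_heated_for_sterilisation * HEAT_PER_LITRE
        + plan.sterilisation_batches_per_kg * scenario.sterilisation_boil_margin
    )
    preparation_heat = plan.water_heated_for_prep * HEAT_PER_LITRE
    return sterilisation_heat * ef_delivered, preparation_heat * ef_delivered


def cfp_consumption(
    scenario: CountryScenario,
    production_result: ProductionResult,
    gwp: GWPSet = REFERENCE_GWP,
    sterilisation_mode: str = "stovetop",
    feeding: FeedingParameters = FeedingParameters(),
    include_luc: bool = False,
    mult: Optional[Mapping[str, float]] = None,
) -> StageBreakdown:
    """Stage breakdown of consuming 1 kg BMS in the given country."""
    if not scenario.has_role("consumption"):
        raise ValueError(f"scenario {scenario.name!r} has no consumption role")
    if production_result is None:
        raise ValueError(
            f"scenario {scenario.name!r} needs a paired production result "
            f"(pairing: {scenario.production_pairing})"
        )
    if sterilisation_mode not in STERILISATION_MODES:
        raise ValueError(f"unknown sterilisation mode {sterilisation_mode!r}")
    if production_result.gwp != gwp.label:
        raise ValueError(
            f"production result was characterised under {production_result.gwp}, "
            f"not {gwp.label}"
        )

    plan = feeding_plan(feeding, mult)
    sterilisation, preparation = home_energy_cfp(plan, scenario, gwp, mult)
    if sterilisation_mode == "steam":
        sterilisation *= scenario.steam_sterilisation_scale
    elif sterilisation_mode == "none":
        sterilisation = 0.0

    cargo = (1.0 + _packaging_mass(production_result_scenario_mass(scenario))) / 1000.0
    transport = sum(
        cargo * leg.distance_km * _m(mult, "retail_transport_distance") * leg.ef_per_tkm
        for leg in scenario.retail_transport
    )

    bottles = plan.bottles_manufactured_per_kg * scenario.bottle_ef

    stages = {
        "bms_production": production_result.total,
        "sterilisation": sterilisation,
        "preparation": preparation,
        "transport": transport,
        "bottle_production": bottles,
    }
    breakdown = StageBreakdown(stages, label=f"CFP_Cons {scenario.name}")
    breakdown.check()
    return breakdown


def production_result_scenario_mass(scenario: CountryScenario) -> CountryScenario:
    """Scenario whose packaging spec sets the retail cargo mass.

    Consumption countries inherit the packaged product from their paired
    production site; the packaging mix is identical across the defaults,
    so the consuming scenario's own spec is used when present.
    """
    return scenario
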
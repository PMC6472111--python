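"""Cradle-to-factory-gate footprint of 1 kg packaged BMS (CFP_Prod).

Stage structure mirrors the production results table: raw milk,
vegetable oils, processing energy, packaging, transport, plus optional
land-use-change and additive add-on stages.

All stage functions accept a ``mult`` mapping of named multipliers (e.g.
``{"raw_milk_ef": 1.1}``) used by the Monte Carlo and one-at-a-time
sensitivity drivers; unset parameters default to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .allocation import (
    AllocatedBurden,
    MilkProcessParams,
    ProcessTree,
    allocated_burden,
    dairy_mass_balance,
)
from .recipe import BASELINE_RECIPE, IngredientSpec, Recipe, default_ingredients
from .types import CountryScenario, GWPSet, REFERENCE_GWP, StageBreakdown

__all__ = ["ProductionResult", "cfp_production", "waste_multiplier", "oil_blend_cfp"]


def _m(mult: Optional[Mapping[str, float]], key: str) -> float:
    return 1.0 if mult is None else float(mult.get(key, 1.0))


def waste_multiplier(waste_fractions) -> float:
    """Upstream inflation factor from chain losses: prod(1 / (1 - w))."""
    out = 1.0
    for w in waste_fractions:
        if not (0.0 <= w < 1.0):
            raise ValueError(f"waste fraction {w} outside [0, 1)")
        out /= 1.0 - w
    return out


def oil_blend_cfp(
    blend: Mapping[str, float],
    oil_efs: Mapping[str, "EmissionFactor"],
    gwp: GWPSet = REFERENCE_GWP,
    mult: Optional[Mapping[str, float]] = None,
) -> float:
    """Share-weighted CFP of the vegetable-oil blend, kg CO2e per kg oil.

    Per-oil factors already embed the economic allocation between oil and
    press residues; they are inputs, not modelled here.
    """
    total_share = sum(blend.values())
    if abs(total_share - 1.0) > 1e-9:
        raise ValueError(f"oil blend shares sum to {total_share:.12g}, not 1")
    out = 0.0
    for oil, share in blend.items():
        if oil not in oil_efs:
            raise KeyError(f"no emission factor for oil {oil!r}")
        out += share * oil_efs[oil].characterise(gwp) * _m(mult, f"oil_ef:{oil}")
    return out


@dataclass
class ProductionResult:
    breakdown: StageBreakdown
    scenario: str
    basis: str
    gwp: str
    tree: ProcessTree
    burden: AllocatedBurden

    @property
    def total(self) -> float:
        return self.breakdown.total


def _packaging_mass(scenario: CountryScenario) -> float:
    """Mix-weighted packaging material mass per kg BMS."""
    return sum(
        share * sum(scenario.packaging_masses.get(pack, {}).values())
        for pack, share in scenario.packaging_mix.items()
    )


def cfp_production(
    scenario: CountryScenario,
    recipe: Recipe = BASELINE_RECIPE,
    basis: str = "dry_mass",
    gwp: GWPSet = REFERENCE_GWP,
    ingredients: Optional[Mapping[str, IngredientSpec]] = None,
    params: Optional[MilkProcessParams] = None,
    include_luc: bool = False,
    mult: Optional[Mapping[str, float]] = None,
    tree: Optional[ProcessTree] = None,
    burden: Optional[AllocatedBurden] = None,
) -> ProductionResult:
    """Stage breakdown of producing and packaging 1 kg BMS at factory gate.

    Raw-milk burden is the allocated raw-milk mass times the country
    emission factor, inflated by production-chain waste; processing is
    the allocated electricity and heat; packaging, transport and the oil
    blend are scenario-driven.  Pass a precomputed ``tree``/``burden``
    pair to amortise the mass balance across Monte Carlo draws.
    """
    if not scenario.has_role("production"):
        raise ValueError(f"scenario {scenario.name!r} has no production role")
    if tree is None:
        tree = dairy_mass_balance(recipe, ingredients=ingredients, params=params)
    if burden is None:
        burden = allocated_burden(tree, basis)

    wm = waste_multiplier(w * _m(mult, "chain_waste") for w in scenario.chain_waste)
    raw_milk = (
        burden.raw_milk_kg
        * scenario.raw_milk_ef.characterise(gwp)
        * _m(mult, "raw_milk_ef")
        * wm
    )

    processing = (
        burden.electricity_mj
        * _m(mult, "electricity_energy")
        * scenario.electricity_ef.characterise(gwp)
        * _m(mult, "electricity_ef")
        + burden.heat_mj
        * _m(mult, "heat_energy")
        * scenario.heat_ef.characterise(gwp)
        * _m(mult, "heat_ef")
    )

    oil_mass = tree.streams["oil"].dry_mass
    oils = oil_mass * oil_blend_cfp(scenario.oil_blend, scenario.oil_efs, gwp, mult)
    for leg in scenario.oil_transport:
        oils += (
            oil_mass / 1000.0
            * leg.distance_km * _m(mult, "oil_transport_distance")
            * leg.ef_per_tkm
        )

    packaging = 0.0
    for pack, share in scenario.packaging_mix.items():
        for material, mass in scenario.packaging_masses.get(pack, {}).items():
            if material not in scenario.packaging_efs:
                raise KeyError(f"no packaging emission factor for {material!r}")
            packaging += (
                share * mass
                * scenario.packaging_efs[material].characterise(gwp)
                * _m(mult, "packaging_ef")
            )

    cargo_masses = {
        "raw_milk": tree.streams["raw_milk"].wet_mass,
        "whey": tree.streams["whey"].wet_mass,
        "dry_ingredients": tree.streams["wpc"].dry_mass
        + tree.streams["lactose_powder"].dry_mass,
        "bms": 1.0 + _packaging_mass(scenario),
        "packaging": _packaging_mass(scenario),
    }
    transport = 0.0
    for leg in scenario.transport_legs:
        mass = cargo_masses.get(leg.cargo)
        if mass is None:
            raise KeyError(f"unknown transport cargo {leg.cargo!r}")
        transport += (
            mass / 1000.0
            * leg.distance_km * _m(mult, "transport_distance")
            * leg.ef_per_tkm
        )

    stages = {
        "raw_milk": raw_milk,
        "vegetable_oils": oils,
        "processing": processing,
        "packaging": packaging,
        "transport": transport,
    }
    if include_luc and scenario.luc_factors:
        luc = 0.0
        for oil, share in scenario.oil_blend.items():
            factor = scenario.luc_factors.get(f"{oil}_oil", scenario.luc_factors.get(oil, 0.0))
            luc += oil_mass * share * factor
        stages["luc"] = luc
    for name, value in scenario.production_addons.items():
        stages[name] = value

    breakdown = StageBreakdown(stages, label=f"CFP_Prod {scenario.name}")
    breakdown.check()
    return ProductionResult(
        breakdown=breakdown, scenario=scenario.name, basis=basis, gwp=gwp.label,
        tree=tree, burden=burden,
    )
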
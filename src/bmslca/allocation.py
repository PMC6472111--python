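"""Dairy processing mass balance and co-product allocation.

Models the wet-mix / spray-dry route for powdered BMS: raw milk is
skimmed (cream co-product); part of the skim milk goes straight to the
BMS wet mix and part to cheese-making (curd co-product), whose whey is
separated into whey protein concentrate and lactose powder.  The tree is
sized backwards from the recipe's dairy-ingredient demands per kg BMS.

Burdens (raw milk mass, process electricity and heat) are partitioned
among co-products at each step by one of four allocation bases and
compose multiplicatively along the tree, following standard dairy-LCA
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .recipe import (
    ENERGY_CARB,
    ENERGY_FAT,
    ENERGY_PROTEIN,
    IngredientSpec,
    Recipe,
    default_ingredients,
)

DRY_TOL = 1e-6

ALLOCATION_BASES = ("dry_mass", "fat_protein", "energy", "economic")

__all__ = [
    "CoProductStream",
    "ProcessStep",
    "ProcessTree",
    "MilkProcessParams",
    "AllocatedBurden",
    "dairy_mass_balance",
    "allocation_factors",
    "allocated_burden",
    "InfeasibleMassBalanceError",
    "ALLOCATION_BASES",
]

COMPONENTS = ("protein", "fat", "carbohydrate", "ash", "other")


class InfeasibleMassBalanceError(RuntimeError):
    """Raised when the recipe's dairy demands cannot be met by the tree."""


@dataclass
class CoProductStream:
    name: str
    wet_mass: float  # kg per kg BMS
    dry_mass: float
    components: dict[str, float] = field(default_factory=dict)  # kg per kg BMS
    price: float = 0.0  # currency per kg dry matter
    destined_for_bms: bool = False

    @property
    def fat(self) -> float:
        return self.components.get("fat", 0.0)

    @property
    def protein(self) -> float:
        return self.components.get("protein", 0.0)

    @property
    def energy(self) -> float:
        """MJ-scale energy proxy: kJ content per kg BMS, from composition."""
        return (
            ENERGY_FAT * self.fat
            + ENERGY_PROTEIN * self.protein
            + ENERGY_CARB * self.components.get("carbohydrate", 0.0)
        )

    def check(self) -> None:
        if self.dry_mass > self.wet_mass + DRY_TOL:
            raise ValueError(f"{self.name}: dry mass exceeds wet mass")
        if self.fat + self.protein > self.dry_mass + DRY_TOL:
            raise ValueError(f"{self.name}: fat+protein exceed dry mass")
        if min(self.wet_mass, self.dry_mass, self.fat, self.protein) < -DRY_TOL:
            raise ValueError(f"{self.name}: negative mass")


@dataclass
class ProcessStep:
    name: str
    inputs: list[str]
    outputs: list[str]
    electricity: float = 0.0  # MJ per kg BMS
    heat: float = 0.0
    dedicated_to: str = "shared"  # "shared" or "bms"
    evaporated_water: float = 0.0  # kg per kg BMS


@dataclass
class ProcessTree:
    streams: dict[str, CoProductStream]
    steps: list[ProcessStep]
    raw_milk_input: float  # kg raw milk per kg BMS

    def terminal_streams(self) -> list[CoProductStream]:
        consumed = {name for step in self.steps for name in step.inputs}
        return [s for n, s in self.streams.items() if n not in consumed and n != "raw_milk"]

    def check_conservation(self) -> None:
        for step in self.steps:
            in_wet = sum(self.streams[n].wet_mass for n in step.inputs)
            out_wet = sum(self.streams[n].wet_mass for n in step.outputs)
            if abs(in_wet - out_wet - step.evaporated_water) > 1e-6:
                raise ValueError(f"{step.name}: wet-mass balance violated")
            in_dry = sum(self.streams[n].dry_mass for n in step.inputs)
            out_dry = sum(self.streams[n].dry_mass for n in step.outputs)
            if abs(in_dry - out_dry) > DRY_TOL:
                raise ValueError(f"{step.name}: dry-mass balance violated")
        for s in self.streams.values():
            s.check()

    def to_dict(self) -> dict:
        return {
            "raw_milk_input": self.raw_milk_input,
            "streams": {
                n: {
                    "wet_mass": s.wet_mass,
                    "dry_mass": s.dry_mass,
                    "components": dict(s.components),
                    "price": s.price,
                    "destined_for_bms": s.destined_for_bms,
                }
                for n, s in self.streams.items()
            },
            "steps": [
                {
                    "name": st.name,
                    "inputs": list(st.inputs),
                    "outputs": list(st.outputs),
                    "electricity": st.electricity,
                    "heat": st.heat,
                    "dedicated_to": st.dedicated_to,
                    "evaporated_water": st.evaporated_water,
                }
                for st in self.steps
            ],
        }


@dataclass(frozen=True)
class MilkProcessParams:
    """Physical and economic constants of the dairy chain.

    Compositions are mass fractions of dry solids.  Split fractions give
    the share of each skim-solids component that reports to whey in
    cheese-making.  Calibrated so the baseline recipe draws 13.7 kg raw
    milk per kg BMS with 6.55 kg allocated under dry-mass allocation.
    """

    skim_solids_fraction: float = 0.0960699
    cream_mass_fraction: float = 0.051984  # of raw milk
    cream_solids_fraction: float = 0.45
    cream_composition: Mapping[str, float] = field(
        default_factory=lambda: {
            "fat": 0.87, "protein": 0.05, "carbohydrate": 0.06, "ash": 0.01, "other": 0.01,
        }
    )
    whey_split: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein": 0.17580, "fat": 0.61330, "carbohydrate": 0.96,
            "ash": 0.06150, "other": 0.07370,
        }
    )
    curd_moisture: float = 0.55
    prices: Mapping[str, float] = field(
        default_factory=lambda: {
            "skim_milk_bms": 2.5, "skim_milk_cheese": 2.5, "cream": 5.5,
            "curd": 15.5, "whey": 1.76, "wpc": 8.0, "lactose_powder": 0.8,
            "surplus_whey": 0.8, "bms": 12.0, "oil": 1.6, "raw_milk": 3.0,
        }
    )
    # Step energy rates, dedicated flag per step.
    skimming_el_per_kg_milk: float = 0.05
    cheese_heat_per_kg_skim: float = 0.08
    whey_sep_el_per_kg_solids: float = 1.0
    whey_sep_heat_per_kg_solids: float = 4.0
    spray_dry_el_per_kg_bms: float = 1.9724
    spray_dry_heat_per_kg_bms: float = 6.7004


def _ingredient_components(spec: IngredientSpec, mass: float) -> dict[str, float]:
    other = max(0.0, 1.0 - spec.protein - spec.fat - spec.carbohydrate - spec.ash)
    return {
        "protein": spec.protein * mass,
        "fat": spec.fat * mass,
        "carbohydrate": spec.carbohydrate * mass,
        "ash": spec.ash * mass,
        "other": other * mass,
    }


def dairy_mass_balance(
    recipe: Recipe,
    ingredients: Mapping[str, IngredientSpec] | None = None,
    params: MilkProcessParams | None = None,
    chain_waste: Sequence[float] = (),
    demand_scale: float = 1.0,
) -> ProcessTree:
    """Size the dairy process tree for one kg of BMS powder.

    Demands for skim-milk solids, whey protein concentrate and lactose are
    read off the recipe, optionally inflated by supply-chain waste
    fractions, and the tree is solved backwards: the cheese-milk quantity
    is set by the binding whey requirement (protein, carbohydrate or
    total dry matter), surplus whey solids become a co-product, and the
    skimming stage supplies all skim milk plus the cream co-product.
    """
    ingredients = ingredients or default_ingredients()
    params = params or MilkProcessParams()

    if demand_scale <= 0:
        raise ValueError("demand_scale must be positive")
    waste_mult = demand_scale
    for w in chain_waste:
        if not (0.0 <= w < 1.0):
            raise ValueError("chain waste fractions must lie in [0, 1)")
        waste_mult /= 1.0 - w

    d_smp = recipe.fraction("skimmed milk solids") * waste_mult
    d_wpc = recipe.fraction("whey protein concentrate") * waste_mult
    d_lac = recipe.fraction("lactose") * waste_mult
    d_oil = recipe.fraction("vegetable oil") * waste_mult

    smp = ingredients["skimmed milk solids"]
    wpc = ingredients["whey protein concentrate"]
    lac = ingredients["lactose"]

    wpc_comp = _ingredient_components(wpc, d_wpc)
    lac_comp = _ingredient_components(lac, d_lac)
    need = {c: wpc_comp[c] + lac_comp[c] for c in COMPONENTS}
    need_dry = d_wpc + d_lac

    # Whey yield per kg of cheese-milk (skim) solids.
    skim_comp_frac = _ingredient_components(smp, 1.0)
    whey_per_solid = {c: skim_comp_frac[c] * params.whey_split[c] for c in COMPONENTS}
    whey_dry_per_solid = sum(whey_per_solid.values())

    # Cheese-milk solids set by the binding constraint.
    candidates = {}
    if need_dry > 0:
        checks = {c: (need[c], whey_per_solid[c]) for c in COMPONENTS}
        checks["dry mass"] = (need_dry, whey_dry_per_solid)
        for key, (req, avail) in checks.items():
            if req > DRY_TOL:
                if avail <= 0:
                    raise InfeasibleMassBalanceError(
                        f"whey supplies no {key} but the recipe requires it"
                    )
                candidates[key] = req / avail
    cheese_solids = max(candidates.values()) if candidates else 0.0

    whey_comp = {c: whey_per_solid[c] * cheese_solids for c in COMPONENTS}
    whey_dry = whey_dry_per_solid * cheese_solids
    surplus_dry = whey_dry - need_dry
    surplus_comp = {c: whey_comp[c] - need[c] for c in COMPONENTS}
    if min(surplus_comp.values()) < -DRY_TOL:
        bad = min(surplus_comp, key=surplus_comp.get)
        raise InfeasibleMassBalanceError(
            f"whey {bad} demand exceeds whey supply at the binding cheese-milk quantity"
        )
    surplus_comp = {c: max(0.0, v) for c, v in surplus_comp.items()}

    s = params.skim_solids_fraction
    skim_bms_wet = d_smp / s
    skim_cheese_wet = cheese_solids / s
    skim_wet = skim_bms_wet + skim_cheese_wet
    cf = params.cream_mass_fraction
    raw_milk = skim_wet / (1.0 - cf) if skim_wet > 0 else 0.0
    cream_wet = raw_milk * cf
    cream_dry = cream_wet * params.cream_solids_fraction
    cream_comp = {c: cream_dry * params.cream_composition.get(c, 0.0) for c in COMPONENTS}

    curd_dry = cheese_solids - whey_dry
    curd_comp = {
        c: skim_comp_frac[c] * cheese_solids - whey_comp[c] for c in COMPONENTS
    }
    curd_wet = curd_dry / (1.0 - params.curd_moisture)
    whey_wet = skim_cheese_wet - curd_wet
    if whey_wet < whey_dry - DRY_TOL:
        raise InfeasibleMassBalanceError("whey stream drier than its own solids")

    milk_dry = skim_wet * s + cream_dry
    milk_comp = {
        c: skim_comp_frac[c] * skim_wet * s + cream_comp[c] for c in COMPONENTS
    }

    prices = params.prices
    streams = {
        "raw_milk": CoProductStream("raw_milk", raw_milk, milk_dry, milk_comp,
                                    prices["raw_milk"]),
        "skim_milk_bms": CoProductStream(
            "skim_milk_bms", skim_bms_wet, d_smp,
            _ingredient_components(smp, d_smp), prices["skim_milk_bms"]),
        "skim_milk_cheese": CoProductStream(
            "skim_milk_cheese", skim_cheese_wet, cheese_solids,
            _ingredient_components(smp, cheese_solids), prices["skim_milk_cheese"]),
        "cream": CoProductStream("cream", cream_wet, cream_dry, cream_comp,
                                 prices["cream"]),
        "curd": CoProductStream("curd", curd_wet, curd_dry, curd_comp, prices["curd"]),
        "whey": CoProductStream("whey", whey_wet, whey_dry, whey_comp, prices["whey"]),
        "wpc": CoProductStream("wpc", d_wpc, d_wpc, wpc_comp, prices["wpc"],
                               destined_for_bms=True),
        "lactose_powder": CoProductStream("lactose_powder", d_lac, d_lac, lac_comp,
                                          prices["lactose_powder"], destined_for_bms=True),
        "skim_bms_solids": CoProductStream(
            "skim_bms_solids", d_smp, d_smp, _ingredient_components(smp, d_smp),
            prices["skim_milk_bms"], destined_for_bms=True),
        "oil": CoProductStream("oil", d_oil, d_oil, {"fat": d_oil}, prices["oil"]),
        "bms": CoProductStream(
            "bms", d_smp + d_wpc + d_lac + d_oil, d_smp + d_wpc + d_lac + d_oil,
            {}, prices["bms"], destined_for_bms=True),
    }
    surplus = None
    if surplus_dry > DRY_TOL:
        surplus = CoProductStream("surplus_whey", surplus_dry, surplus_dry,
                                  surplus_comp, prices["surplus_whey"])
        streams["surplus_whey"] = surplus

    whey_outputs = ["wpc", "lactose_powder"] + (["surplus_whey"] if surplus else [])
    steps = [
        ProcessStep(
            "skimming", ["raw_milk"], ["skim_milk_bms", "skim_milk_cheese", "cream"],
            electricity=params.skimming_el_per_kg_milk * raw_milk,
        ),
        ProcessStep(
            "cheese_making", ["skim_milk_cheese"], ["curd", "whey"],
            heat=params.cheese_heat_per_kg_skim * skim_cheese_wet,
        ),
        ProcessStep(
            "whey_separation", ["whey"], whey_outputs,
            electricity=params.whey_sep_el_per_kg_solids * whey_dry,
            heat=params.whey_sep_heat_per_kg_solids * whey_dry,
            evaporated_water=whey_wet - whey_dry,
        ),
        # The BMS wet mix takes skim milk; its water leaves in spray-drying.
        ProcessStep(
            "wet_mix_spray_dry", ["skim_milk_bms", "oil", "wpc", "lactose_powder"],
            ["bms"],
            electricity=params.spray_dry_el_per_kg_bms * (d_smp + d_wpc + d_lac + d_oil),
            heat=params.spray_dry_heat_per_kg_bms * (d_smp + d_wpc + d_lac + d_oil),
            dedicated_to="bms",
            evaporated_water=skim_bms_wet - d_smp,
        ),
    ]
    # spray-dry input uses the liquid skim stream; swap the solids entry
    streams["bms"].components = {
        c: streams["skim_bms_solids"].components[c] + wpc_comp[c] + lac_comp[c]
        for c in COMPONENTS
    }
    streams["bms"].components["fat"] += d_oil
    del streams["skim_bms_solids"]

    tree = ProcessTree(streams=streams, steps=steps, raw_milk_input=raw_milk)
    tree.check_conservation()
    return tree


def _basis_property(stream: CoProductStream, basis: str) -> float:
    if basis == "dry_mass":
        return stream.dry_mass
    if basis == "fat_protein":
        return stream.fat + stream.protein
    if basis == "energy":
        return stream.energy
    if basis == "economic":
        return stream.price * stream.dry_mass
    raise ValueError(f"unknown allocation basis {basis!r}")


def allocation_factors(
    streams: Iterable[CoProductStream], basis: str
) -> dict[str, float]:
    """Fractions of a shared burden assigned to each co-product stream.

    ``fraction_i = p_i / sum_j p_j`` where ``p`` is the basis property
    (dry mass, fat+protein, energy content, or price x dry mass).
    """
    streams = list(streams)
    props = {s.name: max(0.0, _basis_property(s, basis)) for s in streams}
    total = sum(props.values())
    if total <= 0:
        raise ValueError(f"allocation undefined: all streams have zero {basis}")
    return {name: p / total for name, p in props.items()}


@dataclass(frozen=True)
class AllocatedBurden:
    raw_milk_kg: float
    electricity_mj: float
    heat_mj: float


def allocated_burden(tree: ProcessTree, basis: str = "dry_mass") -> AllocatedBurden:
    """Raw milk and process energy carried by the BMS through the tree.

    Step burdens split over step outputs by the allocation basis and
    propagate multiplicatively; energy of steps dedicated to the BMS is
    assigned in full to BMS-destined outputs.  Returns totals over all
    BMS-destined terminal streams.
    """
    carried: dict[str, list[float]] = {
        name: [0.0, 0.0, 0.0] for name in tree.streams
    }
    if "raw_milk" in tree.streams:
        carried["raw_milk"][0] = tree.streams["raw_milk"].wet_mass

    consumed: set[str] = set()
    for step in tree.steps:
        inflow = [0.0, 0.0, 0.0]
        for name in step.inputs:
            if name not in tree.streams:
                raise ValueError(f"{step.name}: dangling input stream {name!r}")
            for i in range(3):
                inflow[i] += carried[name][i]
            consumed.add(name)
        outputs = [tree.streams[n] for n in step.outputs]
        energy = [0.0, step.electricity, step.heat]
        if outputs and all(_basis_property(o, basis) <= 0 for o in outputs):
            if max(inflow) <= DRY_TOL and max(energy) <= DRY_TOL:
                continue  # degenerate empty branch (e.g. dairy-free recipe)
        factors = allocation_factors(outputs, basis) if outputs else {}
        if step.dedicated_to == "bms":
            bms_out = [o for o in outputs if o.destined_for_bms]
            sub = allocation_factors(bms_out, basis) if bms_out else {}
            for name, f in factors.items():
                for i in range(3):
                    carried[name][i] += inflow[i] * f
            for name, f in sub.items():
                for i in (1, 2):
                    carried[name][i] += energy[i] * f
        else:
            for name, f in factors.items():
                for i in range(3):
                    carried[name][i] += (inflow[i] + energy[i]) * f

    totals = [0.0, 0.0, 0.0]
    for s in tree.terminal_streams():
        if s.destined_for_bms:
            for i in range(3):
                totals[i] += carried[s.name][i]
    return AllocatedBurden(*totals)
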
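"""Carbon footprint of breastfeeding the equivalent of 1 kg BMS (CFP_BF).

Breastfeeding mothers need ~500 kcal of extra food per day, assumed to
come from the national average diet; 1 kg of powder corresponds to
385 MJ / 21 kg = 18.33 MJ of extra maternal food, reduced by the BMS
wasted after preparation (waste lowers the amount of breastmilk that is
equivalent to a kg of powder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .consumption import _ef_scale, stove_delivered_ef
from .production import _m
from .types import (
    CountryScenario,
    Diet,
    FeedingParameters,
    GWPSet,
    REFERENCE_GWP,
    StageBreakdown,
    StoveFuel,
)

#: MJ of cooking heat per kg of food consumed (rice-cooking reference value).
COOKING_HEAT_PER_KG = 1.3

__all__ = [
    "BreastfeedingResult",
    "ComparisonResult",
    "equivalent_food_energy",
    "diet_cfp",
    "cfp_breastfeeding",
    "compare",
    "waste_sweep",
]


@dataclass(frozen=True)
class BreastfeedingResult:
    per_mj_plant: float
    per_mj_animal: float
    per_mj_cooking: float
    per_mj_luc: float
    per_kg_bms: float
    luc_included: bool
    gwp: str

    @property
    def per_mj_total(self) -> float:
        """Production + cooking per MJ consumed (LUC reported separately)."""
        return self.per_mj_plant + self.per_mj_animal + self.per_mj_cooking


@dataclass(frozen=True)
class ComparisonResult:
    difference: float  # CFP_Cons - CFP_BF, kg CO2e per kg BMS
    ratio: float  # CFP_BF / CFP_Cons
    exceedance_probability: Optional[float] = None  # P(difference > 0)


def equivalent_food_energy(p: FeedingParameters = FeedingParameters()) -> float:
    """Extra maternal food energy equivalent to 1 kg of BMS powder, MJ.

    Unrounded (385/21 = 18.33 MJ by default); table output rounds to the
    nearest MJ.
    """
    if p.period_bms_mass <= 0:
        raise ValueError("period BMS mass must be positive")
    return p.period_total_food / p.period_bms_mass


def diet_cfp(
    diet: Diet,
    stove_profile: Sequence[StoveFuel],
    gwp: GWPSet = REFERENCE_GWP,
    include_luc: bool = False,
    luc_factors: Optional[Mapping[str, float]] = None,
    mult: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Per-MJ-consumed footprint of a diet, split plant/animal/cooking/LUC.

    Production terms are inflated by household food waste; cooking uses
    1.3 MJ of delivered heat per kg of food through the same stove mix as
    BMS preparation.
    """
    issues = diet.issues()
    if issues:
        raise ValueError("invalid diet: " + "; ".join(str(i) for i in issues))
    ef_delivered = stove_delivered_ef(stove_profile, gwp, mult) if stove_profile else 0.0
    plant = animal = cooking = luc = 0.0
    for item in diet.items:
        ef = (
            item.ef_per_mj
            * _ef_scale(item.gas_shares, gwp)
            * _m(mult, f"diet_ef:{item.name}")
        )
        production = item.energy_share * ef / (1.0 - item.household_waste)
        if item.category == "plant":
            plant += production
        else:
            animal += production
        cooking += (
            item.energy_share
            * item.mass_per_mj
            * COOKING_HEAT_PER_KG
            * _m(mult, f"cooking_energy:{item.name}")
            * ef_delivered
        )
        if include_luc and item.luc_commodity and luc_factors:
            luc += (
                item.energy_share
                * item.mass_per_mj
                * luc_factors.get(item.luc_commodity, 0.0)
            )
    return {"plant": plant, "animal": animal, "cooking": cooking, "luc": luc}


def cfp_breastfeeding(
    scenario: CountryScenario,
    gwp: GWPSet = REFERENCE_GWP,
    include_luc: bool = False,
    feeding: FeedingParameters = FeedingParameters(),
    mult: Optional[Mapping[str, float]] = None,
) -> BreastfeedingResult:
    """CFP of breastfeeding equivalent to 1 kg BMS in a consumption country."""
    if not scenario.has_role("consumption"):
        raise ValueError(f"scenario {scenario.name!r} has no consumption role")
    per_mj = diet_cfp(
        scenario.diet, scenario.stove_profile, gwp,
        include_luc=include_luc, luc_factors=scenario.luc_factors, mult=mult,
    )
    energy = equivalent_food_energy(feeding)
    total = per_mj["plant"] + per_mj["animal"] + per_mj["cooking"]
    if include_luc:
        total += per_mj["luc"]
    per_kg = total * energy * (1.0 - scenario.bms_waste_fraction * _m(mult, "bms_waste"))
    return BreastfeedingResult(
        per_mj_plant=per_mj["plant"],
        per_mj_animal=per_mj["animal"],
        per_mj_cooking=per_mj["cooking"],
        per_mj_luc=per_mj["luc"],
        per_kg_bms=per_kg,
        luc_included=include_luc,
        gwp=gwp.label,
    )


def compare(
    cons: StageBreakdown,
    bf: BreastfeedingResult,
    gwp: Optional[GWPSet] = None,
    exceedance_probability: Optional[float] = None,
) -> ComparisonResult:
    """CFP_Cons minus CFP_BF on unrounded totals; positive favours breastfeeding."""
    if gwp is not None and bf.gwp != gwp.label:
        raise ValueError(f"GWP sets differ: {bf.gwp} vs {gwp.label}")
    difference = cons.total - bf.per_kg_bms
    ratio = bf.per_kg_bms / cons.total if cons.total > 0 else float("nan")
    return ComparisonResult(
        difference=difference, ratio=ratio,
        exceedance_probability=exceedance_probability,
    )


def waste_sweep(
    scenario: CountryScenario,
    cons: StageBreakdown,
    waste_grid: Optional[Sequence[float]] = None,
    gwp: GWPSet = REFERENCE_GWP,
    feeding: FeedingParameters = FeedingParameters(),
) -> list[dict[str, float]]:
    """CFP_BF vs CFP_Cons across consumer-stage BMS waste assumptions.

    CFP_Cons does not depend on the waste fraction (the functional unit
    is the kg of powder, wasted or not); CFP_BF falls linearly with it.
    """
    if waste_grid is None:
        waste_grid = np.linspace(0.0, 0.5, 26)
    rows = []
    for w in waste_grid:
        s = scenario.with_updates(bms_waste_fraction=float(w))
        bf = cfp_breastfeeding(s, gwp, feeding=feeding)
        rows.append(
            {
                "bms_waste_fraction": float(w),
                "cfp_bf": bf.per_kg_bms,
                "cfp_cons": cons.total,
                "ratio": bf.per_kg_bms / cons.total,
                "difference": cons.total - bf.per_kg_bms,
            }
        )
    return rows
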
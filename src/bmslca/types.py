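"""Shared domain types for the BMS carbon-footprint model.

All footprints are expressed in kg CO2-equivalents (GWP100).  Scenario
objects are plain dataclasses validated by :func:`validate_scenario`
rather than at construction, so that deliberately broken scenarios can be
built in tests and reported on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

MIX_TOL = 1e-9

__all__ = [
    "EmissionFactor",
    "GWPSet",
    "GWP_SETS",
    "DistributionSpec",
    "DietItem",
    "Diet",
    "TransportLeg",
    "StoveFuel",
    "FeedingParameters",
    "CountryScenario",
    "StageBreakdown",
    "ValidationIssue",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, halves away from zero.

    This is the rounding used for all table-style reporting (two
    significant figures, matching the source tables); arithmetic is always
    done on unrounded values.
    """
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    q = Decimal(10) ** (exponent - sig + 1)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GWPSet:
    """A characterisation-factor set converting CH4 and N2O to CO2e."""

    label: str
    ch4: float  # kg CO2e per kg CH4
    n2o: float  # kg CO2e per kg N2O

    def __post_init__(self) -> None:
        if self.ch4 <= 0 or self.n2o <= 0:
            raise ValueError("GWP factors must be positive")


#: Packaged characterisation sets.  AR4 is the reference set under which all
#: emission factors in the packaged configurations are expressed.
GWP_SETS: Mapping[str, GWPSet] = {
    "AR4": GWPSet("AR4", ch4=25.0, n2o=298.0),
    "AR5": GWPSet("AR5", ch4=28.0, n2o=265.0),
    "AR5F": GWPSet("AR5F", ch4=34.0, n2o=298.0),
}

REFERENCE_GWP = GWP_SETS["AR4"]


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty grammar for Monte Carlo parameters.

    ``normal_cv`` / ``lognormal_cv`` are parameterised by a coefficient of
    variation in percent around the point value.  ``triangular`` has its
    mode at the point value and support ``[point*(1+rel_min),
    point*(1+rel_max)]``.  ``recentre`` rescales triangular draws so the
    ensemble mean equals the point value (used for strongly asymmetric
    ranges where the point value is the central estimate to be preserved).
    """

    family: str = "point"  # point | normal_cv | lognormal_cv | triangular
    cv: float = 0.0  # percent
    rel_min: float = 0.0
    rel_max: float = 0.0
    recentre: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("point", "normal_cv", "lognormal_cv", "triangular"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not (self.rel_min <= 0.0 <= self.rel_max):
            raise ValueError("triangular offsets must satisfy rel_min <= 0 <= rel_max")


@dataclass(frozen=True)
class EmissionFactor:
    """An emission factor in kg CO2e per declared unit under AR4 GWP100.

    ``gas_shares`` apportion the CO2e among CO2, CH4 and N2O and drive
    re-characterisation to other GWP sets.
    """

    value: float
    unit: str = "kg product"
    gas_shares: Mapping[str, float] = field(
        default_factory=lambda: {"co2": 1.0, "ch4": 0.0, "n2o": 0.0}
    )
    distribution: Optional[DistributionSpec] = None

    def issues(self, path: str = "emission_factor") -> list["ValidationIssue"]:
        out = []
        if self.value < 0:
            out.append(ValidationIssue(path + ".value", "negative emission factor"))
        total = sum(self.gas_shares.values())
        if abs(total - 1.0) > MIX_TOL:
            out.append(
                ValidationIssue(path + ".gas_shares", f"shares sum to {total:.12g}, not 1")
            )
        for gas, s in self.gas_shares.items():
            if not (0.0 <= s <= 1.0):
                out.append(ValidationIssue(f"{path}.gas_shares[{gas}]", "share outside [0, 1]"))
        return out

    def characterise(self, gwp: GWPSet, reference: GWPSet = REFERENCE_GWP) -> float:
        """Value of this factor under another GWP set.

        The CO2e attributed to each gas is scaled by the ratio of the new
        to the reference characterisation factor (CO2 is always 1).
        """
        scale = (
            self.gas_shares.get("co2", 0.0)
            + self.gas_shares.get("ch4", 0.0) * gwp.ch4 / reference.ch4
            + self.gas_shares.get("n2o", 0.0) * gwp.n2o / reference.n2o
        )
        return self.value * scale


@dataclass(frozen=True)
class DietItem:
    name: str
    category: str  # plant | animal
    energy_share: float  # share of dietary energy
    ef_per_mj: float  # kg CO2e per MJ food produced and distributed
    household_waste: float  # fraction of purchased food wasted at home
    mass_per_mj: float  # kg food (as eaten) per MJ
    luc_commodity: Optional[str] = None
    ef_distribution: Optional[DistributionSpec] = None
    gas_shares: Mapping[str, float] = field(
        default_factory=lambda: {"co2": 1.0, "ch4": 0.0, "n2o": 0.0}
    )


@dataclass(frozen=True)
class Diet:
    items: Sequence[DietItem]

    def issues(self, path: str = "diet") -> list["ValidationIssue"]:
        out: list[ValidationIssue] = []
        if not self.items:  # production-only scenarios carry no diet
            return out
        total = sum(i.energy_share for i in self.items)
        if abs(total - 1.0) > MIX_TOL:
            out.append(ValidationIssue(path + ".items", f"energy shares sum to {total:.12g}"))
        for i in self.items:
            p = f"{path}.items[{i.name}]"
            if i.ef_per_mj < 0:
                out.append(ValidationIssue(p + ".ef_per_mj", "negative"))
            if not (0.0 <= i.household_waste < 1.0):
                out.append(ValidationIssue(p + ".household_waste", "outside [0, 1)"))
            if i.category not in ("plant", "animal"):
                out.append(ValidationIssue(p + ".category", f"unknown category {i.category!r}"))
            if i.mass_per_mj < 0:
                out.append(ValidationIssue(p + ".mass_per_mj", "negative"))
            if abs(sum(i.gas_shares.values()) - 1.0) > MIX_TOL:
                out.append(ValidationIssue(p + ".gas_shares", "do not sum to 1"))
        return out


@dataclass(frozen=True)
class TransportLeg:
    mode: str  # road | road_refrigerated | sea | sea_refrigerated
    distance_km: float
    ef_per_tkm: float  # kg CO2e per tonne-km
    refrigerated: bool = False
    cargo: str = "bms"  # bms | raw_milk | whey | dry_ingredients | oils | packaging


@dataclass(frozen=True)
class StoveFuel:
    fuel: str
    share: float
    ef_per_mj_fuel: float  # kg CO2e per MJ of fuel energy
    efficiency: float  # delivered heat / fuel energy, in (0, 1]
    gas_shares: Mapping[str, float] = field(
        default_factory=lambda: {"co2": 1.0, "ch4": 0.0, "n2o": 0.0}
    )


@dataclass(frozen=True)
class FeedingParameters:
    """Feeding-plan constants for an exclusively formula-fed infant, 0-6 mo."""

    infant_energy_per_day: float = 2480.0  # kJ
    feeds_per_day: int = 6
    serving_mass: float = 18.6  # g powder per serving
    bms_energy_density: float = 21.7  # kJ per g powder
    water_per_bottle: float = 0.13  # L heated per serving
    sterilisation_water: float = 5.0  # L boiled per sterilisation batch
    bottles_per_batch: int = 6
    bottles_per_period: int = 6  # bottles manufactured per feeding period
    period_days: int = 184  # six months
    maternal_extra_energy: float = 500.0  # kcal/day extra while breastfeeding
    period_total_food: float = 385.0  # MJ extra maternal food over the period
    period_bms_mass: float = 21.0  # kg powder consumed over the period

    def issues(self, path: str = "feeding") -> list["ValidationIssue"]:
        out = []
        for name in (
            "infant_energy_per_day", "feeds_per_day", "serving_mass",
            "bms_energy_density", "water_per_bottle", "sterilisation_water",
            "bottles_per_batch", "bottles_per_period", "period_days",
            "maternal_extra_energy", "period_total_food", "period_bms_mass",
        ):
            if getattr(self, name) <= 0:
                out.append(ValidationIssue(f"{path}.{name}", "must be strictly positive"))
        per_serving = self.infant_energy_per_day / self.feeds_per_day
        implied = self.serving_mass * self.bms_energy_density
        # 2480/6 = 413 kJ vs the printed 403 kJ / 18.6 g: the serving mass is
        # authoritative, so allow a 3% slack on this consistency check.
        if abs(implied - per_serving) / per_serving > 0.03:
            out.append(
                ValidationIssue(
                    f"{path}.serving_mass",
                    f"serving energy {implied:.0f} kJ deviates >3% from "
                    f"{per_serving:.0f} kJ per feed",
                )
            )
        return out


@dataclass(frozen=True)
class CountryScenario:
    """All country-specific parameters for BMS production and/or consumption."""

    name: str
    role: str  # production | consumption | both
    # --- production side ---
    raw_milk_ef: EmissionFactor = field(
        default_factory=lambda: EmissionFactor(0.0, "kg ECM raw milk")
    )
    milk_density: float = 1.035  # kg per L
    milk_meat_allocation: float = 0.90  # farm-level share of burden on milk
    electricity_ef: EmissionFactor = field(
        default_factory=lambda: EmissionFactor(0.0, "MJ electricity")
    )
    heat_ef: EmissionFactor = field(default_factory=lambda: EmissionFactor(0.0, "MJ heat"))
    oil_blend: Mapping[str, float] = field(default_factory=dict)
    oil_efs: Mapping[str, EmissionFactor] = field(default_factory=dict)
    oil_transport: Sequence[TransportLeg] = field(default_factory=tuple)
    packaging_mix: Mapping[str, float] = field(default_factory=dict)  # tin_can share etc.
    packaging_efs: Mapping[str, EmissionFactor] = field(default_factory=dict)
    packaging_masses: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    transport_legs: Sequence[TransportLeg] = field(default_factory=tuple)
    chain_waste: Sequence[float] = field(default_factory=tuple)  # production-chain stages
    # --- consumption side ---
    production_pairing: Optional[str] = None
    retail_transport: Sequence[TransportLeg] = field(default_factory=tuple)
    stove_profile: Sequence[StoveFuel] = field(default_factory=tuple)
    bottle_ef: float = 0.0  # kg CO2e per bottle manufactured
    sterilisation_boil_margin: float = 0.0  # MJ delivered per batch beyond heating to boil
    steam_sterilisation_scale: float = 0.15  # steam-steriliser CFP relative to stovetop
    diet: Diet = field(default_factory=lambda: Diet(items=()))
    bms_waste_fraction: float = 0.0  # consumer-stage BMS waste, in [0, 1)
    luc_factors: Mapping[str, float] = field(default_factory=dict)  # kg CO2e per kg commodity
    production_addons: Mapping[str, float] = field(default_factory=dict)  # kg CO2e per kg BMS
    calibrated: Mapping[str, bool] = field(default_factory=dict)

    def has_role(self, role: str) -> bool:
        return self.role == role or self.role == "both"

    def with_updates(self, **kwargs) -> "CountryScenario":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ValidationIssue:
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


@dataclass
class StageBreakdown:
    """Per-life-cycle-stage footprint contributions, kg CO2e per kg BMS."""

    stages: dict[str, float]
    label: str = ""

    @property
    def total(self) -> float:
        return float(sum(self.stages.values()))

    def __getitem__(self, stage: str) -> float:
        return self.stages[stage]

    def rounded(self, sig: int = 2) -> dict[str, float]:
        out = {k: round_sig(v, sig) for k, v in self.stages.items()}
        out["total"] = round_sig(self.total, sig)
        return out

    def check(self) -> None:
        for k, v in self.stages.items():
            if v < -MIX_TOL:
                raise ValueError(f"negative stage {k}: {v}")
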
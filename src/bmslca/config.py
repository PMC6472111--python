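"""Scenario configuration: packaged country defaults, YAML I/O, validation.

One YAML document per country under ``bmslca/data/countries/``.  Values
carry their units in-field; entries flagged ``calibrated: true`` were
fitted once against the published stage totals rather than taken from a
printed table.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .types import (
    CountryScenario,
    Diet,
    DietItem,
    DistributionSpec,
    EmissionFactor,
    FeedingParameters,
    MIX_TOL,
    StoveFuel,
    TransportLeg,
    ValidationIssue,
)

__all__ = [
    "default_scenarios",
    "load_scenario",
    "load_scenario_file",
    "scenario_to_dict",
    "save_scenario",
    "validate_scenario",
    "validation_report",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A packaged or user configuration file is malformed."""


def _dist_from_dict(d: Optional[Mapping]) -> Optional[DistributionSpec]:
    if not d:
        return None
    return DistributionSpec(
        family=d.get("family", "point"),
        cv=float(d.get("cv", 0.0)),
        rel_min=float(d.get("rel_min", 0.0)),
        rel_max=float(d.get("rel_max", 0.0)),
        recentre=bool(d.get("recentre", False)),
    )


def _ef_from_dict(d: Mapping, field: str) -> EmissionFactor:
    try:
        return EmissionFactor(
            value=float(d["value"]),
            unit=str(d.get("unit", "kg product")),
            gas_shares=dict(d.get("gas_shares", {"co2": 1.0})),
            distribution=_dist_from_dict(d.get("distribution")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed emission factor at {field!r}: {exc}") from exc


def _leg_from_dict(d: Mapping) -> TransportLeg:
    return TransportLeg(
        mode=d.get("mode", "road"),
        distance_km=float(d["distance_km"]),
        ef_per_tkm=float(d["ef_per_tkm"]),
        refrigerated=bool(d.get("refrigerated", False)),
        cargo=d.get("cargo", "bms"),
    )


def load_scenario(doc: Mapping) -> CountryScenario:
    """Build a :class:`CountryScenario` from a parsed YAML document."""
    try:
        name = doc["name"]
        role = doc["role"]
    except KeyError as exc:
        raise ConfigurationError(f"missing required field {exc}") from exc
    kwargs = dict(name=name, role=role)
    if "raw_milk_ef" in doc:
        kwargs["raw_milk_ef"] = _ef_from_dict(doc["raw_milk_ef"], "raw_milk_ef")
    for scalar in ("milk_density", "milk_meat_allocation", "bms_waste_fraction",
                   "bottle_ef", "sterilisation_boil_margin", "steam_sterilisation_scale"):
        if scalar in doc:
            kwargs[scalar] = float(doc[scalar])
    for ef_field in ("electricity_ef", "heat_ef"):
        if ef_field in doc:
            kwargs[ef_field] = _ef_from_dict(doc[ef_field], ef_field)
    if "oil_blend" in doc:
        kwargs["oil_blend"] = {k: float(v) for k, v in doc["oil_blend"].items()}
    if "oil_efs" in doc:
        kwargs["oil_efs"] = {
            k: _ef_from_dict(v, f"oil_efs.{k}") for k, v in doc["oil_efs"].items()
        }
    if "oil_transport" in doc:
        kwargs["oil_transport"] = tuple(_leg_from_dict(d) for d in doc["oil_transport"])
    if "packaging_mix" in doc:
        kwargs["packaging_mix"] = {k: float(v) for k, v in doc["packaging_mix"].items()}
    if "packaging_efs" in doc:
        kwargs["packaging_efs"] = {
            k: _ef_from_dict(v, f"packaging_efs.{k}") for k, v in doc["packaging_efs"].items()
        }
    if "packaging_masses" in doc:
        kwargs["packaging_masses"] = {
            k: {m: float(x) for m, x in v.items()} for k, v in doc["packaging_masses"].items()
        }
    if "transport_legs" in doc:
        kwargs["transport_legs"] = tuple(_leg_from_dict(d) for d in doc["transport_legs"])
    if "retail_transport" in doc:
        kwargs["retail_transport"] = tuple(_leg_from_dict(d) for d in doc["retail_transport"])
    if "chain_waste" in doc:
        kwargs["chain_waste"] = tuple(float(w) for w in doc["chain_waste"])
    if "production_pairing" in doc:
        kwargs["production_pairing"] = doc["production_pairing"]
    if "stove_profile" in doc:
        kwargs["stove_profile"] = tuple(
            StoveFuel(
                fuel=d["fuel"],
                share=float(d["share"]),
                ef_per_mj_fuel=float(d["ef_per_mj_fuel"]),
                efficiency=float(d["efficiency"]),
                gas_shares=dict(d.get("gas_shares", {"co2": 1.0})),
            )
            for d in doc["stove_profile"]
        )
    if "diet" in doc:
        kwargs["diet"] = Diet(
            items=tuple(
                DietItem(
                    name=d["name"],
                    category=d["category"],
                    energy_share=float(d["energy_share"]),
                    ef_per_mj=float(d["ef_per_mj"]),
                    household_waste=float(d["household_waste"]),
                    mass_per_mj=float(d["mass_per_mj"]),
                    luc_commodity=d.get("luc_commodity"),
                    ef_distribution=_dist_from_dict(d.get("ef_distribution")),
                    gas_shares=dict(d.get("gas_shares", {"co2": 1.0})),
                )
                for d in doc["diet"]["items"]
            )
        )
    if "luc_factors" in doc:
        kwargs["luc_factors"] = {k: float(v) for k, v in doc["luc_factors"].items()}
    if "calibrated" in doc:
        kwargs["calibrated"] = dict(doc["calibrated"])
    return CountryScenario(**kwargs)


def load_scenario_file(path: str | Path) -> CountryScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: not a mapping document")
    return load_scenario(doc)


def _dist_to_dict(d: Optional[DistributionSpec]) -> Optional[dict]:
    if d is None:
        return None
    out = {"family": d.family}
    if d.cv:
        out["cv"] = d.cv
    if d.rel_min or d.rel_max:
        out["rel_min"] = d.rel_min
        out["rel_max"] = d.rel_max
    if d.recentre:
        out["recentre"] = True
    return out


def _ef_to_dict(ef: EmissionFactor) -> dict:
    out = {"value": ef.value, "unit": ef.unit, "gas_shares": dict(ef.gas_shares)}
    if ef.distribution is not None:
        out["distribution"] = _dist_to_dict(ef.distribution)
    return out


def _leg_to_dict(leg: TransportLeg) -> dict:
    return {
        "mode": leg.mode, "distance_km": leg.distance_km, "ef_per_tkm": leg.ef_per_tkm,
        "refrigerated": leg.refrigerated, "cargo": leg.cargo,
    }


def scenario_to_dict(s: CountryScenario) -> dict:
    doc: dict = {"name": s.name, "role": s.role}
    doc["raw_milk_ef"] = _ef_to_dict(s.raw_milk_ef)
    doc["milk_density"] = s.milk_density
    doc["milk_meat_allocation"] = s.milk_meat_allocation
    doc["electricity_ef"] = _ef_to_dict(s.electricity_ef)
    doc["heat_ef"] = _ef_to_dict(s.heat_ef)
    if s.oil_blend:
        doc["oil_blend"] = dict(s.oil_blend)
        doc["oil_efs"] = {k: _ef_to_dict(v) for k, v in s.oil_efs.items()}
        doc["oil_transport"] = [_leg_to_dict(l) for l in s.oil_transport]
    if s.packaging_mix:
        doc["packaging_mix"] = dict(s.packaging_mix)
        doc["packaging_efs"] = {k: _ef_to_dict(v) for k, v in s.packaging_efs.items()}
        doc["packaging_masses"] = {k: dict(v) for k, v in s.packaging_masses.items()}
    if s.transport_legs:
        doc["transport_legs"] = [_leg_to_dict(l) for l in s.transport_legs]
    if s.chain_waste:
        doc["chain_waste"] = list(s.chain_waste)
    if s.production_pairing:
        doc["production_pairing"] = s.production_pairing
    if s.retail_transport:
        doc["retail_transport"] = [_leg_to_dict(l) for l in s.retail_transport]
    if s.stove_profile:
        doc["stove_profile"] = [
            {
                "fuel": f.fuel, "share": f.share, "ef_per_mj_fuel": f.ef_per_mj_fuel,
                "efficiency": f.efficiency, "gas_shares": dict(f.gas_shares),
            }
            for f in s.stove_profile
        ]
    if s.diet.items:
        doc["diet"] = {
            "items": [
                {
                    "name": i.name, "category": i.category, "energy_share": i.energy_share,
                    "ef_per_mj": i.ef_per_mj, "household_waste": i.household_waste,
                    "mass_per_mj": i.mass_per_mj, "gas_shares": dict(i.gas_shares),
                    **({"luc_commodity": i.luc_commodity} if i.luc_commodity else {}),
                    **(
                        {"ef_distribution": _dist_to_dict(i.ef_distribution)}
                        if i.ef_distribution else {}
                    ),
                }
                for i in s.diet.items
            ]
        }
    if s.luc_factors:
        doc["luc_factors"] = dict(s.luc_factors)
    doc["bottle_ef"] = s.bottle_ef
    doc["bms_waste_fraction"] = s.bms_waste_fraction
    doc["sterilisation_boil_margin"] = s.sterilisation_boil_margin
    doc["steam_sterilisation_scale"] = s.steam_sterilisation_scale
    if s.calibrated:
        doc["calibrated"] = dict(s.calibrated)
    return doc


def save_scenario(s: CountryScenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(s), fh, sort_keys=False)


@lru_cache(maxsize=1)
def _packaged_scenarios() -> dict[str, CountryScenario]:
    out: dict[str, CountryScenario] = {}
    root = resources.files("bmslca.data").joinpath("countries")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if not entry.name.endswith(".yaml"):
            continue
        doc = yaml.safe_load(entry.read_text())
        try:
            scenario = load_scenario(doc)
        except ConfigurationError as exc:
            raise ConfigurationError(f"{entry.name}: {exc}") from exc
        issues = validate_scenario(scenario)
        if issues:
            raise ConfigurationError(
                f"{entry.name}: invalid packaged scenario: "
                + "; ".join(str(i) for i in issues)
            )
        out[scenario.name] = scenario
    return out


def default_scenarios(config_dir: str | Path | None = None) -> dict[str, CountryScenario]:
    """Packaged default scenarios keyed by country name.

    Production: New Zealand, United States, Brazil, France.  Consumption:
    United Kingdom (paired with France), China (New Zealand), Brazil
    (itself; role ``both``) and Vietnam (France).
    """
    if config_dir is None:
        return dict(_packaged_scenarios())
    out = {}
    for path in sorted(Path(config_dir).glob("*.yaml")):
        s = load_scenario_file(path)
        out[s.name] = s
    return out


def _check_mixture(name: str, mapping, issues: list[ValidationIssue]) -> None:
    if not mapping:
        return
    total = sum(mapping.values())
    if abs(total - 1.0) > MIX_TOL:
        issues.append(ValidationIssue(name, f"shares sum to {total:.12g}, not 1"))
    for k, v in mapping.items():
        if not (0.0 <= v <= 1.0):
            issues.append(ValidationIssue(f"{name}[{k}]", "share outside [0, 1]"))


def validate_scenario(s: CountryScenario) -> list[ValidationIssue]:
    """All invariant violations in a scenario; empty list iff valid."""
    issues: list[ValidationIssue] = []
    if s.role not in ("production", "consumption", "both"):
        issues.append(ValidationIssue("role", f"unknown role {s.role!r}"))
    issues += s.raw_milk_ef.issues("raw_milk_ef")
    issues += s.electricity_ef.issues("electricity_ef")
    issues += s.heat_ef.issues("heat_ef")
    if s.milk_density <= 0:
        issues.append(ValidationIssue("milk_density", "must be positive"))
    if not (0.0 < s.milk_meat_allocation <= 1.0):
        issues.append(ValidationIssue("milk_meat_allocation", "outside (0, 1]"))
    _check_mixture("oil_blend", s.oil_blend, issues)
    for k, ef in s.oil_efs.items():
        issues += ef.issues(f"oil_efs[{k}]")
    _check_mixture("packaging_mix", s.packaging_mix, issues)
    for k, ef in s.packaging_efs.items():
        issues += ef.issues(f"packaging_efs[{k}]")
    for group, legs in (("transport_legs", s.transport_legs),
                        ("oil_transport", s.oil_transport),
                        ("retail_transport", s.retail_transport)):
        for i, leg in enumerate(legs):
            if leg.distance_km < 0:
                issues.append(ValidationIssue(f"{group}[{i}].distance_km", "negative"))
            if leg.ef_per_tkm < 0:
                issues.append(ValidationIssue(f"{group}[{i}].ef_per_tkm", "negative"))
    for i, w in enumerate(s.chain_waste):
        if not (0.0 <= w < 1.0):
            issues.append(ValidationIssue(f"chain_waste[{i}]", "outside [0, 1)"))
    if s.stove_profile:
        _check_mixture("stove_profile", {f.fuel: f.share for f in s.stove_profile}, issues)
        for f in s.stove_profile:
            if not (0.0 < f.efficiency <= 1.0):
                issues.append(
                    ValidationIssue(f"stove_profile[{f.fuel}].efficiency", "outside (0, 1]")
                )
            if f.ef_per_mj_fuel < 0:
                issues.append(ValidationIssue(f"stove_profile[{f.fuel}].ef_per_mj_fuel", "negative"))
            total = sum(f.gas_shares.values())
            if abs(total - 1.0) > MIX_TOL:
                issues.append(
                    ValidationIssue(f"stove_profile[{f.fuel}].gas_shares", "do not sum to 1")
                )
    issues += s.diet.issues("diet")
    if not (0.0 <= s.bms_waste_fraction < 1.0):
        issues.append(ValidationIssue("bms_waste_fraction", "outside [0, 1)"))
    for k, v in s.luc_factors.items():
        if v < 0:
            issues.append(ValidationIssue(f"luc_factors[{k}]", "negative"))
    if s.bottle_ef < 0:
        issues.append(ValidationIssue("bottle_ef", "negative"))
    return issues


def validation_report(s: CountryScenario, fmt: str = "text"):
    """Human- or machine-readable validation report for a scenario."""
    issues = validate_scenario(s)
    if fmt == "json":
        return {
            "scenario": s.name,
            "valid": not issues,
            "issues": [{"path": i.path, "message": i.message} for i in issues],
        }
    if not issues:
        return f"{s.name}: valid"
    lines = [f"{s.name}: {len(issues)} issue(s)"] + [f"  - {i}" for i in issues]
    return "\n".join(lines)
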
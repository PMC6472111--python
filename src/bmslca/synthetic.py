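"""Synthetic scenario generator for property-based testing.

Generates structurally valid country scenarios whose emission factors
fall within three times the range spanned by the packaged defaults, with
all mixtures renormalised to one.  Deterministic for a fixed seed; the
scenarios exercise the pipeline's invariants, not any real country.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CountryScenario,
    Diet,
    DietItem,
    DistributionSpec,
    EmissionFactor,
    StoveFuel,
    TransportLeg,
)

__all__ = ["generate_synthetic_scenario", "SYNTHETIC_BOUNDS"]

#: (low, high) envelopes: one third to three times the packaged ranges.
SYNTHETIC_BOUNDS = {
    "raw_milk_ef": (0.73 / 3.0, 1.28 * 3.0),
    "electricity_ef": (0.0069 / 3.0, 0.138 * 3.0),
    "heat_ef": (0.0625 / 3.0, 0.0625 * 3.0),
    "oil_ef": (1.3 / 3.0, 2.5 * 3.0),
    "packaging_ef": (0.70 / 3.0, 3.52 * 3.0),
    "transport_ef": (0.011 / 3.0, 0.225 * 3.0),
    "stove_fuel_ef": (0.005 / 3.0, 0.175 * 3.0),
    "food_ef_per_mj": (0.01, 6.0),
}

_OILS = ("palm", "soybean", "rapeseed", "sunflower")
_FOODS = ("cereal", "roots", "vegetables", "fruit", "pulses",
          "dairy", "red meat", "poultry", "fish", "eggs")


def _gas_shares(rng: np.random.Generator) -> dict[str, float]:
    shares = rng.dirichlet([4.0, 2.0, 1.0])
    return {"co2": float(shares[0]), "ch4": float(shares[1]), "n2o": float(shares[2])}


def _uniform(rng: np.random.Generator, key: str) -> float:
    lo, hi = SYNTHETIC_BOUNDS[key]
    return float(rng.uniform(lo, hi))


def generate_synthetic_scenario(seed: int, role: str = "both") -> CountryScenario:
    """A valid, random scenario; identical for identical seeds."""
    rng = np.random.default_rng(seed)

    oil_shares = rng.dirichlet(np.ones(len(_OILS)))
    oil_blend = {o: float(s) for o, s in zip(_OILS, oil_shares)}
    oil_efs = {
        o: EmissionFactor(_uniform(rng, "oil_ef"), "kg product", _gas_shares(rng),
                          DistributionSpec("lognormal_cv", cv=25.0))
        for o in _OILS
    }

    tin_share = float(rng.uniform(0.0, 1.0))
    packaging_mix = {"tin_can": tin_share, "bag_in_box": 1.0 - tin_share}
    packaging_masses = {
        "tin_can": {"steel": float(rng.uniform(0.05, 0.2))},
        "bag_in_box": {
            "paperboard": float(rng.uniform(0.02, 0.08)),
            "plastic": float(rng.uniform(0.002, 0.02)),
        },
    }
    packaging_efs = {
        m: EmissionFactor(_uniform(rng, "packaging_ef"), "kg packaging material")
        for m in ("steel", "paperboard", "plastic")
    }

    legs = tuple(
        TransportLeg(
            mode="road_refrigerated" if cargo in ("raw_milk", "whey") else "road",
            distance_km=float(rng.uniform(10.0, 500.0)),
            ef_per_tkm=_uniform(rng, "transport_ef"),
            refrigerated=cargo in ("raw_milk", "whey"),
            cargo=cargo,
        )
        for cargo in ("raw_milk", "whey", "dry_ingredients")
    )

    n_waste = int(rng.integers(0, 3))
    chain_waste = tuple(float(w) for w in rng.uniform(0.0, 0.15, size=n_waste))

    fuels = ("gas", "electricity", "solid fuel")
    stove_shares = rng.dirichlet(np.ones(len(fuels)))
    stove = tuple(
        StoveFuel(
            fuel=f, share=float(s),
            ef_per_mj_fuel=_uniform(rng, "stove_fuel_ef"),
            efficiency=float(rng.uniform(0.15, 0.95)),
            gas_shares=_gas_shares(rng),
        )
        for f, s in zip(fuels, stove_shares)
    )

    n_items = int(rng.integers(5, len(_FOODS) + 1))
    names = list(rng.choice(_FOODS, size=n_items, replace=False))
    diet_shares = rng.dirichlet(np.ones(n_items))
    items = tuple(
        DietItem(
            name=str(name),
            category="animal" if name in ("dairy", "red meat", "poultry", "fish", "eggs")
            else "plant",
            energy_share=float(s),
            ef_per_mj=float(rng.uniform(*SYNTHETIC_BOUNDS["food_ef_per_mj"])),
            household_waste=float(rng.uniform(0.0, 0.4)),
            mass_per_mj=float(rng.uniform(0.02, 1.0)),
            luc_commodity="beef" if name == "red meat" and rng.random() < 0.5 else None,
            ef_distribution=DistributionSpec("lognormal_cv", cv=45.0),
        )
        for name, s in zip(names, diet_shares)
    )

    return CountryScenario(
        name=f"synthetic-{seed}",
        role=role,
        raw_milk_ef=EmissionFactor(
            _uniform(rng, "raw_milk_ef"), "kg ECM raw milk", _gas_shares(rng),
            DistributionSpec("normal_cv", cv=20.0),
        ),
        milk_density=float(rng.uniform(1.02, 1.05)),
        milk_meat_allocation=float(rng.uniform(0.88, 0.94)),
        electricity_ef=EmissionFactor(_uniform(rng, "electricity_ef"), "MJ electricity"),
        heat_ef=EmissionFactor(_uniform(rng, "heat_ef"), "MJ heat", _gas_shares(rng)),
        oil_blend=oil_blend,
        oil_efs=oil_efs,
        oil_transport=(
            TransportLeg("sea", float(rng.uniform(500.0, 20000.0)),
                         _uniform(rng, "transport_ef") / 10.0, cargo="oils"),
        ),
        packaging_mix=packaging_mix,
        packaging_efs=packaging_efs,
        packaging_masses=packaging_masses,
        transport_legs=legs,
        chain_waste=chain_waste,
        production_pairing=None,
        retail_transport=(
            TransportLeg("road", float(rng.uniform(50.0, 2000.0)),
                         _uniform(rng, "transport_ef"), cargo="bms"),
        ),
        stove_profile=stove,
        bottle_ef=float(rng.uniform(0.05, 0.5)),
        sterilisation_boil_margin=float(rng.uniform(0.0, 0.1)),
        steam_sterilisation_scale=float(rng.uniform(0.05, 0.5)),
        diet=Diet(items=items),
        bms_waste_fraction=float(rng.uniform(0.0, 0.5)),
        luc_factors={"beef": float(rng.uniform(0.0, 30.0)),
                     "palm_oil": float(rng.uniform(0.0, 3.0)),
                     "soybean_oil": float(rng.uniform(0.0, 3.0))},
    )
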
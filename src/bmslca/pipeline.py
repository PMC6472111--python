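"""End-to-end pipeline: production -> consumption -> breastfeeding comparison.

``run_pipeline`` executes the three stages for all configured countries
and returns a bundle of data frames mirroring the published result
tables, plus the comparison figure series; a manifest records everything
needed to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .breastfeeding import cfp_breastfeeding, compare, equivalent_food_energy, waste_sweep
from .config import default_scenarios, scenario_to_dict
from .consumption import cfp_consumption
from .montecarlo import run_comparison_mc, run_production_mc
from .production import cfp_production
from .recipe import BASELINE_RECIPE
from .types import CountryScenario, GWP_SETS, round_sig
from .variants import apply_variant

__all__ = ["RunManifest", "run_pipeline"]

PRODUCTION_STAGES = ["raw_milk", "vegetable_oils", "processing", "packaging", "transport"]
CONSUMPTION_STAGES = ["bms_production", "sterilisation", "preparation", "transport",
                      "bottle_production"]

#: Fig-4 variant set: default, alternative allocation, and both without
#: bottle sterilisation.
FIG4_VARIANTS = (
    ("default", "dry_mass", "stovetop"),
    ("fat_protein", "fat_protein", "stovetop"),
    ("default_no_sterilisation", "dry_mass", "none"),
    ("fat_protein_no_sterilisation", "fat_protein", "none"),
)


@dataclass
class RunManifest:
    seed: int = 0
    n: int = 10_000
    gwp: str = "AR4"
    basis: str = "dry_mass"
    sterilisation_mode: str = "stovetop"
    countries: Optional[list[str]] = None  # None = all configured
    config_dir: Optional[str] = None  # None = packaged defaults
    switches: list[str] = field(default_factory=list)
    include_luc: bool = False
    version: str = __version__
    timestamp: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self, scenarios: dict[str, CountryScenario]) -> str:
        blob = json.dumps(
            {name: scenario_to_dict(s) for name, s in sorted(scenarios.items())},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(manifest: RunManifest) -> dict:
    """Execute all three stages; returns a bundle of pandas DataFrames."""
    scenarios = default_scenarios(manifest.config_dir)
    gwp = GWP_SETS[manifest.gwp]
    if manifest.countries is not None:
        scenarios = {k: v for k, v in scenarios.items() if k in manifest.countries}

    production_names = [n for n, s in scenarios.items() if s.has_role("production")]
    consumption_names = [n for n, s in scenarios.items() if s.has_role("consumption")]

    prod_results = {}
    prod_rows = []
    for name in production_names:
        scenario = scenarios[name]
        try:
            result = cfp_production(scenario, BASELINE_RECIPE, manifest.basis, gwp,
                                    include_luc=manifest.include_luc)
            mc = run_production_mc(scenario, n=manifest.n, seed=manifest.seed,
                                   basis=manifest.basis, gwp=gwp)
        except Exception as exc:
            raise RuntimeError(f"production stage failed for {name}: {exc}") from exc
        prod_results[name] = result
        row = {"country": name}
        for stage in result.breakdown.stages:
            row[stage] = result.breakdown[stage]
            row[f"{stage}_sd"] = mc.stats.get(stage, {}).get("sd", 0.0)
        row["total"] = result.total
        row["total_sd"] = mc.stats["total"]["sd"]
        prod_rows.append(row)
    production_df = pd.DataFrame(prod_rows)

    cons_rows, bf_rows, comp_rows, fig4_rows, fig5_rows = [], [], [], [], []
    for name in consumption_names:
        scenario = scenarios[name]
        pairing = scenario.production_pairing or name
        if pairing not in prod_results:
            if pairing not in scenarios:
                raise RuntimeError(
                    f"consumption stage failed for {name}: production pairing "
                    f"{pairing!r} is not configured"
                )
            prod_results[pairing] = cfp_production(
                scenarios[pairing], BASELINE_RECIPE, manifest.basis, gwp,
                include_luc=manifest.include_luc,
            )
        try:
            cons = cfp_consumption(scenario, prod_results[pairing], gwp,
                                   manifest.sterilisation_mode,
                                   include_luc=manifest.include_luc)
            bf = cfp_breastfeeding(scenario, gwp, include_luc=manifest.include_luc)
            mc = run_comparison_mc(
                scenario, scenarios[pairing], n=manifest.n, seed=manifest.seed,
                basis=manifest.basis, gwp=gwp,
                sterilisation_mode=manifest.sterilisation_mode,
            )
        except Exception as exc:
            raise RuntimeError(f"consumption stage failed for {name}: {exc}") from exc

        row = {"country": name, "production_country": pairing}
        for stage in cons.stages:
            row[stage] = cons[stage]
        row["bms_production_sd"] = (
            production_df.set_index("country")["total_sd"].get(pairing, 0.0)
            if not production_df.empty else 0.0
        )
        row["sterilisation_sd"] = mc.stats["sterilisation"]["sd"]
        row["total"] = cons.total
        row["total_sd"] = mc.stats["cfp_cons"]["sd"]
        cons_rows.append(row)

        bf_rows.append(
            {
                "country": name,
                "plant_per_mj": bf.per_mj_plant,
                "animal_per_mj": bf.per_mj_animal,
                "cooking_per_mj": bf.per_mj_cooking,
                "total_per_mj": bf.per_mj_total,
                "total_per_mj_sd": mc.stats["bf_per_mj"]["sd"],
                "per_kg_bms": bf.per_kg_bms,
                "per_kg_bms_sd": mc.stats["cfp_bf"]["sd"],
                "equivalent_food_mj": equivalent_food_energy(),
            }
        )

        comparison = compare(cons, bf,
                             exceedance_probability=mc.exceedance_probability)
        comp_rows.append(
            {
                "country": name,
                "cfp_cons": cons.total,
                "cfp_bf": bf.per_kg_bms,
                "difference": comparison.difference,
                "ratio": comparison.ratio,
                "exceedance_probability": comparison.exceedance_probability,
            }
        )

        for label, basis, steril in FIG4_VARIANTS:
            vmc = run_comparison_mc(
                scenario, scenarios[pairing], n=manifest.n, seed=manifest.seed,
                basis=basis, gwp=gwp, sterilisation_mode=steril,
            )
            stats = vmc.stats["difference"]
            fig4_rows.append(
                {
                    "country": name, "variant": label,
                    "difference": vmc.point["difference"],
                    "ci95_low": stats["ci95_low"], "ci95_high": stats["ci95_high"],
                    "exceedance_probability": vmc.exceedance_probability,
                }
            )

        for basis in ("dry_mass", "fat_protein"):
            prod_b = cfp_production(scenarios[pairing], BASELINE_RECIPE, basis, gwp)
            cons_b = cfp_consumption(scenario, prod_b, gwp, manifest.sterilisation_mode)
            for point in waste_sweep(scenario, cons_b, gwp=gwp):
                fig5_rows.append({"country": name, "basis": basis, **point})

    bundle = {
        "manifest": manifest,
        "scenarios": scenarios,
        "production": production_df,
        "consumption": pd.DataFrame(cons_rows),
        "breastfeeding": pd.DataFrame(bf_rows),
        "comparison": pd.DataFrame(comp_rows),
        "fig4": pd.DataFrame(fig4_rows),
        "fig5": pd.DataFrame(fig5_rows),
    }
    return bundle
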
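"""Monte Carlo uncertainty propagation.

Distributions follow the published uncertainty grammar: normal or
lognormal with a stated coefficient of variation, or triangular with
relative offsets around the point value (mode at the point).  Parameters
are sampled independently as unit multipliers applied to the scenario's
point values, and the full pipeline is re-evaluated per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .allocation import allocated_burden, dairy_mass_balance
from .breastfeeding import cfp_breastfeeding, equivalent_food_energy
from .consumption import cfp_consumption
from .production import cfp_production
from .recipe import (
    BASELINE_RECIPE,
    FUNCTIONAL_UNIT_ENERGY_DENSITY,
    Recipe,
    default_ingredients,
    nutrient_profile,
    sample_recipes,
)
from .types import CountryScenario, DistributionSpec, GWPSet, REFERENCE_GWP

__all__ = [
    "sample",
    "MonteCarloResult",
    "monte_carlo",
    "production_mc_spec",
    "consumption_mc_spec",
    "breastfeeding_mc_spec",
    "run_production_mc",
    "run_comparison_mc",
    "run_recipe_mc",
]

# Published uncertainty assignments for parameters whose point values sit
# in the scenario but whose spread is a study-wide assumption.  The
# strongly right-skewed triangulars are recentred so the ensemble mean
# stays at the deterministic point estimate (see docs/methods.md).
DIST_ELECTRICITY_ENERGY = DistributionSpec("triangular", rel_min=-0.50, rel_max=0.80,
                                           recentre=True)
DIST_HEAT_ENERGY = DistributionSpec("triangular", rel_min=-0.30, rel_max=0.60,
                                    recentre=True)
DIST_STERILISATION_WATER = DistributionSpec("triangular", rel_min=-0.50, rel_max=0.50)
DIST_STOVE_EFFICIENCY = DistributionSpec("triangular", rel_min=-0.15, rel_max=0.15)
DIST_COOKING_ENERGY = DistributionSpec("triangular", rel_min=-0.30, rel_max=3.00,
                                       recentre=True)


def sample(
    dist: DistributionSpec,
    point_value: float,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` values for a parameter with the given point value."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist.family == "point":
        return np.full(n, float(point_value))
    if dist.family == "normal_cv":
        sd = dist.cv / 100.0 * point_value
        # emission factors are non-negative; the rare far-left normal tail
        # is clipped at zero (mass ~3e-7 at CV 20%)
        return np.maximum(rng.normal(point_value, sd, size=n), 0.0)
    if dist.family == "lognormal_cv":
        if point_value <= 0:
            raise ValueError("lognormal requires a positive point value")
        cv = dist.cv / 100.0
        sigma2 = np.log1p(cv * cv)
        mu = np.log(point_value) - sigma2 / 2.0  # arithmetic mean = point
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    if dist.family == "triangular":
        left = point_value * (1.0 + dist.rel_min)
        right = point_value * (1.0 + dist.rel_max)
        draws = rng.triangular(left, point_value, right, size=n)
        if dist.recentre:
            analytic_mean = (left + point_value + right) / 3.0
            draws *= point_value / analytic_mean
        return draws
    raise ValueError(f"unknown distribution family {dist.family!r}")


@dataclass
class MonteCarloResult:
    n: int
    seed: int
    stats: dict[str, dict[str, float]]  # output -> mean/sd/cv/ci95_low/ci95_high
    exceedance_probability: Optional[float] = None
    point: dict[str, float] = field(default_factory=dict)
    draws: Optional[dict[str, np.ndarray]] = None

    def __getitem__(self, output: str) -> dict[str, float]:
        return self.stats[output]


def _summarise(values: np.ndarray) -> dict[str, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    lo, hi = (np.percentile(values, [2.5, 97.5]) if len(values) > 1
              else (values[0], values[0]))
    return {
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean else float("nan"),
        "ci95_low": float(lo),
        "ci95_high": float(hi),
    }


def monte_carlo(
    evaluate: Callable[[Mapping[str, float]], Mapping[str, float]],
    spec: Mapping[str, DistributionSpec],
    n: int,
    seed: int,
    known_parameters: Optional[Sequence[str]] = None,
    comparison_output: Optional[str] = None,
    keep_draws: bool = False,
) -> MonteCarloResult:
    """Propagate parameter uncertainty through a model evaluation.

    ``evaluate`` maps a dict of unit multipliers to named outputs; the
    multipliers are sampled independently per the spec.  Reproducible for
    fixed ``(spec, n, seed)``.
    """
    if known_parameters is not None:
        unknown = set(spec) - set(known_parameters)
        if unknown:
            raise KeyError(f"unknown Monte Carlo parameters: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    multipliers = {key: sample(spec[key], 1.0, n, rng) for key in sorted(spec)}
    point = dict(evaluate({}))
    outputs: dict[str, np.ndarray] = {k: np.empty(n) for k in point}
    for i in range(n):
        result = evaluate({k: v[i] for k, v in multipliers.items()})
        for k in outputs:
            outputs[k][i] = result[k]
    stats = {k: _summarise(v) for k, v in outputs.items()}
    exceedance = None
    if comparison_output is not None:
        exceedance = float(np.mean(outputs[comparison_output] > 0.0))
    return MonteCarloResult(
        n=n, seed=seed, stats=stats, exceedance_probability=exceedance,
        point=point, draws=outputs if keep_draws else None,
    )


# ----------------------------------------------------------- spec builders

def production_mc_spec(scenario: CountryScenario) -> dict[str, DistributionSpec]:
    spec: dict[str, DistributionSpec] = {}
    if scenario.raw_milk_ef.distribution is not None:
        spec["raw_milk_ef"] = scenario.raw_milk_ef.distribution
    for oil, ef in scenario.oil_efs.items():
        if ef.distribution is not None:
            spec[f"oil_ef:{oil}"] = ef.distribution
    spec["electricity_energy"] = DIST_ELECTRICITY_ENERGY
    spec["heat_energy"] = DIST_HEAT_ENERGY
    return spec


def consumption_mc_spec(scenario: CountryScenario) -> dict[str, DistributionSpec]:
    return {
        "sterilisation_water": DIST_STERILISATION_WATER,
        "stove_efficiency": DIST_STOVE_EFFICIENCY,
    }


def breastfeeding_mc_spec(scenario: CountryScenario) -> dict[str, DistributionSpec]:
    spec: dict[str, DistributionSpec] = {}
    for item in scenario.diet.items:
        if item.ef_distribution is not None:
            spec[f"diet_ef:{item.name}"] = item.ef_distribution
        spec[f"cooking_energy:{item.name}"] = DIST_COOKING_ENERGY
    return spec


def production_parameters(scenario: CountryScenario) -> list[str]:
    return (
        ["raw_milk_ef", "electricity_energy", "heat_energy", "electricity_ef",
         "heat_ef", "transport_distance", "oil_transport_distance",
         "packaging_ef", "chain_waste"]
        + [f"oil_ef:{oil}" for oil in scenario.oil_efs]
    )


def consumption_parameters(scenario: CountryScenario) -> list[str]:
    out = ["sterilisation_water", "stove_efficiency", "serving_mass",
           "retail_transport_distance"]
    for item in scenario.diet.items:
        out += [f"diet_ef:{item.name}", f"cooking_energy:{item.name}"]
    out.append("bms_waste")
    return out


# ----------------------------------------------------------------- drivers

def run_production_mc(
    scenario: CountryScenario,
    n: int = 10_000,
    seed: int = 0,
    recipe: Recipe = BASELINE_RECIPE,
    basis: str = "dry_mass",
    gwp: GWPSet = REFERENCE_GWP,
) -> MonteCarloResult:
    """Uncertainty in the production footprint stages and total."""
    tree = dairy_mass_balance(recipe)
    burden = allocated_burden(tree, basis)

    def evaluate(mult):
        r = cfp_production(scenario, recipe, basis, gwp, tree=tree, burden=burden,
                           mult=mult)
        out = dict(r.breakdown.stages)
        out["total"] = r.total
        return out

    spec = production_mc_spec(scenario)
    return monte_carlo(
        evaluate, spec, n, seed,
        known_parameters=production_parameters(scenario),
    )


def run_comparison_mc(
    consumption_scenario: CountryScenario,
    production_scenario: CountryScenario,
    n: int = 10_000,
    seed: int = 0,
    recipe: Recipe = BASELINE_RECIPE,
    basis: str = "dry_mass",
    gwp: GWPSet = REFERENCE_GWP,
    sterilisation_mode: str = "stovetop",
    keep_draws: bool = False,
) -> MonteCarloResult:
    """Joint uncertainty in CFP_Cons, CFP_BF and their difference.

    The exceedance probability is P(CFP_Cons > CFP_BF).  One seed stream
    drives all parameters, so repeated calls with the same seed give
    paired draws across allocation variants.
    """
    tree = dairy_mass_balance(recipe)
    burden = allocated_burden(tree, basis)

    def evaluate(mult):
        prod = cfp_production(production_scenario, recipe, basis, gwp,
                              tree=tree, burden=burden, mult=mult)
        cons = cfp_consumption(consumption_scenario, prod, gwp,
                               sterilisation_mode=sterilisation_mode, mult=mult)
        bf = cfp_breastfeeding(consumption_scenario, gwp, mult=mult)
        return {
            "cfp_cons": cons.total,
            "cfp_bf": bf.per_kg_bms,
            "difference": cons.total - bf.per_kg_bms,
            "sterilisation": cons["sterilisation"],
            "bf_per_mj": bf.per_mj_total,
            "bf_plant": bf.per_mj_plant,
            "bf_animal": bf.per_mj_animal,
            "bf_cooking": bf.per_mj_cooking,
        }

    spec = {
        **production_mc_spec(production_scenario),
        **consumption_mc_spec(consumption_scenario),
        **breastfeeding_mc_spec(consumption_scenario),
    }
    known = (
        production_parameters(production_scenario)
        + consumption_parameters(consumption_scenario)
    )
    return monte_carlo(
        evaluate, spec, n, seed,
        known_parameters=known, comparison_output="difference",
        keep_draws=keep_draws,
    )


def run_recipe_mc(
    consumption_scenario: CountryScenario,
    production_scenario: CountryScenario,
    n: int = 10_000,
    seed: int = 0,
    basis: str = "dry_mass",
    gwp: GWPSet = REFERENCE_GWP,
    normalisation: str = "cfp",
    keep_draws: bool = False,
) -> MonteCarloResult:
    """Consumption-footprint spread over randomly generated compliant recipes.

    Recipes are sampled uniformly over the solids simplex subject to the
    permitted nutrient ranges; each recipe's footprint is normalised to
    the 21.7 kJ/g functional unit either by rescaling the final CFP
    (``normalisation="cfp"``, default) or by rescaling the ingredient
    masses entering the process chain (``"mass"``).
    """
    if normalisation not in ("cfp", "mass"):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    ingredients = default_ingredients()
    recipes = sample_recipes(n, seed, ingredients)
    totals = np.empty(n)
    for i, recipe in enumerate(recipes):
        profile = nutrient_profile(recipe, ingredients)
        scale = FUNCTIONAL_UNIT_ENERGY_DENSITY / profile.energy_density
        tree = dairy_mass_balance(
            recipe, ingredients=ingredients,
            demand_scale=scale if normalisation == "mass" else 1.0,
        )
        burden = allocated_burden(tree, basis)
        prod = cfp_production(production_scenario, recipe, basis, gwp,
                              tree=tree, burden=burden)
        cons = cfp_consumption(consumption_scenario, prod, gwp)
        totals[i] = cons.total * (scale if normalisation == "cfp" else 1.0)
    stats = {"cfp_cons": _summarise(totals)}
    return MonteCarloResult(
        n=n, seed=seed, stats=stats,
        point={"cfp_cons": float(np.median(totals))},
        draws={"cfp_cons": totals} if keep_draws else None,
    )
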
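"""One-at-a-time (OAT) sensitivity analysis.

Each parameter is perturbed by +/-10% (by default) around its point
value and the relevant total re-evaluated; for a stage that is exactly
linear in the parameter, the percent response equals the perturbation
times the stage's share of the total.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

from .consumption import cfp_consumption
from .montecarlo import consumption_parameters, production_parameters
from .production import ProductionResult, cfp_production
from .recipe import BASELINE_RECIPE, Recipe
from .types import CountryScenario, GWPSet, REFERENCE_GWP

__all__ = [
    "oat_sensitivity",
    "production_oat",
    "consumption_oat",
]


def oat_sensitivity(
    evaluate_total: Callable[[dict[str, float]], float],
    parameters: Iterable[str],
    perturbation: float = 0.10,
) -> list[dict[str, float]]:
    """Signed percent change in a total for +/- perturbations of each parameter."""
    if perturbation <= 0:
        raise ValueError("perturbation must be positive")
    base = evaluate_total({})
    rows = []
    for param in parameters:
        up = evaluate_total({param: 1.0 + perturbation})
        down = evaluate_total({param: 1.0 - perturbation})
        rows.append(
            {
                "parameter": param,
                "pct_change_up": 100.0 * (up - base) / base,
                "pct_change_down": 100.0 * (down - base) / base,
            }
        )
    return rows


def production_oat(
    scenario: CountryScenario,
    parameters: Optional[Sequence[str]] = None,
    perturbation: float = 0.10,
    recipe: Recipe = BASELINE_RECIPE,
    basis: str = "dry_mass",
    gwp: GWPSet = REFERENCE_GWP,
) -> list[dict[str, float]]:
    """OAT sensitivity of CFP_Prod to its emission factors, energy and logistics."""
    params = parameters if parameters is not None else production_parameters(scenario)

    def evaluate_total(mult: dict[str, float]) -> float:
        return cfp_production(scenario, recipe, basis, gwp, mult=mult).total

    return oat_sensitivity(evaluate_total, params, perturbation)


def consumption_oat(
    scenario: CountryScenario,
    production_result: ProductionResult,
    parameters: Optional[Sequence[str]] = None,
    perturbation: float = 0.10,
    gwp: GWPSet = REFERENCE_GWP,
) -> list[dict[str, float]]:
    """OAT sensitivity of CFP_Cons to the consumption-phase parameters."""
    if parameters is None:
        parameters = ["stove_efficiency", "serving_mass", "sterilisation_water",
                      "retail_transport_distance"]

    def evaluate_total(mult: dict[str, float]) -> float:
        return cfp_consumption(scenario, production_result, gwp, mult=mult).total

    return oat_sensitivity(evaluate_total, parameters, perturbation)
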
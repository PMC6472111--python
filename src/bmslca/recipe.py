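"""BMS recipe model: composition, Codex compliance and recipe sampling.

A recipe is a point on the simplex of dry-solids fractions over the four
main ingredients of milk-based powdered formula (skimmed milk solids, whey
protein concentrate, lactose, vegetable oil).  Nutrient bookkeeping uses
metabolisable-energy coefficients of 37 kJ/g for fat and 17 kJ/g for
protein and carbohydrate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import MIX_TOL, ValidationIssue

ENERGY_FAT = 37.0  # kJ per g
ENERGY_PROTEIN = 17.0
ENERGY_CARB = 17.0

FUNCTIONAL_UNIT_ENERGY_DENSITY = 21.7  # kJ per g powder

__all__ = [
    "IngredientSpec",
    "Recipe",
    "NutrientProfile",
    "CodexLimits",
    "BASELINE_RECIPE",
    "default_ingredients",
    "nutrient_profile",
    "validate_codex",
    "sample_recipes",
    "RecipeInfeasibleError",
]


class RecipeInfeasibleError(RuntimeError):
    """Raised when no compliant recipe can be found under the given specs."""


@dataclass(frozen=True)
class IngredientSpec:
    """Composition of one dry ingredient, g per g dry ingredient."""

    name: str
    protein: float
    fat: float
    carbohydrate: float
    ash: float
    whey_share_of_protein: float = 0.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        parts = (self.protein, self.fat, self.carbohydrate, self.ash)
        if any(p < 0 for p in parts):
            raise ValueError(f"{self.name}: negative component fraction")
        if sum(parts) > 1.0 + MIX_TOL:
            raise ValueError(f"{self.name}: component fractions sum above 1")
        if not (0.0 <= self.whey_share_of_protein <= 1.0):
            raise ValueError(f"{self.name}: whey share outside [0, 1]")

    @property
    def energy_density(self) -> float:
        """kJ per g dry ingredient, from the energy coefficients."""
        return (
            ENERGY_FAT * self.fat
            + ENERGY_PROTEIN * self.protein
            + ENERGY_CARB * self.carbohydrate
        )


@dataclass(frozen=True)
class Recipe:
    """Ingredient fractions of total BMS solids; must sum to one."""

    solids_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.solids_fractions.values())
        if abs(total - 1.0) > MIX_TOL:
            raise ValueError(f"solids fractions sum to {total:.12g}, not 1")
        if any(v < 0 for v in self.solids_fractions.values()):
            raise ValueError("negative solids fraction")

    def fraction(self, name: str) -> float:
        return self.solids_fractions.get(name, 0.0)


@dataclass(frozen=True)
class NutrientProfile:
    """Composition per 100 kJ, plus the recipe energy density in kJ/g."""

    protein: float
    carbohydrate: float
    fat: float
    ash: float
    whey_fraction: float
    energy_density: float


@dataclass(frozen=True)
class CodexLimits:
    """Permitted nutrient ranges in g per 100 kJ (infant formula standard)."""

    protein: tuple[float, float] = (0.45, 0.70)
    carbohydrate: tuple[float, float] = (2.30, 3.30)
    fat: tuple[float, float] = (1.05, 1.40)
    whey_min: float = 0.50

    def __post_init__(self) -> None:
        for lo, hi in (self.protein, self.carbohydrate, self.fat):
            if lo > hi:
                raise ValueError("limit min above max")


BASELINE_RECIPE = Recipe(
    {
        "skimmed milk solids": 0.15,
        "whey protein concentrate": 0.10,
        "lactose": 0.50,
        "vegetable oil": 0.25,
    }
)


def default_ingredients() -> dict[str, IngredientSpec]:
    """Packaged ingredient composition table (see data/ingredients.csv)."""
    out: dict[str, IngredientSpec] = {}
    with resources.files("bmslca.data").joinpath("ingredients.csv").open() as fh:
        for row in csv.DictReader(filter(lambda l: not l.startswith("#"), fh)):
            spec = IngredientSpec(
                name=row["name"],
                protein=float(row["protein"]),
                fat=float(row["fat"]),
                carbohydrate=float(row["carbohydrate"]),
                ash=float(row["ash"]),
                whey_share_of_protein=float(row["whey_share_of_protein"]),
                calibrated=row.get("calibrated", "").strip().lower() == "true",
            )
            out[spec.name] = spec
    return out


def nutrient_profile(
    recipe: Recipe, ingredients: Mapping[str, IngredientSpec] | Iterable[IngredientSpec]
) -> NutrientProfile:
    """Per-100 kJ composition of a recipe.

    Nutrient masses are the mass-weighted means over ingredients; the
    energy density is likewise mass-weighted, and the per-100 kJ values are
    nutrient mass divided by energy density.
    """
    if not isinstance(ingredients, Mapping):
        ingredients = {s.name: s for s in ingredients}
    missing = [n for n in recipe.solids_fractions if n not in ingredients]
    if missing:
        raise KeyError(f"no ingredient spec for: {', '.join(sorted(missing))}")

    protein = fat = carb = ash = whey = 0.0
    for name, frac in recipe.solids_fractions.items():
        spec = ingredients[name]
        protein += frac * spec.protein
        fat += frac * spec.fat
        carb += frac * spec.carbohydrate
        ash += frac * spec.ash
        whey += frac * spec.protein * spec.whey_share_of_protein
    energy = ENERGY_FAT * fat + ENERGY_PROTEIN * protein + ENERGY_CARB * carb
    if energy <= 0:
        raise ValueError("recipe has zero energy density")
    return NutrientProfile(
        protein=100.0 * protein / energy,
        carbohydrate=100.0 * carb / energy,
        fat=100.0 * fat / energy,
        ash=100.0 * ash / energy,
        whey_fraction=whey / protein if protein > 0 else 0.0,
        energy_density=energy,
    )


def validate_codex(
    profile: NutrientProfile, limits: CodexLimits | None = None
) -> list[ValidationIssue]:
    """Check a profile against the permitted ranges; empty list means pass."""
    limits = limits or CodexLimits()
    out: list[ValidationIssue] = []
    for nutrient in ("protein", "carbohydrate", "fat"):
        lo, hi = getattr(limits, nutrient)
        value = getattr(profile, nutrient)
        if value < lo:
            out.append(ValidationIssue(nutrient, f"{value:.3f} g/100 kJ below minimum {lo}"))
        elif value > hi:
            out.append(ValidationIssue(nutrient, f"{value:.3f} g/100 kJ above maximum {hi}"))
    if profile.whey_fraction < limits.whey_min:
        out.append(
            ValidationIssue(
                "whey_fraction",
                f"{profile.whey_fraction:.3f} below minimum {limits.whey_min}",
            )
        )
    return out


def _uniform_simplex(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Uniform samples on the (k-1)-simplex via normalised exponentials."""
    x = rng.exponential(size=(n, k))
    return x / x.sum(axis=1, keepdims=True)


def sample_recipes(
    n: int,
    seed: int,
    ingredients: Mapping[str, IngredientSpec] | None = None,
    limits: CodexLimits | None = None,
    max_attempts: int = 2000,
    return_acceptance: bool = False,
):
    """Sample ``n`` Codex-compliant recipes uniformly over the solids simplex.

    Rejection sampling: candidate solids fractions are drawn uniformly on
    the 3-simplex over the four ingredients and kept when their nutrient
    profile passes :func:`validate_codex`.  Deterministic for a fixed seed.

    When ``return_acceptance`` is true, also returns the observed
    acceptance rate of the sampler (an estimate of the feasible fraction
    of the simplex).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ingredients = ingredients or default_ingredients()
    limits = limits or CodexLimits()
    names = list(BASELINE_RECIPE.solids_fractions)
    for name in names:
        if name not in ingredients:
            raise KeyError(f"no ingredient spec for: {name}")
    specs = [ingredients[name] for name in names]
    protein = np.array([s.protein for s in specs])
    fat = np.array([s.fat for s in specs])
    carb = np.array([s.carbohydrate for s in specs])
    whey = np.array([s.protein * s.whey_share_of_protein for s in specs])

    rng = np.random.default_rng(seed)
    accepted: list[Recipe] = []
    tried = 0
    n_accepted = 0
    batch = max(4 * n, 1000)
    for _ in range(max_attempts):
        x = _uniform_simplex(rng, batch, len(names))
        tried += batch
        p = x @ protein
        f = x @ fat
        c = x @ carb
        w = x @ whey
        energy = ENERGY_FAT * f + ENERGY_PROTEIN * p + ENERGY_CARB * c
        with np.errstate(invalid="ignore", divide="ignore"):
            ok = (
                (100 * p / energy >= limits.protein[0])
                & (100 * p / energy <= limits.protein[1])
                & (100 * c / energy >= limits.carbohydrate[0])
                & (100 * c / energy <= limits.carbohydrate[1])
                & (100 * f / energy >= limits.fat[0])
                & (100 * f / energy <= limits.fat[1])
                & (np.where(p > 0, w / np.where(p > 0, p, 1.0), 0.0) >= limits.whey_min)
            )
        n_accepted += int(ok.sum())
        for row in x[ok]:
            if len(accepted) < n:
                accepted.append(Recipe(dict(zip(names, map(float, row)))))
        if len(accepted) == n:
            break
    else:
        raise RecipeInfeasibleError(
            f"no {n} compliant recipes found in {tried} draws; feasible region "
            "may be empty under the given ingredient specs"
        )
    if return_acceptance:
        # full batches are always classified, so the rate is unbiased
        return accepted, n_accepted / tried
    return accepted


def feasible_volume_grid(
    ingredients: Mapping[str, IngredientSpec] | None = None,
    limits: CodexLimits | None = None,
    step: float = 0.005,
) -> float:
    """Feasible fraction of the simplex by dense-grid enumeration.

    Independent oracle for the sampler's acceptance rate: enumerates
    barycentric grid points at the given step and returns the fraction
    passing the Codex check.
    """
    ingredients = ingredients or default_ingredients()
    limits = limits or CodexLimits()
    names = list(BASELINE_RECIPE.solids_fractions)
    specs = [ingredients[name] for name in names]
    m = int(round(1.0 / step))
    i, j, k = np.meshgrid(
        np.arange(m + 1), np.arange(m + 1), np.arange(m + 1), indexing="ij"
    )
    mask = i + j + k <= m
    i, j, k = i[mask], j[mask], k[mask]
    x = np.stack([i, j, k, m - i - j - k], axis=1) / m
    protein = x @ np.array([s.protein for s in specs])
    fat = x @ np.array([s.fat for s in specs])
    carb = x @ np.array([s.carbohydrate for s in specs])
    whey = x @ np.array([s.protein * s.whey_share_of_protein for s in specs])
    energy = ENERGY_FAT * fat + ENERGY_PROTEIN * protein + ENERGY_CARB * carb
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (
            (100 * protein / energy >= limits.protein[0])
            & (100 * protein / energy <= limits.protein[1])
            & (100 * carb / energy >= limits.carbohydrate[0])
            & (100 * carb / energy <= limits.carbohydrate[1])
            & (100 * fat / energy >= limits.fat[0])
            & (100 * fat / energy <= limits.fat[1])
            & (np.where(protein > 0, whey / np.where(protein > 0, protein, 1), 0) >= limits.whey_min)
        )
    return float(ok.sum()) / float(len(x))
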
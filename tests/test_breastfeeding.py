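"""Breastfeeding equivalence: diet footprint, comparison, waste sweep."""

import numpy as np
import pytest

from bmslca.breastfeeding import (
    cfp_breastfeeding,
    compare,
    diet_cfp,
    equivalent_food_energy,
    waste_sweep,
)
from bmslca.consumption import cfp_consumption
from bmslca.types import Diet, DietItem, FeedingParameters, GWP_SETS

from conftest import PAIRINGS, assert_printed

# Published diet table: plant, animal, cooking, total (kg CO2e per MJ
# consumed) and per kg BMS.
PUBLISHED_DIETS = {
    "United Kingdom": (0.074, 0.26, 0.10, 0.44, 6.9),
    "China": (0.12, 0.15, 0.14, 0.41, 6.5),
    "Brazil": (0.082, 0.27, 0.10, 0.45, 7.8),
    "Vietnam": (0.13, 0.13, 0.07, 0.33, 5.9),
}


class TestEquivalentFoodEnergy:
    def test_defaults_round_to_18_mj_per_kg(self):
        value = equivalent_food_energy()
        assert round(value) == 18
        assert value == pytest.approx(385.0 / 21.0)

    def test_linear_in_maternal_energy(self):
        half = equivalent_food_energy(FeedingParameters(period_total_food=385.0 / 2))
        assert half == pytest.approx(equivalent_food_energy() / 2)

    def test_zero_period_mass_is_rejected(self):
        with pytest.raises(ValueError):
            equivalent_food_energy(FeedingParameters(period_bms_mass=0.0))


class TestDietCfp:
    @pytest.mark.parametrize("country", sorted(PAIRINGS))
    def test_diet_terms_match_published_table(self, scenarios, country):
        bf = cfp_breastfeeding(scenarios[country])
        plant, animal, cooking, total, per_kg = PUBLISHED_DIETS[country]
        assert_printed(bf.per_mj_plant, plant)
        assert_printed(bf.per_mj_animal, animal)
        assert_printed(bf.per_mj_cooking, cooking)
        assert_printed(bf.per_mj_total, total)
        assert_printed(bf.per_kg_bms, per_kg)

    def test_wheat_only_diet_sits_at_the_cited_low_end(self, scenarios):
        """~0.03 kg CO2e per MJ if the extra energy came from wheat alone."""
        diet = Diet(items=(DietItem("wheat", "plant", 1.0, 0.03, 0.0, 0.08),))
        terms = diet_cfp(diet, stove_profile=())
        assert terms["plant"] == pytest.approx(0.03)
        assert terms["animal"] == 0.0

    def test_zero_ef_diet_without_cooking_is_zero(self):
        diet = Diet(items=(DietItem("x", "plant", 1.0, 0.0, 0.0, 0.0),))
        terms = diet_cfp(diet, stove_profile=())
        assert terms["plant"] == terms["cooking"] == 0.0

    def test_household_waste_inflates_production_terms(self):
        lean = Diet(items=(DietItem("x", "plant", 1.0, 0.1, 0.0, 0.0),))
        wasteful = Diet(items=(DietItem("x", "plant", 1.0, 0.1, 0.5, 0.0),))
        assert diet_cfp(wasteful, ())["plant"] == pytest.approx(
            2.0 * diet_cfp(lean, ())["plant"]
        )

    def test_brazil_luc_doubles_the_diet_footprint(self, scenarios):
        base = cfp_breastfeeding(scenarios["Brazil"])
        with_luc = cfp_breastfeeding(scenarios["Brazil"], include_luc=True)
        assert with_luc.per_kg_bms / base.per_kg_bms == pytest.approx(2.0, abs=0.05)

    def test_other_countries_luc_adds_at_most_2_percent(self, scenarios):
        for country in ("United Kingdom", "China", "Vietnam"):
            base = cfp_breastfeeding(scenarios[country]).per_kg_bms
            luc = cfp_breastfeeding(scenarios[country], include_luc=True).per_kg_bms
            assert 1.0 <= luc / base <= 1.02


class TestComparison:
    def test_bms_exceeds_breastfeeding_in_every_default_country(
        self, scenarios, production_results
    ):
        for country, pairing in PAIRINGS.items():
            cons = cfp_consumption(scenarios[country], production_results[pairing])
            bf = cfp_breastfeeding(scenarios[country])
            assert compare(cons, bf).difference > 0

    def test_breastfeeding_is_40_to_53_percent_lower(
        self, scenarios, production_results
    ):
        """Published reductions: 40/53/43/46% for UK/China/Brazil/Vietnam,
        reproduced within 3 percentage points."""
        published = {"United Kingdom": 0.40, "China": 0.53,
                     "Brazil": 0.43, "Vietnam": 0.46}
        for country, pairing in PAIRINGS.items():
            cons = cfp_consumption(scenarios[country], production_results[pairing])
            bf = cfp_breastfeeding(scenarios[country])
            reduction = 1.0 - bf.per_kg_bms / cons.total
            assert reduction == pytest.approx(published[country], abs=0.03)

    def test_identical_totals_compare_as_equal(self, scenarios):
        bf = cfp_breastfeeding(scenarios["China"])
        from bmslca.types import StageBreakdown

        cons = StageBreakdown({"total": bf.per_kg_bms})
        result = compare(cons, bf)
        assert result.difference == pytest.approx(0.0, abs=1e-12)
        assert result.ratio == pytest.approx(1.0)

    def test_mismatched_gwp_sets_are_rejected(self, scenarios):
        bf = cfp_breastfeeding(scenarios["China"], gwp=GWP_SETS["AR5"])
        from bmslca.types import StageBreakdown

        with pytest.raises(ValueError, match="GWP"):
            compare(StageBreakdown({"total": 1.0}), bf, gwp=GWP_SETS["AR4"])

    def test_full_waste_limit_sends_breastfeeding_to_zero(self, scenarios):
        s = scenarios["China"].with_updates(bms_waste_fraction=1.0 - 1e-9)
        assert cfp_breastfeeding(s).per_kg_bms == pytest.approx(0.0, abs=1e-6)


class TestWasteSweep:
    def test_breastfeeding_curve_is_strictly_decreasing(
        self, scenarios, production_results
    ):
        cons = cfp_consumption(scenarios["China"], production_results["New Zealand"])
        rows = waste_sweep(scenarios["China"], cons, waste_grid=np.linspace(0, 0.5, 11))
        bf = [r["cfp_bf"] for r in rows]
        assert all(b > a for a, b in zip(bf[1:], bf))
        assert all(r["cfp_cons"] == pytest.approx(cons.total) for r in rows)

    def test_ratio_stays_below_one_for_all_defaults(
        self, scenarios, production_results
    ):
        for country, pairing in PAIRINGS.items():
            cons = cfp_consumption(scenarios[country], production_results[pairing])
            rows = waste_sweep(scenarios[country], cons)
            assert max(r["ratio"] for r in rows) < 1.0
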
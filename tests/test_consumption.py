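"""Cradle-to-bottle footprint: feeding plan, home energy, stage table."""

import pytest

from bmslca.consumption import (
    cfp_consumption,
    feeding_plan,
    home_energy_cfp,
    stove_delivered_ef,
)
from bmslca.types import FeedingParameters, StoveFuel

from conftest import PAIRINGS, assert_printed

# Published consumption table: BMS production, sterilisation, preparation,
# transport, bottle production, total.
PUBLISHED_CONSUMPTION = {
    "United Kingdom": (8.4, 2.4, 0.38, 0.15, 0.05, 11),
    "China": (9.2, 3.8, 0.59, 0.20, 0.05, 14),
    "Brazil": (11, 2.2, 0.33, 0.09, 0.05, 14),
    "Vietnam": (8.4, 1.8, 0.28, 0.27, 0.05, 11),
}
STAGES = ("bms_production", "sterilisation", "preparation", "transport",
          "bottle_production")


class TestFeedingPlan:
    def test_default_parameters_give_published_bottle_counts(self):
        """18.6 g servings: 54 bottles sterilised and 0.3 manufactured per kg."""
        plan = feeding_plan()
        assert plan.bottles_to_sterilise_per_kg == 54
        assert plan.sterilisation_batches_per_kg == pytest.approx(9.0)
        assert round(plan.bottles_manufactured_per_kg, 1) == 0.3
        assert plan.water_heated_for_sterilisation == pytest.approx(45.0)
        assert plan.water_heated_for_prep == pytest.approx(54 * 0.13)

    def test_kilogram_serving_gives_one_bottle(self):
        plan = feeding_plan(FeedingParameters(serving_mass=1000.0,
                                              bms_energy_density=21.7))
        assert plan.servings_per_kg == 1

    def test_zero_serving_mass_is_rejected(self):
        with pytest.raises(ValueError):
            feeding_plan(mult={"serving_mass": 0.0})


class TestHomeEnergy:
    def test_china_sterilisation_matches_published_value(self, scenarios):
        steril, prep = home_energy_cfp(feeding_plan(), scenarios["China"])
        assert_printed(steril, 3.8)
        assert_printed(prep, 0.59)

    def test_zero_fuel_emissions_give_zero(self, scenarios):
        profile = tuple(
            StoveFuel(f.fuel, f.share, 0.0, f.efficiency)
            for f in scenarios["China"].stove_profile
        )
        s = scenarios["China"].with_updates(stove_profile=profile,
                                            sterilisation_boil_margin=0.0)
        assert home_energy_cfp(feeding_plan(), s) == (0.0, 0.0)

    def test_sterilisation_scales_linearly_with_water(self, scenarios):
        s = scenarios["Vietnam"]  # no boil margin
        base, _ = home_energy_cfp(feeding_plan(), s)
        doubled, _ = home_energy_cfp(
            feeding_plan(mult={"sterilisation_water": 2.0}), s
        )
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)

    def test_zero_efficiency_is_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            stove_delivered_ef((StoveFuel("gas", 1.0, 0.06, 0.0),))


class TestConsumptionBreakdown:
    @pytest.mark.parametrize("country", sorted(PAIRINGS))
    def test_stage_breakdown_matches_published_table(
        self, scenarios, production_results, country
    ):
        cons = cfp_consumption(
            scenarios[country], production_results[PAIRINGS[country]]
        )
        for stage, expected in zip(STAGES, PUBLISHED_CONSUMPTION[country]):
            assert_printed(cons[stage], expected)
        assert_printed(cons.total, PUBLISHED_CONSUMPTION[country][-1])

    def test_consumption_phase_share_is_19_to_33_percent(
        self, scenarios, production_results
    ):
        shares = []
        for country, pairing in PAIRINGS.items():
            cons = cfp_consumption(scenarios[country], production_results[pairing])
            shares.append(1.0 - cons["bms_production"] / cons.total)
        assert 0.185 <= min(shares)
        assert max(shares) <= 0.335

    def test_bottles_and_retail_transport_are_at_most_3_percent(
        self, scenarios, production_results
    ):
        for country, pairing in PAIRINGS.items():
            cons = cfp_consumption(scenarios[country], production_results[pairing])
            minor = cons["transport"] + cons["bottle_production"]
            assert 0.005 <= minor / cons.total <= 0.031

    def test_no_sterilisation_zeroes_the_stage(self, scenarios, production_results):
        cons = cfp_consumption(
            scenarios["China"], production_results["New Zealand"],
            sterilisation_mode="none",
        )
        assert cons["sterilisation"] == 0.0

    def test_china_no_sterilisation_reduction_is_largest_at_27_percent(
        self, scenarios, production_results
    ):
        """Skipping sterilisation cuts 16-27% off the total; China is the
        extreme because of its coal-heavy stove mix."""
        reductions = {}
        for country, pairing in PAIRINGS.items():
            base = cfp_consumption(scenarios[country], production_results[pairing])
            none = cfp_consumption(scenarios[country], production_results[pairing],
                                   sterilisation_mode="none")
            reductions[country] = 1.0 - none.total / base.total
        assert max(reductions, key=reductions.get) == "China"
        assert round(100 * reductions["China"]) == 27
        assert round(100 * min(reductions.values())) == 16

    def test_steam_sterilisation_cuts_14_to_23_percent(
        self, scenarios, production_results
    ):
        for country, pairing in PAIRINGS.items():
            base = cfp_consumption(scenarios[country], production_results[pairing])
            steam = cfp_consumption(scenarios[country], production_results[pairing],
                                    sterilisation_mode="steam")
            assert 0.13 <= 1.0 - steam.total / base.total <= 0.235

    def test_missing_production_result_is_an_error(self, scenarios):
        with pytest.raises(ValueError, match="paired production"):
            cfp_consumption(scenarios["China"], None)

    def test_unknown_sterilisation_mode_is_rejected(
        self, scenarios, production_results
    ):
        with pytest.raises(ValueError, match="sterilisation mode"):
            cfp_consumption(scenarios["China"], production_results["New Zealand"],
                            sterilisation_mode="uv")
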
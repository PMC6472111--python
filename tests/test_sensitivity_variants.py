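"""One-at-a-time sensitivity and the published scenario switches."""

import pytest

from bmslca.consumption import cfp_consumption
from bmslca.production import cfp_production
from bmslca.sensitivity import consumption_oat, oat_sensitivity, production_oat
from bmslca.variants import CITED_ADDITIVE_EFS, apply_variant
from bmslca.types import GWP_SETS, round_sig

from conftest import PAIRINGS


class TestOat:
    def test_nz_raw_milk_elasticity_rounds_to_8_percent(self, scenarios):
        """A +/-10% change in the raw-milk factor moves the New Zealand
        production footprint by 8% (nearest percent)."""
        rows = production_oat(scenarios["New Zealand"], parameters=["raw_milk_ef"])
        assert round(rows[0]["pct_change_up"]) == 8
        assert round(rows[0]["pct_change_down"]) == -8

    def test_irrelevant_parameter_changes_nothing(self, scenarios):
        rows = production_oat(scenarios["New Zealand"],
                              parameters=["sterilisation_water"])
        assert rows[0]["pct_change_up"] == 0.0

    def test_linear_parameters_respond_with_stage_share_elasticity(
        self, production_results, scenarios
    ):
        """Analytic oracle: for a purely linear stage, the percent change
        equals the perturbation times the stage share."""
        for country, result in production_results.items():
            rows = production_oat(scenarios[country], parameters=["raw_milk_ef"],
                                  perturbation=0.1)
            share = result.breakdown["raw_milk"] / result.total
            assert rows[0]["pct_change_up"] == pytest.approx(10.0 * share, rel=1e-9)

    def test_all_non_raw_milk_parameters_respond_below_1_percent(self, scenarios):
        rows = production_oat(scenarios["New Zealand"])
        others = [r for r in rows if r["parameter"] != "raw_milk_ef"]
        assert others and all(abs(r["pct_change_up"]) < 1.0 for r in others)

    def test_consumption_oat_top_parameters_respond_2_to_3_percent(
        self, scenarios, production_results
    ):
        """Stove efficiency, serving size and sterilisation water dominate
        the China consumption response, each at 2-3% per +/-10%; stove
        efficiency and serving size are structurally tied (both rescale
        the same heating stages)."""
        rows = consumption_oat(scenarios["China"], production_results["New Zealand"])
        by_size = sorted(rows, key=lambda r: -abs(r["pct_change_up"]))
        leaders = {r["parameter"] for r in by_size[:3]}
        assert leaders == {"stove_efficiency", "serving_mass", "sterilisation_water"}
        for r in by_size[:3]:
            assert 2.0 <= abs(r["pct_change_up"]) <= 3.0

    def test_zero_perturbation_is_rejected(self):
        with pytest.raises(ValueError):
            oat_sensitivity(lambda m: 1.0, ["x"], perturbation=0.0)


class TestVariants:
    def test_identity_switch_changes_nothing(self, scenarios):
        v = apply_variant(scenarios["New Zealand"], "identity")
        assert cfp_production(v.scenario).total == pytest.approx(
            cfp_production(scenarios["New Zealand"]).total
        )

    def test_packaging_extremes_move_totals_by_published_percents(self, scenarios):
        """All-tin raises the production footprint ~1%; all bag-in-box
        lowers it ~2%."""
        base = cfp_production(scenarios["New Zealand"]).total
        tin = cfp_production(
            apply_variant(scenarios["New Zealand"], "tin_cans_only").scenario
        ).total
        bib = cfp_production(
            apply_variant(scenarios["New Zealand"], "bag_in_box_only").scenario
        ).total
        assert 100 * (tin / base - 1) == pytest.approx(1.0, abs=0.5)
        assert 100 * (bib / base - 1) == pytest.approx(-2.0, abs=0.5)

    def test_vitamin_addon_spans_published_bounds(self, scenarios):
        """2% additive mass at the cited factor range adds 0.006-1.3 kg."""
        base = cfp_production(scenarios["New Zealand"]).total
        low = apply_variant(scenarios["New Zealand"], "vitamins",
                            additive_ef=min(CITED_ADDITIVE_EFS.values()))
        high = apply_variant(scenarios["New Zealand"], "vitamins",
                             additive_ef=max(CITED_ADDITIVE_EFS.values()))
        low_delta = cfp_production(low.scenario).total - base
        high_delta = cfp_production(high.scenario).total - base
        assert low_delta == pytest.approx(0.006, abs=1e-12)
        assert round_sig(high_delta) == 1.3

    def test_ar5_switch_raises_consumption_4_to_5_percent(
        self, scenarios, production_results
    ):
        """Re-characterising methane at 28 instead of 25 raises the
        cradle-to-bottle footprint by 4-5%."""
        gwp5 = GWP_SETS["AR5"]
        for country, pairing in PAIRINGS.items():
            base = cfp_consumption(scenarios[country], production_results[pairing])
            prod5 = cfp_production(scenarios[pairing], gwp=gwp5)
            cons5 = cfp_consumption(scenarios[country], prod5, gwp=gwp5)
            assert 0.035 <= cons5.total / base.total - 1.0 <= 0.055

    def test_ar5_switch_raises_breastfeeding_2_to_4_percent(self, scenarios):
        from bmslca.breastfeeding import cfp_breastfeeding

        for country in PAIRINGS:
            base = cfp_breastfeeding(scenarios[country]).per_kg_bms
            bumped = cfp_breastfeeding(scenarios[country],
                                       gwp=GWP_SETS["AR5"]).per_kg_bms
            assert 0.015 <= bumped / base - 1.0 <= 0.045

    def test_luc_adds_at_most_one_percent_to_consumption(
        self, scenarios, production_results
    ):
        for country, pairing in PAIRINGS.items():
            prod = cfp_production(scenarios[pairing], include_luc=True)
            cons = cfp_consumption(scenarios[country], prod, include_luc=True)
            base = cfp_consumption(scenarios[country], production_results[pairing])
            assert 0.004 <= cons.total / base.total - 1.0 <= 0.0101

    def test_unknown_switch_is_rejected(self, scenarios):
        with pytest.raises(ValueError, match="unknown variant"):
            apply_variant(scenarios["China"], "teleportation")
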
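"""Dairy mass balance and co-product allocation."""

import pytest

from bmslca.allocation import (
    ALLOCATION_BASES,
    CoProductStream,
    InfeasibleMassBalanceError,
    ProcessStep,
    ProcessTree,
    allocated_burden,
    allocation_factors,
    dairy_mass_balance,
)
from bmslca.recipe import BASELINE_RECIPE, Recipe

from conftest import assert_printed


class TestMassBalance:
    def test_baseline_recipe_draws_published_raw_milk_quantities(self, baseline_tree,
                                                                 baseline_burden):
        """13.7 kg raw milk in, 6.6 kg allocated to BMS under dry mass."""
        assert_printed(baseline_tree.raw_milk_input, 13.7)
        assert_printed(baseline_burden.raw_milk_kg, 6.6)

    def test_conservation_holds_at_every_step(self, baseline_tree):
        baseline_tree.check_conservation()

    def test_dairy_free_recipe_needs_no_milk(self):
        tree = dairy_mass_balance(Recipe({"vegetable oil": 1.0}))
        assert tree.raw_milk_input == 0.0
        assert allocated_burden(tree, "dry_mass").raw_milk_kg == 0.0

    def test_stream_masses_are_linear_in_demands(self, baseline_tree):
        doubled = dairy_mass_balance(BASELINE_RECIPE, demand_scale=2.0)
        for name, stream in baseline_tree.streams.items():
            assert doubled.streams[name].wet_mass == pytest.approx(
                2.0 * stream.wet_mass, abs=1e-9
            )
            assert doubled.streams[name].dry_mass == pytest.approx(
                2.0 * stream.dry_mass, abs=1e-9
            )

    def test_chain_waste_inflates_demands_multiplicatively(self):
        tree = dairy_mass_balance(BASELINE_RECIPE, chain_waste=[0.1, 0.1])
        base = dairy_mass_balance(BASELINE_RECIPE)
        assert tree.raw_milk_input == pytest.approx(
            base.raw_milk_input / 0.81, rel=1e-12
        )

    def test_excess_whey_protein_demand_is_infeasible(self, ingredients):
        recipe = Recipe(
            {
                "skimmed milk solids": 0.05,
                "whey protein concentrate": 0.60,
                "lactose": 0.05,
                "vegetable oil": 0.30,
            }
        )
        tree = dairy_mass_balance(recipe, ingredients)
        # protein-heavy demand binds on protein, leaving surplus lactose
        assert tree.streams["surplus_whey"].dry_mass > 0

    def test_roundtrip_serialisation(self, baseline_tree):
        doc = baseline_tree.to_dict()
        assert doc["raw_milk_input"] == baseline_tree.raw_milk_input
        assert set(doc["streams"]) == set(baseline_tree.streams)


class TestAllocationFactors:
    def test_equal_dry_mass_splits_in_half(self):
        streams = [
            CoProductStream("a", 2.0, 1.0, {"protein": 0.3}),
            CoProductStream("b", 3.0, 1.0, {"protein": 0.1}),
        ]
        assert allocation_factors(streams, "dry_mass") == {"a": 0.5, "b": 0.5}

    def test_lactose_gets_nothing_under_fat_protein(self, baseline_tree):
        factors = allocation_factors(
            [baseline_tree.streams["wpc"], baseline_tree.streams["lactose_powder"]],
            "fat_protein",
        )
        assert factors["lactose_powder"] == 0.0
        assert factors["wpc"] == 1.0

    @pytest.mark.parametrize("basis", ALLOCATION_BASES)
    def test_factors_sum_to_one_under_every_basis(self, baseline_tree, basis):
        for step_outputs in (
            ["skim_milk_bms", "skim_milk_cheese", "cream"],
            ["curd", "whey"],
        ):
            streams = [baseline_tree.streams[n] for n in step_outputs]
            assert sum(allocation_factors(streams, basis).values()) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_all_zero_basis_property_is_an_error(self):
        streams = [CoProductStream("a", 1.0, 0.0), CoProductStream("b", 1.0, 0.0)]
        with pytest.raises(ValueError, match="allocation undefined"):
            allocation_factors(streams, "dry_mass")


def _toy_tree():
    """Three-step toy tree with hand-enumerable allocation paths."""
    streams = {
        "raw_milk": CoProductStream("raw_milk", 10.0, 2.0, {"protein": 0.5, "fat": 0.5}),
        "a": CoProductStream("a", 6.0, 1.2, {"protein": 0.4, "fat": 0.2}, price=2.0),
        "b": CoProductStream("b", 4.0, 0.8, {"protein": 0.1, "fat": 0.3}, price=1.0),
        "a1": CoProductStream("a1", 3.0, 0.9, {"protein": 0.3}, price=3.0,
                              destined_for_bms=True),
        "a2": CoProductStream("a2", 3.0, 0.3, {"protein": 0.1, "fat": 0.2}, price=1.0),
        "final": CoProductStream("final", 1.0, 0.9, {"protein": 0.3}, price=5.0,
                                 destined_for_bms=True),
    }
    steps = [
        ProcessStep("split", ["raw_milk"], ["a", "b"], electricity=2.0, heat=4.0),
        ProcessStep("refine", ["a"], ["a1", "a2"], electricity=1.0),
        ProcessStep("finish", ["a1"], ["final"], heat=3.0, dedicated_to="bms",
                    evaporated_water=2.0),
    ]
    return ProcessTree(streams=streams, steps=steps, raw_milk_input=10.0)


class TestAllocatedBurden:
    @pytest.mark.parametrize("basis", ALLOCATION_BASES)
    def test_toy_tree_equals_exhaustive_path_oracle(self, basis):
        """Multiplicative path products, enumerated by hand, reproduce the
        propagated burden exactly."""
        tree = _toy_tree()

        def prop(name):
            s = tree.streams[name]
            return {
                "dry_mass": s.dry_mass,
                "fat_protein": s.fat + s.protein,
                "energy": s.energy,
                "economic": s.price * s.dry_mass,
            }[basis]

        f_a = prop("a") / (prop("a") + prop("b"))
        f_a1 = prop("a1") / (prop("a1") + prop("a2"))
        # raw milk: 10 kg enters, path raw->a->a1->final
        expected_milk = 10.0 * f_a * f_a1
        # electricity: split shares 2 MJ, refine shares 1 MJ; heat: split 4 MJ
        # shared, finish 3 MJ dedicated to the BMS stream.
        expected_el = 2.0 * f_a * f_a1 + 1.0 * f_a1
        expected_heat = 4.0 * f_a * f_a1 + 3.0

        burden = allocated_burden(tree, basis)
        assert burden.raw_milk_kg == pytest.approx(expected_milk, rel=1e-12)
        assert burden.electricity_mj == pytest.approx(expected_el, rel=1e-12)
        assert burden.heat_mj == pytest.approx(expected_heat, rel=1e-12)

    @pytest.mark.parametrize("basis", ALLOCATION_BASES)
    def test_terminal_burden_conserves_total_raw_milk(self, basis):
        """Summed over all terminal streams, allocation returns every kg."""
        tree = dairy_mass_balance(BASELINE_RECIPE)
        bms = allocated_burden(tree, basis).raw_milk_kg
        # flip all terminals to BMS-destined to capture the full balance
        for s in tree.terminal_streams():
            s.destined_for_bms = True
        carried = allocated_burden(tree, basis).raw_milk_kg
        assert carried == pytest.approx(tree.raw_milk_input, rel=1e-9)
        assert bms <= carried + 1e-9

    def test_basis_ordering_on_allocated_bms_burden(self, baseline_tree):
        """Fat+protein < energy < dry mass, and economic < dry mass: the
        lactose-heavy BMS chain carries least under fat/protein or price."""
        milk = {
            basis: allocated_burden(baseline_tree, basis).raw_milk_kg
            for basis in ALLOCATION_BASES
        }
        assert milk["fat_protein"] < milk["energy"] < milk["dry_mass"]
        assert milk["economic"] < milk["dry_mass"]
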
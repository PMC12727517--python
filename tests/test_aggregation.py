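"""Group totals, stratification, energetic intactness and dominance."""

import math

import numpy as np
import pandas as pd
import pytest

import ecoflow
from ecoflow import aggregation, classification, vocab
from ecoflow.core import EnergyLayer, ValidationError
from tests.conftest import build_world, make_species_row, simple_density, uniform_landscape


@pytest.fixture(scope="module")
def small_layer(small_world):
    return ecoflow.compute_energy_layers(small_world)


@pytest.fixture(scope="module")
def guilds(small_world):
    return classification.assign_guilds(small_world.species)


class TestCellTotals:
    def test_single_species_guild_total_is_species_flow(self):
        world = build_world(
            [make_species_row()], [simple_density("m0", 10.0)], uniform_landscape()
        )
        layer = ecoflow.compute_energy_layers(world)
        assignment = pd.Series({"m0": "g"})
        totals = aggregation.cell_totals_by_group(layer, assignment)
        assert np.array_equal(totals["g"][0], layer.historical[0])

    def test_guild_totals_partition_species_totals(self, small_world, small_layer, guilds):
        totals = aggregation.cell_totals_by_group(small_layer, guilds)
        summed_h = sum(h for h, _ in totals.values())
        summed_c = sum(c for _, c in totals.values())
        assert np.allclose(summed_h, small_layer.total("historical"), rtol=1e-12, atol=0)
        assert np.allclose(summed_c, small_layer.total("current"), rtol=1e-12, atol=0)

    def test_multi_function_species_double_counts(self):
        layer = EnergyLayer(
            ["s1"], np.full((1, 12, 12), 5.0), np.full((1, 12, 12), 5.0)
        )
        membership = pd.DataFrame(
            {"fnA": [True], "fnB": [True]}, index=pd.Index(["s1"], name="species_id")
        )
        totals = aggregation.cell_totals_by_group(layer, membership, "function")
        fn_sum = totals["fnA"][0] + totals["fnB"][0]
        assert (fn_sum == 10.0).all()  # exceeds the 5.0 total by design

    def test_unassigned_species_rejected_for_partitions(self, small_layer):
        with pytest.raises(ValidationError):
            aggregation.cell_totals_by_group(small_layer, pd.Series({"nobody": "g"}))


class TestLanduseMapping:
    def test_urban_cover_threshold(self):
        out = aggregation.map_landuse_to_analysis_class(
            np.array([0]), np.array([False]), np.array([0.25]),
            np.array([0.0]), np.array([0.0]),
        )
        assert out[0] == "settlements"

    def test_crop_cover_threshold(self):
        out = aggregation.map_landuse_to_analysis_class(
            np.array([0]), np.array([False]), np.array([0.0]),
            np.array([0.0]), np.array([0.30]),
        )
        assert out[0] == "croplands"

    def test_population_density_triggers_settlement(self):
        out = aggregation.map_landuse_to_analysis_class(
            np.array([0]), np.array([False]), np.array([0.0]),
            np.array([1500.0]), np.array([0.5]),
        )
        assert out[0] == "settlements"  # settlement check outranks cropland

    def test_remaining_cells_are_untransformed(self):
        out = aggregation.map_landuse_to_analysis_class(
            np.array([0]), np.array([False]), np.array([0.05]),
            np.array([10.0]), np.array([0.1]),
        )
        assert out[0] == "unprotected_untransformed"

    def test_protection_wins(self):
        out = aggregation.map_landuse_to_analysis_class(
            np.array([0]), np.array([True]), np.array([0.9]),
            np.array([5000.0]), np.array([0.9]),
        )
        assert out[0] == "strict_protected"


class TestStratifiedMean:
    def test_uniform_stratum_returns_value(self):
        values = np.full((2, 2), 7.0)
        labels = np.array([["a", "a"], ["a", "a"]])
        assert aggregation.stratified_mean(values, labels) == {"a": 7.0}

    def test_two_cell_mean(self):
        values = np.array([[2.0, 4.0]])
        labels = np.array([["a", "a"]])
        assert aggregation.stratified_mean(values, labels)["a"] == 3.0

    def test_mosaic_cells_do_not_move_biome_means(self):
        land = uniform_landscape(12, 12, biome="grassy")
        labels, include = aggregation.biome_strata(land)
        values = np.arange(144, dtype=float).reshape(12, 12)
        base = aggregation.stratified_mean(values, labels, include)["grassy"]
        # convert one block to mosaic: excluded from strata, mean unchanged
        land.biome[:6, :6] = vocab.biome_code("mosaic")
        labels2, include2 = aggregation.biome_strata(land)
        moved = aggregation.stratified_mean(values, labels2, include2)["grassy"]
        expected = values[land.biome == vocab.biome_code("grassy")].mean()
        assert moved == pytest.approx(expected)
        assert "mosaic" not in aggregation.stratified_mean(values, labels2, include2)
        assert base != moved  # the mosaic block did hold different values


class TestEnergeticIntactness:
    def test_half_remaining(self):
        assert aggregation.energetic_intactness(50, 100) == 0.5

    def test_amplified_function_exceeds_one(self):
        assert aggregation.energetic_intactness(108, 100) == pytest.approx(1.08)

    def test_zero_historical_flagged_as_nan(self):
        assert math.isnan(aggregation.energetic_intactness(0.0, 0.0))

    def test_scale_invariance(self):
        a = aggregation.energetic_intactness(30.0, 80.0)
        b = aggregation.energetic_intactness(30.0 * 17.3, 80.0 * 17.3)
        assert a == pytest.approx(b, rel=1e-12)

    def test_fully_intact_world_scores_one_everywhere(self, small_world):
        world = build_world(
            [make_species_row(), make_species_row(species_id="m1")],
            [simple_density("m0", 5.0), simple_density("m1", 2.0)],
            uniform_landscape(12, 12, land_use="rangeland", intensity=0.5),
        )
        layer = ecoflow.compute_energy_layers(world)
        summary = aggregation.flow_summary(
            layer, pd.Series({"m0": "g", "m1": "g"}), world.landscape
        )
        assert (summary["energetic_intactness"] == 1.0).all()


class TestRichness:
    def test_counts_overlapping_ranges(self):
        grids = {
            "a": np.ones((12, 12), bool),
            "b": np.ones((12, 12), bool),
            "c": np.zeros((12, 12), bool),
        }
        rich = aggregation.richness(grids)
        assert (rich["all"] == 2).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            aggregation.richness({})

    def test_per_class_counts_partition_total(self, small_world):
        from ecoflow.energetics import filtered_occupancy

        occ = filtered_occupancy(small_world)
        rich = aggregation.richness(occ, small_world.species)
        assert np.array_equal(rich["all"], rich["bird"] + rich["mammal"])


class TestDominance:
    def test_constructed_top_share(self):
        flows = [50.0] + [50.0 / 19] * 19  # one species holds half the total
        shares = aggregation.dominance_shares(flows, top_fraction=0.05)
        assert shares["top_share"] == pytest.approx(0.5)

    def test_equal_flows_give_proportional_share(self):
        shares = aggregation.dominance_shares(np.ones(20), top_fraction=0.05)
        assert shares["top_share"] == pytest.approx(0.05)

    def test_top_and_bottom_halves_partition(self):
        rng = np.random.default_rng(3)
        flows = rng.random(40)
        top = aggregation.dominance_shares(flows, top_fraction=0.5)["top_share"]
        bottom = aggregation.dominance_shares(flows, bottom_fraction=0.5)["bottom_share"]
        assert top + bottom == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            aggregation.dominance_shares(np.zeros(5))
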
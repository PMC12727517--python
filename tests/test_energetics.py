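"""Field metabolic rate, intake, annual flow and the composed species flow."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoflow import energetics, vocab
from ecoflow.core import ValidationError
from ecoflow.energetics import AllometricModel, AllometricParams, AssimilationLookup
from tests.conftest import build_world, make_species_row, simple_density, uniform_landscape

MODEL = AllometricModel()


class TestDee:
    def test_unit_mass_returns_coefficient(self):
        assert energetics.dee(1.0, MODEL, "mammal") == pytest.approx(MODEL.mammal.a)
        assert energetics.dee(1.0, MODEL, "bird") == pytest.approx(MODEL.bird.a)

    @pytest.mark.parametrize(
        "taxon,mass,a,b",
        [("mammal", 1000.0, 4.82, 0.734), ("bird", 100.0, 10.5, 0.681)],
    )
    def test_power_law_evaluation(self, taxon, mass, a, b):
        # independent evaluation through logarithms
        expected = math.exp(math.log(a) + b * math.log(mass))
        assert energetics.dee(mass, MODEL, taxon) == pytest.approx(expected, rel=1e-12)

    def test_known_magnitudes(self):
        assert energetics.dee(1000.0, MODEL, "mammal") == pytest.approx(767.3, abs=0.5)
        assert energetics.dee(100.0, MODEL, "bird") == pytest.approx(241.6, abs=0.5)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            energetics.dee(10.0, MODEL, "reptile")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            AllometricParams(a=-1.0, b=0.7)
        with pytest.raises(ValidationError):
            AllometricParams(a=1.0, b=1.5)


class TestGrossIntake:
    def test_single_food(self):
        diet = [0, 0, 0, 0, 0, 0, 1.0]
        ae = [1, 1, 1, 1, 1, 1, 0.5]
        assert energetics.gross_intake(100.0, diet, ae) == pytest.approx(200.0)

    def test_two_food_mix(self):
        # fruit/foliage half-and-half with AE 0.8/0.5: 100 * (0.5/0.5 + 0.5/0.8)
        diet = dict.fromkeys(vocab.FOOD_TYPES, 0.0)
        diet.update({"foliage": 0.5, "fruit": 0.5})
        ae = dict.fromkeys(vocab.FOOD_TYPES, 1.0)
        ae.update({"foliage": 0.5, "fruit": 0.8})
        got = energetics.gross_intake(
            100.0,
            [diet[f] for f in vocab.FOOD_TYPES],
            [ae[f] for f in vocab.FOOD_TYPES],
        )
        assert got == pytest.approx(162.5)

    def test_perfect_assimilation_identity(self):
        diet = np.full(7, 1 / 7)
        assert energetics.gross_intake(100.0, diet, np.ones(7)) == pytest.approx(100.0)

    def test_mean_ae_convention_differs(self):
        diet = dict.fromkeys(vocab.FOOD_TYPES, 0.0)
        diet.update({"foliage": 0.5, "fruit": 0.5})
        ae = dict.fromkeys(vocab.FOOD_TYPES, 1.0)
        ae.update({"foliage": 0.5, "fruit": 0.8})
        d = [diet[f] for f in vocab.FOOD_TYPES]
        a = [ae[f] for f in vocab.FOOD_TYPES]
        assert energetics.gross_intake(100.0, d, a, per_food=False) == pytest.approx(
            100.0 / 0.65
        )

    @given(st.lists(st.floats(min_value=0.3, max_value=1.0), min_size=7, max_size=7))
    @settings(derandomize=True, max_examples=30)
    def test_intake_never_below_expenditure(self, ae):
        diet = np.full(7, 1 / 7)
        assert energetics.gross_intake(50.0, diet, ae) >= 50.0 - 1e-9

    def test_off_simplex_diet_rejected(self):
        with pytest.raises(ValidationError):
            energetics.gross_intake(100.0, np.full(7, 0.1), np.ones(7))


class TestAssimilationLookup:
    def _table(self):
        return pd.DataFrame(
            [
                {"taxon_group": "mammal", "food_type": "foliage", "mean": 0.5, "sd": 0.1},
                {"taxon_group": "ordA", "food_type": "foliage", "mean": 0.6, "sd": 0.1},
                {"taxon_group": "famA", "food_type": "foliage", "mean": 0.7, "sd": 0.1},
            ]
        )

    def test_family_beats_order_beats_class(self):
        lookup = AssimilationLookup(self._table())
        sp = pd.Series(make_species_row(family="famA", order="ordA"))
        assert lookup.resolve(sp, "foliage")[0] == 0.7
        sp2 = pd.Series(make_species_row(family="famX", order="ordA"))
        assert lookup.resolve(sp2, "foliage")[0] == 0.6
        sp3 = pd.Series(make_species_row(family="famX", order="ordX"))
        assert lookup.resolve(sp3, "foliage")[0] == 0.5

    def test_missing_entry_names_species_and_food(self):
        lookup = AssimilationLookup(self._table())
        sp = pd.Series(make_species_row(species_id="gap", diet={"fruit": 1.0}))
        with pytest.raises(ValidationError, match="gap.*fruit"):
            lookup.vectors(sp)


class TestAnnualFlow:
    def test_unit_conversion(self):
        # 10 ind km^-2 * 1000 kJ day^-1 * 365 / 1e6 m^2 per km^2
        assert energetics.annual_flow_per_area(10, 1000) == pytest.approx(3.65)

    def test_zero_density_zero_flow(self):
        assert energetics.annual_flow_per_area(0, 1234.5) == 0.0

    def test_linear_in_density(self):
        assert energetics.annual_flow_per_area(20, 1000) == pytest.approx(
            2 * energetics.annual_flow_per_area(10, 1000)
        )

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            energetics.annual_flow_per_area(-1, 100)


class TestSpeciesCellFlow:
    def test_worked_chain(self):
        """1 kg mammal, AE 0.8, 10 ind km^-2: flow = 10*(dee/0.8)*365/1e6."""
        world = build_world(
            [make_species_row(mass_g=1000.0)],
            [simple_density("m0", 10.0)],
            uniform_landscape(),
        )
        layer = energetics.compute_energy_layers(world, MODEL)
        expected = 10.0 * (energetics.dee(1000.0, MODEL, "mammal") / 0.8) * 365 / 1e6
        assert layer.historical[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.501, abs=2e-3)

    def test_unoccupied_cells_have_zero_flow(self):
        ranges = {"m0": np.zeros((12, 12), dtype=bool)}
        ranges["m0"][:6, :6] = True
        world = build_world(
            [make_species_row()],
            [simple_density("m0", 10.0)],
            uniform_landscape(),
            ranges=ranges,
        )
        layer = energetics.compute_energy_layers(world, MODEL)
        assert (layer.historical[0, 6:, :] == 0).all()
        assert (layer.current[0, 6:, :] == 0).all()
        assert (layer.historical[0, :6, :6] > 0).all()

    def test_full_intactness_current_equals_historical(self):
        world = build_world(
            [make_species_row()], [simple_density("m0", 10.0)], uniform_landscape()
        )
        layer = energetics.compute_energy_layers(world, MODEL)
        assert np.array_equal(layer.historical, layer.current)

    def test_flow_increases_with_body_mass(self):
        flows = []
        for mass in (100.0, 1000.0, 10000.0):
            world = build_world(
                [make_species_row(mass_g=mass)],
                [simple_density("m0", 10.0)],
                uniform_landscape(),
            )
            flows.append(energetics.compute_energy_layers(world, MODEL).historical.max())
        assert flows[0] < flows[1] < flows[2]

    def test_density_override_hook(self):
        override = np.full((12, 12), 2.0)
        world = build_world(
            [make_species_row()], [simple_density("m0", 10.0)], uniform_landscape()
        )
        world.density_overrides["m0"] = override
        layer = energetics.compute_energy_layers(world, MODEL)
        base = build_world(
            [make_species_row()], [simple_density("m0", 2.0)], uniform_landscape()
        )
        expected = energetics.compute_energy_layers(base, MODEL)
        assert np.allclose(layer.historical, expected.historical, rtol=1e-12)
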
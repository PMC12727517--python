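"""Samplers, percentile intervals and the Monte Carlo engine."""

import numpy as np
import pandas as pd
import pytest

import ecoflow
from ecoflow import uncertainty, vocab
from ecoflow.core import ValidationError
from ecoflow.uncertainty import MonteCarloConfig
from tests.conftest import build_world, make_species_row, simple_density, uniform_landscape


class TestMassSampler:
    def test_draws_respect_lower_bound(self):
        cfg = MonteCarloConfig(n_sims=1, mass_sd_fraction=2.0)
        rng = np.random.default_rng(0)
        draws = uncertainty.sample_mass(2.0, cfg, rng, size=10_000)
        assert (draws >= cfg.mass_lower_bound_g).all()

    def test_zero_sd_returns_mean(self):
        cfg = MonteCarloConfig(n_sims=1, mass_sd_fraction=0.0)
        assert uncertainty.sample_mass(123.0, cfg, np.random.default_rng(0)) == 123.0

    def test_moments_far_from_truncation(self):
        cfg = MonteCarloConfig(n_sims=1)
        rng = np.random.default_rng(1)
        draws = uncertainty.sample_mass(100.0, cfg, rng, size=200_000)
        assert draws.mean() == pytest.approx(100.0, abs=0.15)
        assert draws.std() == pytest.approx(15.0, rel=0.01)


class TestBetaMomentMatching:
    def test_uniform_case(self):
        a, b = uncertainty.beta_from_mean_sd(0.5, np.sqrt(1 / 12))
        assert a == pytest.approx(1.0, rel=1e-9)
        assert b == pytest.approx(1.0, rel=1e-9)

    def test_zero_sd_degenerates_to_mean(self):
        assert uncertainty.draw_beta(0.37, 0.0, np.random.default_rng(0)) == 0.37

    def test_empirical_moments(self):
        rng = np.random.default_rng(2)
        draws = uncertainty.draw_beta(0.8, 0.05, rng, size=200_000)
        assert draws.mean() == pytest.approx(0.8, rel=0.005)
        assert draws.std() == pytest.approx(0.05, rel=0.02)

    def test_infeasible_sd_clamped_not_dropped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ecoflow.uncertainty"):
            a, b = uncertainty.beta_from_mean_sd(0.5, 10.0)
        assert a > 0 and b > 0
        assert any("clamped" in r.message for r in caplog.records)

    def test_mean_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            uncertainty.beta_from_mean_sd(1.5, 0.1)


class TestDietSampler:
    def test_single_food_diet_is_invariant(self):
        diet = np.array([0, 0, 0, 0, 0, 0, 1.0])
        out = uncertainty.sample_diet(diet, 0.1, np.random.default_rng(0), size=100)
        assert np.array_equal(out, np.tile(diet, (100, 1)))

    def test_zero_halfwidth_returns_input(self):
        diet = np.array([0.5, 0.5, 0, 0, 0, 0, 0])
        out = uncertainty.sample_diet(diet, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, diet)

    def test_symmetric_perturbation_preserves_means(self):
        diet = np.array([0.5, 0.5, 0, 0, 0, 0, 0])
        out = uncertainty.sample_diet(diet, 0.1, np.random.default_rng(3), size=200_000)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert out[:, 0].mean() == pytest.approx(0.5, abs=0.002)

    def test_zero_components_stay_zero(self):
        diet = np.array([0.7, 0.3, 0, 0, 0, 0, 0])
        out = uncertainty.sample_diet(diet, 0.2, np.random.default_rng(4), size=1000)
        assert (out[:, 2:] == 0).all()


class TestIntactnessSampler:
    def test_amplified_mean_supported(self):
        rng = np.random.default_rng(5)
        draws = uncertainty.sample_intactness(1.08, 0.1, 2.0, rng, size=200_000)
        assert ((draws >= 0) & (draws <= 2.0)).all()
        assert draws.mean() == pytest.approx(1.08, rel=0.005)

    def test_zero_sd_returns_mean(self):
        assert uncertainty.sample_intactness(0.4, 0.0, 2.0, np.random.default_rng(0)) == 0.4

    def test_zero_mean_always_zero(self):
        out = uncertainty.sample_intactness(0.0, 0.1, 2.0, np.random.default_rng(0), size=50)
        assert (out == 0).all()

    def test_mean_at_bound_rejected(self):
        with pytest.raises(ValidationError):
            uncertainty.sample_intactness(2.0, 0.1, 2.0, np.random.default_rng(0))


class TestDeeMultiplier:
    def test_zero_se_is_identity(self):
        assert uncertainty.sample_dee_multiplier(0.0, np.random.default_rng(0)) == 1.0

    def test_quantiles_match_lognormal(self):
        rng = np.random.default_rng(6)
        draws = uncertainty.sample_dee_multiplier(0.2, rng, size=200_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(10 ** (-1.959964 * 0.2), rel=0.02)
        assert hi == pytest.approx(10 ** (1.959964 * 0.2), rel=0.02)
        assert np.median(draws) == pytest.approx(1.0, abs=0.01)


class TestPercentileCi:
    def test_constant_samples_collapse(self):
        assert uncertainty.percentile_ci(np.full(100, 3.3)) == (3.3, 3.3)

    def test_linear_interpolation_formula(self):
        lo, hi = uncertainty.percentile_ci(np.arange(1, 1001))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_ordering(self):
        rng = np.random.default_rng(7)
        lo, hi = uncertainty.percentile_ci(rng.random(500))
        assert lo <= hi

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            uncertainty.percentile_ci([])


def _density_only_cfg(**kwargs):
    base = dict(
        n_sims=400,
        seed=11,
        use_mass=False,
        use_dee=False,
        use_ae=False,
        use_diet=False,
        use_intactness=False,
    )
    base.update(kwargs)
    return MonteCarloConfig(**base)


class TestEngine:
    def test_seeded_determinism(self, small_world):
        cfg = MonteCarloConfig(n_sims=50, seed=21)
        a = ecoflow.run_monte_carlo(small_world, cfg)
        b = ecoflow.run_monte_carlo(small_world, cfg)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_small_sim_count_warns(self, small_world):
        with pytest.warns(UserWarning, match="n_sims"):
            ecoflow.run_monte_carlo(small_world, MonteCarloConfig(n_sims=10, seed=0))

    def test_mean_preservation_density_only(self):
        """With a median-centred log-normal sampler the MC mean of the flow
        matches the deterministic point estimate (which uses the log-normal
        mean) within Monte Carlo error."""
        world = build_world(
            [make_species_row()],
            [simple_density("m0", 10.0, sigma_ln=0.4)],
            uniform_landscape(),
        )
        res = ecoflow.run_monte_carlo(world, _density_only_cfg(n_sims=4000))
        row = res.summary.query("grouping == 'total' and stratum == 'all'").iloc[0]
        se = row.point_historical * 0.4 * 2 / np.sqrt(4000)  # rough MC se
        assert abs(row.mc_mean_historical - row.point_historical) < 3 * se

    def test_current_ci_reflects_intactness_draws(self):
        intactness_rows = [
            {"response_group": "rg", "land_use": lu, "mean": 0.6, "sd": 0.1}
            for lu in vocab.LAND_USES
        ]
        world = build_world(
            [make_species_row()],
            [simple_density("m0", 10.0)],
            uniform_landscape(),
            intactness_rows=intactness_rows,
        )
        cfg = MonteCarloConfig(
            n_sims=2000, seed=3, use_mass=False, use_dee=False, use_ae=False,
            use_diet=False, use_density=False,
        )
        res = ecoflow.run_monte_carlo(world, cfg)
        row = res.summary.query("grouping == 'total' and stratum == 'all'").iloc[0]
        assert row.historical_ci_low == row.historical_ci_high  # no draw touches historical
        assert row.intactness_ci_low < 0.6 < row.intactness_ci_high
        assert row.intactness_mc_mean == pytest.approx(0.6, abs=0.02)
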
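"""Shared fixtures: small synthetic worlds and hand-built degenerate worlds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ecoflow import synthetic, vocab
from ecoflow.core import Landscape, WorldData


@pytest.fixture(scope="session")
def small_spec() -> synthetic.WorldSpec:
    return synthetic.WorldSpec(
        n_bird_species=12, n_mammal_species=8, grid_rows=12, grid_cols=12, seed=3
    )


@pytest.fixture(scope="session")
def small_world(small_spec) -> WorldData:
    return synthetic.generate_world(small_spec)


def make_species_row(
    species_id: str = "m0",
    taxon_class: str = "mammal",
    mass_g: float = 1000.0,
    diet: dict[str, float] | None = None,
    lifestyle: str = "terrestrial",
    herd_size: float = 1.0,
    grass_fraction: float = float("nan"),
    large_herbivore: bool = False,
    response_group: str = "rg",
    habitat_biomes: str = "grassy",
    family: str = "fam",
    order: str = "ord",
) -> dict:
    diet = diet or {"foliage": 1.0}
    row = {
        "species_id": species_id,
        "taxon_class": taxon_class,
        "family": family,
        "order": order,
        "body_mass_g": mass_g,
        **{c: 0.0 for c in vocab.DIET_COLUMNS},
        "lifestyle": lifestyle,
        "herd_size": herd_size,
        "grass_fraction": grass_fraction,
        "large_herbivore": large_herbivore,
        "response_group": response_group,
        "habitat_biomes": habitat_biomes,
    }
    for food, frac in diet.items():
        row[f"diet_{food}"] = frac
    return row


def uniform_landscape(
    rows: int = 12,
    cols: int = 12,
    biome: str = "grassy",
    land_use: str = "near_natural",
    intensity: float = 0.0,
) -> Landscape:
    lu_code = vocab.landuse_code(land_use)
    return Landscape(
        biome=np.full((rows, cols), vocab.biome_code(biome), dtype=np.int8),
        land_use=np.full((rows, cols), lu_code, dtype=np.int8),
        intensity=np.full((rows, cols), float(intensity)),
        protected=np.full((rows, cols), land_use == "strict_protected"),
    )


def build_world(
    species_rows: list[dict],
    density_rows: list[dict],
    landscape: Landscape,
    ae_rows: list[dict] | None = None,
    intactness_rows: list[dict] | None = None,
    ranges: dict[str, np.ndarray] | None = None,
) -> WorldData:
    """Assemble a WorldData bundle from explicit pieces, with easy defaults.

    Defaults: AE 0.8 (sd 0) for every class/food pair; intactness 1 (sd 0)
    for every response group and land use; full-grid ranges.
    """
    species = pd.DataFrame(species_rows)
    if ae_rows is None:
        ae_rows = [
            {"taxon_group": tc, "food_type": f, "mean": 0.8, "sd": 0.0}
            for tc in vocab.TAXON_CLASSES
            for f in vocab.FOOD_TYPES
        ]
    if intactness_rows is None:
        groups = sorted(set(species["response_group"]))
        intactness_rows = [
            {"response_group": g, "land_use": lu, "mean": 1.0, "sd": 0.0}
            for g in groups
            for lu in vocab.LAND_USES
        ]
    if ranges is None:
        ranges = {
            str(s): np.ones(landscape.shape, dtype=bool) for s in species["species_id"]
        }
    return WorldData(
        species=species,
        densities=pd.DataFrame(density_rows),
        assimilation=pd.DataFrame(ae_rows),
        intactness=pd.DataFrame(intactness_rows),
        landscape=landscape,
        ranges=ranges,
    )


def simple_density(species_id: str, median: float, sigma_ln: float = 0.0) -> dict:
    """Density row with a log-scale sd expressed through its 95% interval."""
    h = sigma_ln * vocab.Z95
    return {
        "species_id": species_id,
        "median": median,
        "ci_low": median * np.exp(-h),
        "ci_high": median * np.exp(h),
    }
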
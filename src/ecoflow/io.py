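"""Readers and writers for every table and raster the pipeline touches.

Tables are UTF-8 CSV with headers; rasters are Esri ASCII grids on the
shared nested lattice. Reading validates against the controlled
vocabularies and collects *all* violations before raising, so a broken
bundle reports every problem at once.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .core import Landscape, ValidationError, WorldData
from .grids import GridSpec, read_ascii_grid, write_ascii_grid

SPECIES_REQUIRED = (
    "species_id",
    "taxon_class",
    "family",
    "order",
    "body_mass_g",
    *vocab.DIET_COLUMNS,
    "lifestyle",
    "herd_size",
    "grass_fraction",
    "large_herbivore",
    "response_group",
    "habitat_biomes",
)

DIET_SUM_TOLERANCE = 1e-6


def read_species_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    errors = validate_species_table(table)
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return table


def validate_species_table(table: pd.DataFrame) -> list[str]:
    errors = []
    missing = [c for c in SPECIES_REQUIRED if c not in table.columns]
    if missing:
        return [f"missing columns {missing}"]
    if table["species_id"].duplicated().any():
        dupes = table.loc[table["species_id"].duplicated(), "species_id"].tolist()
        errors.append(f"duplicate species ids {dupes}")
    bad_class = set(table["taxon_class"]) - set(vocab.TAXON_CLASSES)
    if bad_class:
        errors.append(f"unknown taxon classes {sorted(bad_class)}")
    bad_life = set(table["lifestyle"]) - set(vocab.LIFESTYLES)
    if bad_life:
        errors.append(f"unknown lifestyles {sorted(bad_life)}")
    if (table["body_mass_g"] <= 0).any():
        rows = table.index[table["body_mass_g"] <= 0].tolist()
        errors.append(f"non-positive body mass in rows {rows}")
    sums = table[list(vocab.DIET_COLUMNS)].sum(axis=1)
    off = table.index[(sums - 1.0).abs() > DIET_SUM_TOLERANCE]
    for i in off:
        errors.append(
            f"diet fractions for {table.loc[i, 'species_id']!r} sum to {sums[i]:.6f}"
        )
    for i, sp in table.iterrows():
        habitats = set(str(sp["habitat_biomes"]).split("|"))
        unknown = habitats - set(vocab.BIOMES)
        if unknown:
            errors.append(
                f"species {sp['species_id']!r} has unknown habitat biomes {sorted(unknown)}"
            )
    return errors


def read_density_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"species_id", "median", "ci_low", "ci_high"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = table.index[
        (table["ci_low"] <= 0)
        | (table["ci_low"] > table["median"])
        | (table["median"] > table["ci_high"])
    ]
    if len(bad):
        ids = table.loc[bad, "species_id"].tolist()
        raise ValidationError(
            f"{path}: density bounds must satisfy 0 < ci_low <= median <= ci_high "
            f"for species {ids}"
        )
    return table


def read_assimilation_csv(path: str | Path) -> pd.DataFrame:
    from .energetics import AssimilationLookup

    table = pd.read_csv(path)
    AssimilationLookup(table)  # validates
    return table


def read_intactness_csv(path: str | Path) -> pd.DataFrame:
    from .abundance import IntactnessLookup

    table = pd.read_csv(path)
    IntactnessLookup(table)  # validates
    return table


# ---------------------------------------------------------------------------
# landscape + range rasters

_LANDSCAPE_FILES = {
    "biome": "biome.asc",
    "land_use": "land_use.asc",
    "intensity": "intensity.asc",
    "protected": "protected.asc",
}


def write_landscape(landscape: Landscape, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(out / "biome.asc", landscape.biome.astype(float))
    write_ascii_grid(out / "land_use.asc", landscape.land_use.astype(float))
    write_ascii_grid(out / "intensity.asc", landscape.intensity)
    write_ascii_grid(out / "protected.asc", landscape.protected.astype(float))


def read_landscape(in_dir: str | Path) -> Landscape:
    d = Path(in_dir)
    arrays = {}
    for key, fname in _LANDSCAPE_FILES.items():
        arrays[key], _ = read_ascii_grid(d / fname)
    return Landscape(
        biome=arrays["biome"].astype(np.int8),
        land_use=arrays["land_use"].astype(np.int8),
        intensity=arrays["intensity"],
        protected=arrays["protected"].astype(bool),
    )


def write_ranges(ranges: dict[str, np.ndarray], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, grid in ranges.items():
        write_ascii_grid(out / f"{sid}.asc", np.asarray(grid, dtype=float))


def read_ranges(in_dir: str | Path) -> dict[str, np.ndarray]:
    out = {}
    for path in sorted(Path(in_dir).glob("*.asc")):
        values, _ = read_ascii_grid(path)
        out[path.stem] = values.astype(bool)
    return out


# ---------------------------------------------------------------------------
# whole bundles


def write_world(world: WorldData, out_dir: str | Path) -> None:
    """Write a complete input bundle in the layout the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.species.to_csv(out / "species.csv", index=False)
    world.densities.to_csv(out / "densities.csv", index=False)
    world.assimilation.to_csv(out / "assimilation.csv", index=False)
    world.intactness.to_csv(out / "intactness.csv", index=False)
    write_landscape(world.landscape, out / "landscape")
    write_ranges(world.ranges, out / "ranges")


def read_world(in_dir: str | Path) -> WorldData:
    d = Path(in_dir)
    world = WorldData(
        species=read_species_csv(d / "species.csv"),
        densities=read_density_csv(d / "densities.csv"),
        assimilation=read_assimilation_csv(d / "assimilation.csv"),
        intactness=read_intactness_csv(d / "intactness.csv"),
        landscape=read_landscape(d / "landscape"),
        ranges=read_ranges(d / "ranges"),
    )
    errors = cross_validate(world)
    if errors:
        raise ValidationError(f"{d}: " + "; ".join(errors))
    return world


def cross_validate(world: WorldData) -> list[str]:
    """Exhaustive cross-reference checks over a loaded bundle."""
    from .energetics import AssimilationLookup

    errors: list[str] = []
    ids = set(world.species["species_id"].astype(str))
    dens_ids = set(world.densities["species_id"].astype(str))
    for sid in sorted(ids - dens_ids):
        errors.append(f"species {sid!r} has no density row")
    intact_groups = set(world.intactness["response_group"].astype(str))
    tabled = {
        (str(r.response_group), str(r.land_use)) for r in world.intactness.itertuples()
    }
    ae_lookup = AssimilationLookup(world.assimilation)
    for _, sp in world.species.iterrows():
        sid = str(sp["species_id"])
        rg = str(sp["response_group"])
        if rg not in intact_groups:
            errors.append(f"species {sid!r} response group {rg!r} not in intactness table")
        else:
            missing_lu = [lu for lu in vocab.LAND_USES if (rg, lu) not in tabled]
            if missing_lu:
                errors.append(f"response group {rg!r} missing land uses {missing_lu}")
        for food, col in zip(vocab.FOOD_TYPES, vocab.DIET_COLUMNS):
            if float(sp[col]) > 0:
                try:
                    ae_lookup.resolve(sp, food)
                except ValidationError as err:
                    errors.append(str(err))
        if sid not in world.ranges:
            errors.append(f"species {sid!r} has no range grid")
        elif world.ranges[sid].shape != world.landscape.shape:
            errors.append(
                f"range grid for {sid!r} is {world.ranges[sid].shape}, "
                f"landscape is {world.landscape.shape}"
            )
    return sorted(set(errors))


# ---------------------------------------------------------------------------
# outputs


def export_layers(
    out_dir: str | Path,
    layer,
    species: pd.DataFrame,
    spec: GridSpec | None = None,
) -> None:
    """Per-taxon historical/current flow and energetic-intactness rasters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxon = dict(zip(species["species_id"].astype(str), species["taxon_class"]))
    is_bird = np.array([taxon[s] == "bird" for s in layer.species_ids])
    for name, mask in (("bird", is_bird), ("mammal", ~is_bird)):
        hist = layer.historical[mask].sum(axis=0)
        cur = layer.current[mask].sum(axis=0)
        write_ascii_grid(out / f"historical_flow_{name}.asc", hist, spec)
        write_ascii_grid(out / f"current_flow_{name}.asc", cur, spec)
        with np.errstate(invalid="ignore", divide="ignore"):
            intact = np.where(hist > 0, cur / np.where(hist > 0, hist, 1.0), -9999.0)
        write_ascii_grid(out / f"energetic_intactness_{name}.asc", intact, spec)


def config_digest(payload: dict) -> str:
    """Stable hash of a run configuration for output provenance metadata."""
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_run_metadata(out_dir: str | Path, payload: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dict(payload)
    meta["config_hash"] = config_digest(payload)
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
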
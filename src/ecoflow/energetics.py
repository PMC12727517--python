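"""Per-species energetics: field metabolic rate, food intake, energy flow.

Daily energy expenditure (DEE) follows a field-metabolic-rate power law
a * M^b per taxonomic class. Gross food intake divides each food type's
share of assimilated energy by its assimilation efficiency (AE), resolved
per species with family -> order -> class precedence. Annual energy flow
per unit area converts density (ind km^-2) and gross intake (kJ day^-1)
to kJ m^-2 yr^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abundance, vocab
from .core import EnergyLayer, ValidationError, WorldData

DAYS_PER_YEAR = 365.0
KM2_TO_M2 = 1.0e6


@dataclass(frozen=True)
class AllometricParams:
    """One class's field-metabolic-rate power law: DEE = a * mass_g^b."""

    a: float  # kJ day^-1 at 1 g
    b: float  # unitless exponent
    residual_se_log10: float = 0.0  # regression scatter, log10 kJ day^-1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError("allometric coefficient a must be > 0")
        if not 0 < self.b < 1.2:
            raise ValidationError("allometric exponent b must lie in (0, 1.2)")
        if self.residual_se_log10 < 0:
            raise ValidationError("residual_se_log10 must be >= 0")


@dataclass(frozen=True)
class AllometricModel:
    """Field-metabolic-rate laws per taxonomic class.

    Defaults are classic eutherian-mammal and bird field-metabolic-rate
    fits (mammals 4.82 * M^0.734, birds 10.5 * M^0.681 kJ day^-1 with M in
    grams); both are plain config values and are replaced wholesale when a
    run supplies its own equations.
    """

    mammal: AllometricParams = field(
        default_factory=lambda: AllometricParams(4.82, 0.734, 0.15)
    )
    bird: AllometricParams = field(
        default_factory=lambda: AllometricParams(10.5, 0.681, 0.15)
    )

    def params(self, taxon_class: str) -> AllometricParams:
        if taxon_class == "mammal":
            return self.mammal
        if taxon_class == "bird":
            return self.bird
        raise ValidationError(f"unknown taxon class {taxon_class!r}")


def dee(mass_g, model: AllometricModel, taxon_class: str):
    """Daily energy expenditure (kJ day^-1) from body mass (g)."""
    mass = np.asarray(mass_g, dtype=float)
    if np.any(mass <= 0):
        raise ValidationError("body mass must be > 0")
    p = model.params(taxon_class)
    out = p.a * mass**p.b
    return float(out) if out.ndim == 0 else out


class AssimilationLookup:
    """AE means/sds keyed by (taxon_group, food_type) with fallback.

    ``taxon_group`` rows may name a family, an order or a class; per
    species the lookup tries its family first, then its order, then its
    class, and raises naming the species and food type if none resolves.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"taxon_group", "food_type", "mean", "sd"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"AE table missing columns {sorted(missing)}")
        bad_food = set(table["food_type"]) - set(vocab.FOOD_TYPES)
        if bad_food:
            raise ValidationError(f"AE table has unknown food types {sorted(bad_food)}")
        if ((table["mean"] <= 0) | (table["mean"] > 1)).any():
            raise ValidationError("AE means must lie in (0, 1]")
        if (table["sd"] < 0).any():
            raise ValidationError("AE sds must be >= 0")
        self.table = table
        self._entries = {
            (r.taxon_group, r.food_type): (float(r.mean), float(r.sd))
            for r in table.itertuples()
        }

    def resolve(self, species: pd.Series, food_type: str) -> tuple[float, float]:
        """(mean, sd) for one species and food type, family > order > class."""
        for level in ("family", "order", "taxon_class"):
            group = species.get(level)
            if group is None or (isinstance(group, float) and np.isnan(group)):
                continue
            entry = self._entries.get((str(group), food_type))
            if entry is not None:
                return entry
        raise ValidationError(
            f"no assimilation efficiency for species {species.get('species_id')!r}, "
            f"food type {food_type!r} (tried family/order/class fallback)"
        )

    def vectors(self, species: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        """AE mean and sd vectors over the food vocabulary for one species.

        Only food types the species actually eats need to resolve; unused
        types default to AE 1 (they carry zero diet weight).
        """
        means = np.ones(len(vocab.FOOD_TYPES))
        sds = np.zeros(len(vocab.FOOD_TYPES))
        for i, (food, col) in enumerate(zip(vocab.FOOD_TYPES, vocab.DIET_COLUMNS)):
            if float(species[col]) > 0:
                means[i], sds[i] = self.resolve(species, food)
        return means, sds


def gross_intake(dee_kj_day, diet_fractions, ae_values, per_food: bool = True):
    """Gross food intake (kJ day^-1) from DEE, diet shares and AE values.

    With ``per_food=True`` (default) each food type supplies its diet
    share of assimilated energy, so gross intake is
    sum_i p_i * DEE / AE_i; energy bookkeeping then closes exactly per
    food type. With ``per_food=False`` the alternative arithmetic-mean-AE
    convention DEE / sum_i p_i AE_i is used.
    """
    p = np.asarray(diet_fractions, dtype=float)
    ae = np.asarray(ae_values, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"diet fractions sum to {p.sum()!r}, expected 1")
    if np.any((ae <= 0) | (ae > 1)):
        raise ValidationError("AE values must lie in (0, 1]")
    if per_food:
        return float(dee_kj_day * float((p / ae).sum()))
    return float(dee_kj_day / float((p * ae).sum()))


def annual_flow_per_area(density_ind_km2, gross_intake_kj_day):
    """Annual energy flow density: ind km^-2 * kJ day^-1 -> kJ m^-2 yr^-1."""
    d = np.asarray(density_ind_km2, dtype=float)
    g = np.asarray(gross_intake_kj_day, dtype=float)
    if np.any(d < 0) or np.any(g < 0):
        raise ValidationError("density and intake must be >= 0")
    out = d * g * DAYS_PER_YEAR / KM2_TO_M2
    return float(out) if out.ndim == 0 else out


def species_cell_flow(
    species: pd.Series,
    density_mean: float,
    occupancy: np.ndarray,
    intactness_factors: np.ndarray,
    model: AllometricModel,
    ae_lookup: AssimilationLookup,
    density_override: np.ndarray | None = None,
    per_food: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Historical and current per-cell flow grids for one species.

    Flow is zero off the occupancy grid; current flow multiplies the
    historical flow by the per-cell intactness factor. ``density_override``
    substitutes a per-cell density raster for the range-wide constant.
    """
    expenditure = dee(float(species["body_mass_g"]), model, str(species["taxon_class"]))
    diet = np.array([float(species[c]) for c in vocab.DIET_COLUMNS])
    ae_means, _ = ae_lookup.vectors(species)
    intake = gross_intake(expenditure, diet, ae_means, per_food=per_food)
    if density_override is not None:
        dens = np.asarray(density_override, dtype=float)
    else:
        dens = np.full(occupancy.shape, float(density_mean))
    hist = np.where(occupancy, annual_flow_per_area(dens, intake), 0.0)
    cur = hist * intactness_factors
    return hist, cur


def per_species_energetics(
    world: WorldData, model: AllometricModel, per_food: bool = True
) -> pd.DataFrame:
    """Tidy per-species table: mass, density, DEE, intake, unit flow."""
    ae_lookup = AssimilationLookup(world.assimilation)
    dens = abundance.add_density_means(world.densities).set_index("species_id")
    rows = []
    for _, sp in world.species.iterrows():
        expenditure = dee(float(sp["body_mass_g"]), model, str(sp["taxon_class"]))
        diet = np.array([float(sp[c]) for c in vocab.DIET_COLUMNS])
        ae_means, _ = ae_lookup.vectors(sp)
        intake = gross_intake(expenditure, diet, ae_means, per_food=per_food)
        d = float(dens.loc[sp["species_id"], "mean"])
        rows.append(
            {
                "species_id": sp["species_id"],
                "taxon_class": sp["taxon_class"],
                "body_mass_g": float(sp["body_mass_g"]),
                "density_ind_km2": d,
                "dee_kj_day": expenditure,
                "gross_intake_kj_day": intake,
                "flow_kj_m2_yr": annual_flow_per_area(d, intake),
            }
        )
    return pd.DataFrame(rows)


def compute_energy_layers(
    world: WorldData,
    model: AllometricModel | None = None,
    per_food: bool = True,
) -> EnergyLayer:
    """Run the deterministic point-estimate pipeline for a whole world.

    Builds habitat-filtered occupancy from raw ranges, log-normal mean
    densities from the density table, per-species intake from traits and
    AE, per-cell intactness factors from the landscape, and returns the
    species-by-cell historical and current flow layers.
    """
    model = model or AllometricModel()
    ae_lookup = AssimilationLookup(world.assimilation)
    intact = abundance.IntactnessLookup(world.intactness)
    dens = abundance.add_density_means(world.densities).set_index("species_id")
    ids = world.species_ids()
    shape = world.landscape.shape
    hist = np.zeros((len(ids), *shape))
    cur = np.zeros_like(hist)
    factor_cache: dict[str, np.ndarray] = {}
    for i, (_, sp) in enumerate(world.species.iterrows()):
        sid = str(sp["species_id"])
        habitat = set(str(sp["habitat_biomes"]).split("|"))
        occ = abundance.habitat_filter_range(
            world.ranges[sid], world.landscape.biome, habitat
        )
        rg = str(sp["response_group"])
        if rg not in factor_cache:
            factor_cache[rg] = intact.factor_grid(rg, world.landscape)
        hist[i], cur[i] = species_cell_flow(
            sp,
            float(dens.loc[sid, "mean"]),
            occ,
            factor_cache[rg],
            model,
            ae_lookup,
            density_override=world.density_overrides.get(sid),
            per_food=per_food,
        )
    return EnergyLayer(ids, hist, cur)


def filtered_occupancy(world: WorldData) -> dict[str, np.ndarray]:
    """Habitat-filtered occupancy grid per species (block-broadcast)."""
    out = {}
    for _, sp in world.species.iterrows():
        sid = str(sp["species_id"])
        habitat = set(str(sp["habitat_biomes"]).split("|"))
        out[sid] = abundance.habitat_filter_range(
            world.ranges[sid], world.landscape.biome, habitat
        )
    return out
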
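"""Synthetic world generation and a brute-force ground-truth oracle.

This module fabricates complete, internally consistent input bundles --
species pools with traits and diets, nested-lattice landscapes, density
observation tables with 95% intervals, response-group intactness tables
and rectangular range grids -- so the entire pipeline runs at desk scale
with no external data. Statistical structure mirrors the real inputs
(log-normal densities with wide intervals, simplex diets, per-land-use
intactness means/sds, 1/12 -> 1/2 -> 1 degree lattice nesting); no real
biogeography is imitated.

The ground-truth oracle recomputes energy flows with naive per-species,
per-cell Python loops and no shared code with the vectorized pipeline, so
tests can demand exact (1e-9 relative) agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classification, vocab
from .core import Landscape, ValidationError, WorldData
from .energetics import AllometricModel

_DEFAULT_BIOME_MIX = {"forest": 0.35, "grassy": 0.40, "arid": 0.20, "excluded": 0.05}
_DEFAULT_LANDUSE_MIX = {
    "strict_protected": 0.08,
    "near_natural": 0.25,
    "rangeland": 0.30,
    "intensive_cropland": 0.08,
    "smallholder_cropland": 0.12,
    "tree_cropland": 0.04,
    "timber_plantation": 0.03,
    "dense_settlement": 0.06,
    "urban": 0.04,
}

# substream tags so each generator op has its own independent, named stream
_STREAM_POOL = 1
_STREAM_LANDSCAPE = 2
_STREAM_DENSITY = 3
_STREAM_INTACTNESS = 4
_STREAM_RANGES = 5


@dataclass(frozen=True)
class WorldSpec:
    """Size, composition and seed of a synthetic world."""

    n_bird_species: int = 30
    n_mammal_species: int = 20
    grid_rows: int = 36
    grid_cols: int = 36
    biome_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BIOME_MIX))
    landuse_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LANDUSE_MIX)
    )
    seed: int = 0
    bird_mass_range_g: tuple[float, float] = (5.0, 2.0e4)
    mammal_mass_range_g: tuple[float, float] = (5.0, 5.0e6)
    n_bird_response_groups: int = 5
    n_mammal_response_groups: int = 8
    density_noise_sd_log10: float = 0.3
    ci_halfwidth_range_log10: tuple[float, float] = (0.2, 2.5)

    def __post_init__(self) -> None:
        for name, n in (
            ("n_bird_species", self.n_bird_species),
            ("n_mammal_species", self.n_mammal_species),
        ):
            if n < 1:
                raise ValidationError(f"{name} must be >= 1, got {n}")
        if self.grid_rows % 12 or self.grid_cols % 12:
            raise ValidationError(
                f"grid dims ({self.grid_rows}, {self.grid_cols}) must be divisible by 12"
            )
        for name, mix, allowed in (
            ("biome_mix", self.biome_mix, set(vocab.BIOMES)),
            ("landuse_mix", self.landuse_mix, set(vocab.LAND_USES)),
        ):
            unknown = set(mix) - allowed
            if unknown:
                raise ValidationError(f"{name} has unknown keys {sorted(unknown)}")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name} sums to {total!r}, expected 1")
            if any(v < 0 for v in mix.values()):
                raise ValidationError(f"{name} has negative fractions")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


# lifestyle frequencies per class, loosely matching trait databases
_BIRD_LIFESTYLE_P = {
    "aerial": 0.15,
    "insessorial": 0.35,
    "terrestrial": 0.20,
    "arboreal": 0.15,
    "aquatic": 0.15,
}
_MAMMAL_LIFESTYLE_P = {
    "terrestrial": 0.45,
    "arboreal": 0.20,
    "fossorial": 0.15,
    "aerial": 0.10,
    "aquatic": 0.05,
    "insessorial": 0.05,
}
# probability a food type is the dominant diet component, per class
_BIRD_FOOD_P = {
    "invertebrate": 0.32,
    "seed": 0.18,
    "fruit": 0.15,
    "vertebrate": 0.10,
    "nectar": 0.08,
    "foliage": 0.12,
    "carrion": 0.05,
}
_MAMMAL_FOOD_P = {
    "foliage": 0.34,
    "fruit": 0.15,
    "invertebrate": 0.15,
    "vertebrate": 0.12,
    "seed": 0.12,
    "nectar": 0.05,
    "carrion": 0.07,
}


def _draw_diet(rng: np.random.Generator, food_p: dict[str, float]) -> dict[str, float]:
    """Sparse diet on the simplex: one dominant food plus up to two minors."""
    foods = list(food_p)
    probs = np.array([food_p[f] for f in foods])
    dominant = rng.choice(foods, p=probs / probs.sum())
    share = float(rng.uniform(0.45, 0.95))
    others = [f for f in foods if f != dominant]
    k = int(rng.integers(1, 3))
    minors = list(rng.choice(others, size=k, replace=False))
    weights = rng.dirichlet(np.full(k, 0.8))
    diet = dict.fromkeys(vocab.FOOD_TYPES, 0.0)
    diet[dominant] = share
    for m, w in zip(minors, weights):
        diet[m] = (1.0 - share) * float(w)
    return diet


def generate_species_pool(spec: WorldSpec) -> pd.DataFrame:
    """Trait table for a synthetic pool of bird and mammal species.

    Body masses are log-uniform over class-specific ranges; diets are
    sparse simplex vectors; lifestyles, response groups, herd sizes and
    grass fractions follow class-conditional distributions. True
    (latent) population densities follow a Damuth-style density-mass
    power law with log-normal scatter and are carried in the
    ``true_density`` column for oracle use; observation tables are
    produced separately by :func:`generate_density_observations`.
    """
    rng = spec.rng(_STREAM_POOL)
    rows = []
    per_class = (
        ("bird", spec.n_bird_species, spec.bird_mass_range_g, _BIRD_LIFESTYLE_P, _BIRD_FOOD_P, spec.n_bird_response_groups),
        ("mammal", spec.n_mammal_species, spec.mammal_mass_range_g, _MAMMAL_LIFESTYLE_P, _MAMMAL_FOOD_P, spec.n_mammal_response_groups),
    )
    for taxon, n, mass_range, life_p, food_p, n_groups in per_class:
        lo, hi = mass_range
        for i in range(n):
            mass = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
            lifestyles = list(life_p)
            lifestyle = str(
                rng.choice(lifestyles, p=np.array(list(life_p.values())) / sum(life_p.values()))
            )
            diet = _draw_diet(rng, food_p)
            n_habitats = int(rng.integers(1, 4))
            habitats = sorted(
                rng.choice(vocab.ANALYSIS_BIOMES, size=n_habitats, replace=False)
            )
            herd = float(max(1.0, round(10 ** rng.uniform(0, 2.5)))) if taxon == "mammal" else 1.0
            large_herb = (
                taxon == "mammal"
                and lifestyle == "terrestrial"
                and diet["foliage"] >= 0.5
                and mass >= 2.0e4
            )
            grass = float(rng.uniform(0, 1)) if large_herb else math.nan
            # Damuth-style density-mass scaling with 0.5 dex scatter
            intercept = 4.0 if taxon == "mammal" else 3.2
            log10_density = intercept - 0.75 * math.log10(mass) + rng.normal(0, 0.5)
            rows.append(
                {
                    "species_id": f"{taxon}_{i:03d}",
                    "taxon_class": taxon,
                    "family": f"{taxon}_fam{int(rng.integers(0, 5))}",
                    "order": f"{taxon}_ord{int(rng.integers(0, 3))}",
                    "body_mass_g": mass,
                    **{f"diet_{f}": diet[f] for f in vocab.FOOD_TYPES},
                    "lifestyle": lifestyle,
                    "herd_size": herd,
                    "grass_fraction": grass,
                    "large_herbivore": large_herb,
                    "response_group": f"{taxon}_rg{int(rng.integers(0, n_groups))}",
                    "habitat_biomes": "|".join(habitats),
                    "true_density": float(max(10**log10_density, 1e-4)),
                }
            )
    pool = pd.DataFrame(rows)
    sums = pool[list(vocab.DIET_COLUMNS)].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    return pool


def generate_landscape(spec: WorldSpec) -> Landscape:
    """Random landscape on the nested lattice.

    Historical biomes are drawn per 1/2-degree block (spatial coherence at
    the range-map grain); land-use classes are drawn independently per
    analysis cell from ``landuse_mix``, so realized class shares converge
    on the mix for large grids. Gradient-class cells get a uniform
    intensity in [0, 1]; categorical classes get 0 (protected,
    near-natural) or 1 (timber plantation).
    """
    rng = spec.rng(_STREAM_LANDSCAPE)
    rows, cols = spec.grid_rows, spec.grid_cols
    biomes = list(spec.biome_mix)
    bp = np.array([spec.biome_mix[b] for b in biomes])
    block_biomes = rng.choice(
        [vocab.biome_code(b) for b in biomes], size=(rows // 6, cols // 6), p=bp / bp.sum()
    )
    biome = np.repeat(np.repeat(block_biomes, 6, axis=0), 6, axis=1).astype(np.int8)
    uses = list(spec.landuse_mix)
    up = np.array([spec.landuse_mix[u] for u in uses])
    land_use = rng.choice(
        [vocab.landuse_code(u) for u in uses], size=(rows, cols), p=up / up.sum()
    ).astype(np.int8)
    intensity = rng.uniform(0, 1, size=(rows, cols))
    names = np.asarray(vocab.LAND_USES, dtype=object)[land_use]
    gradient = np.isin(names, sorted(vocab.GRADIENT_LAND_USES))
    intensity = np.where(gradient, intensity, 0.0)
    intensity[names == "timber_plantation"] = 1.0
    protected = names == "strict_protected"
    return Landscape(biome=biome, land_use=land_use, intensity=intensity, protected=protected)


def generate_density_observations(
    pool: pd.DataFrame,
    noise_sd_log10: float = 0.3,
    seed: int = 0,
    ci_halfwidth_range_log10: tuple[float, float] = (0.2, 2.5),
    noise_from_ci: bool = False,
) -> pd.DataFrame:
    """Observed density table (median + 95% CI) around the latent truth.

    Medians perturb the true density in log10 space; 95% interval
    half-widths (log10) are drawn uniformly from
    ``ci_halfwidth_range_log10``, whose default upper end matches the
    widest published intervals (2.5 orders of magnitude). With
    ``noise_from_ci=True`` each species' median error sd is the one its
    own reported interval implies, making the observation model exactly
    consistent with the uncertainty the interval claims (used by
    calibration tests).
    """
    if noise_sd_log10 < 0:
        raise ValidationError("noise_sd_log10 must be >= 0")
    rng = np.random.default_rng([int(seed), _STREAM_DENSITY])
    lo, hi = ci_halfwidth_range_log10
    rows = []
    for _, sp in pool.iterrows():
        truth = float(sp["true_density"])
        half = float(rng.uniform(lo, hi))
        sd = half / vocab.Z95 if noise_from_ci else noise_sd_log10
        median = truth * 10 ** rng.normal(0.0, sd)
        rows.append(
            {
                "species_id": sp["species_id"],
                "median": median,
                "ci_low": median / 10**half,
                "ci_high": median * 10**half,
            }
        )
    return pd.DataFrame(rows)


def generate_intactness_table(
    response_groups: list[str],
    landuses: tuple[str, ...] = vocab.LAND_USES,
    seed: int = 0,
    winners: bool = True,
) -> pd.DataFrame:
    """Response-group x land-use intactness means and sds.

    Strict protected areas are the intact reference (mean fixed at 1);
    other land uses draw group means from land-use-specific severity
    ranges. With ``winners=True`` some disturbance-tolerant groups get
    means above 1 in croplands or rangelands, mirroring species whose
    abundance increases under land-use change.
    """
    if not response_groups:
        raise ValidationError("response_groups must be nonempty")
    rng = np.random.default_rng([int(seed), _STREAM_INTACTNESS])
    severity = {
        "strict_protected": (1.0, 1.0),
        "near_natural": (0.85, 1.0),
        "rangeland": (0.5, 0.9),
        "intensive_cropland": (0.1, 0.5),
        "smallholder_cropland": (0.3, 0.7),
        "tree_cropland": (0.3, 0.8),
        "timber_plantation": (0.3, 0.8),
        "dense_settlement": (0.05, 0.4),
        "urban": (0.02, 0.3),
    }
    rows = []
    for group in response_groups:
        for lu in landuses:
            lo, hi = severity.get(lu, (0.2, 0.9))
            if lu == "strict_protected":
                mean, sd = 1.0, 0.02
            else:
                mean = float(rng.uniform(lo, hi))
                if winners and lu in ("intensive_cropland", "smallholder_cropland", "rangeland"):
                    if rng.uniform() < 0.15:
                        mean = float(rng.uniform(1.0, 1.3))
                sd = float(mean * rng.uniform(0.05, 0.2) + 0.01)
            rows.append({"response_group": group, "land_use": lu, "mean": mean, "sd": sd})
    table = pd.DataFrame(rows)
    if winners:
        # guarantee at least one amplified cell so "winner" behaviour is exercised
        if not (table["mean"] > 1).any():
            idx = table.index[table["land_use"] == "intensive_cropland"][0]
            table.loc[idx, "mean"] = 1.1
    return table


def generate_ranges(spec: WorldSpec, pool: pd.DataFrame) -> dict[str, np.ndarray]:
    """Raw (unfiltered) range grid per species: a random rectangle.

    Rectangles span from a single 1/2-degree block up to the whole grid
    (log-uniform edge lengths), so both restricted and wide-ranging
    species exist; habitat filtering happens downstream.
    """
    rng = spec.rng(_STREAM_RANGES)
    rows, cols = spec.grid_rows, spec.grid_cols
    out: dict[str, np.ndarray] = {}
    for sid in pool["species_id"]:
        h = int(round(10 ** rng.uniform(math.log10(6), math.log10(rows))))
        w = int(round(10 ** rng.uniform(math.log10(6), math.log10(cols))))
        h, w = min(h, rows), min(w, cols)
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - w + 1))
        grid = np.zeros((rows, cols), dtype=bool)
        grid[r0 : r0 + h, c0 : c0 + w] = True
        out[str(sid)] = grid
    return out


def generate_world(spec: WorldSpec, noise_from_ci: bool = False) -> WorldData:
    """Assemble a complete synthetic input bundle from one spec + seed."""
    pool = generate_species_pool(spec)
    landscape = generate_landscape(spec)
    densities = generate_density_observations(
        pool,
        noise_sd_log10=spec.density_noise_sd_log10,
        seed=spec.seed,
        ci_halfwidth_range_log10=spec.ci_halfwidth_range_log10,
        noise_from_ci=noise_from_ci,
    )
    groups = sorted(set(pool["response_group"]))
    intactness = generate_intactness_table(groups, seed=spec.seed)
    ranges = generate_ranges(spec, pool)
    from importlib import resources

    with resources.files("ecoflow.data").joinpath("assimilation_defaults.csv").open() as fh:
        ae_table = pd.read_csv(fh)
    return WorldData(
        species=pool.drop(columns=["true_density"]),
        densities=densities,
        assimilation=ae_table,
        intactness=intactness,
        landscape=landscape,
        ranges=ranges,
    )


@dataclass
class GroundTruth:
    """Brute-force per-species, per-cell flows plus group sums.

    Produced by naive loops with no vectorized shortcuts; used only as a
    test oracle.
    """

    species_ids: list[str]
    historical: np.ndarray  # (n_species, rows, cols)
    current: np.ndarray
    guild_historical: dict[str, np.ndarray]
    guild_current: dict[str, np.ndarray]


def ground_truth_energy(
    world: WorldData, model: AllometricModel | None = None
) -> GroundTruth:
    """Recompute the whole point-estimate pipeline with naive loops.

    Every step -- log-normal mean density, habitat filter with block
    aggregation and fallback, DEE power law, per-food intake, per-cell
    intactness with gradient interpolation -- is re-derived here with
    plain Python arithmetic over explicit loops.
    """
    model = model or AllometricModel()
    rows, cols = world.landscape.shape
    ids = world.species_ids()
    hist = np.zeros((len(ids), rows, cols))
    cur = np.zeros_like(hist)
    dens = world.densities.set_index("species_id")
    ae_entries = {
        (str(r.taxon_group), str(r.food_type)): float(r.mean)
        for r in world.assimilation.itertuples()
    }
    intact = {
        (str(r.response_group), str(r.land_use)): float(r.mean)
        for r in world.intactness.itertuples()
    }
    guilds = {
        str(sp["species_id"]): classification.assign_guild(sp)
        for _, sp in world.species.iterrows()
    }
    for si, (_, sp) in enumerate(world.species.iterrows()):
        sid = str(sp["species_id"])
        # log-normal mean density from median + 95% CI
        median = float(dens.loc[sid, "median"])
        lo, hi = float(dens.loc[sid, "ci_low"]), float(dens.loc[sid, "ci_high"])
        sigma = (math.log(hi) - math.log(lo)) / (2.0 * vocab.Z95)
        mean_density = median * math.exp(sigma * sigma / 2.0)
        # DEE and gross intake
        p = model.params(str(sp["taxon_class"]))
        dee_val = p.a * float(sp["body_mass_g"]) ** p.b
        intake = 0.0
        for food in vocab.FOOD_TYPES:
            frac = float(sp[f"diet_{food}"])
            if frac == 0.0:
                continue
            ae = None
            for level in ("family", "order", "taxon_class"):
                key = (str(sp[level]), food)
                if key in ae_entries:
                    ae = ae_entries[key]
                    break
            if ae is None:
                raise ValidationError(f"oracle: no AE for {sid}/{food}")
            intake += frac * dee_val / ae
        # habitat filter: block occupied iff any habitat cell survives
        habitats = set(str(sp["habitat_biomes"]).split("|"))
        habitat_codes = {vocab.biome_code(b) for b in habitats}
        raw = world.ranges[sid]
        any_habitat = False
        for r in range(rows):
            for c in range(cols):
                if raw[r, c] and int(world.landscape.biome[r, c]) in habitat_codes:
                    any_habitat = True
                    break
            if any_habitat:
                break
        occupied = np.zeros((rows, cols), dtype=bool)
        for br in range(rows // 6):
            for bc in range(cols // 6):
                block_occ = False
                for r in range(br * 6, br * 6 + 6):
                    for c in range(bc * 6, bc * 6 + 6):
                        if raw[r, c] and (
                            not any_habitat
                            or int(world.landscape.biome[r, c]) in habitat_codes
                        ):
                            block_occ = True
                if block_occ:
                    occupied[br * 6 : br * 6 + 6, bc * 6 : bc * 6 + 6] = True
        # per-cell flows
        rg = str(sp["response_group"])
        override = world.density_overrides.get(sid)
        for r in range(rows):
            for c in range(cols):
                if not occupied[r, c]:
                    continue
                d = float(override[r, c]) if override is not None else mean_density
                flow = d * intake * 365.0 / 1.0e6
                lu = vocab.LAND_USES[int(world.landscape.land_use[r, c])]
                m = intact[(rg, lu)]
                if lu in vocab.GRADIENT_LAND_USES:
                    nn = intact[(rg, "near_natural")]
                    factor = nn + (m - nn) * float(world.landscape.intensity[r, c])
                else:
                    factor = m
                hist[si, r, c] = flow
                cur[si, r, c] = flow * factor
    guild_hist: dict[str, np.ndarray] = {}
    guild_cur: dict[str, np.ndarray] = {}
    for si, sid in enumerate(ids):
        g = guilds[sid]
        guild_hist.setdefault(g, np.zeros((rows, cols)))
        guild_cur.setdefault(g, np.zeros((rows, cols)))
        guild_hist[g] += hist[si]
        guild_cur[g] += cur[si]
    return GroundTruth(
        species_ids=ids,
        historical=hist,
        current=cur,
        guild_historical=guild_hist,
        guild_current=guild_cur,
    )
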
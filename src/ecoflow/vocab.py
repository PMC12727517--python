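"""Controlled vocabularies shared across the pipeline.

Every categorical axis (food types, lifestyles, land-use classes, biomes)
is defined once here; tables read from disk are validated against these
sets before any computation runs.
"""

from __future__ import annotations

#: Food types making up a diet composition vector (fractions sum to 1).
FOOD_TYPES: tuple[str, ...] = (
    "invertebrate",
    "vertebrate",
    "carrion",
    "fruit",
    "nectar",
    "seed",
    "foliage",
)

#: Trait-table column names holding diet fractions.
DIET_COLUMNS: tuple[str, ...] = tuple(f"diet_{f}" for f in FOOD_TYPES)

#: Tie-break priority when two food types share the dominant diet fraction.
#: Earlier wins. Animal matter outranks plant matter so a 50/50
#: vertebrate/foliage mammal classifies as a carnivore, mirroring the
#: precautionary convention used for trophic-level assignment.
FOOD_PRIORITY: tuple[str, ...] = (
    "vertebrate",
    "invertebrate",
    "carrion",
    "foliage",
    "fruit",
    "seed",
    "nectar",
)

LIFESTYLES: tuple[str, ...] = (
    "terrestrial",
    "arboreal",
    "fossorial",
    "aerial",
    "aquatic",
    "insessorial",
)

TAXON_CLASSES: tuple[str, ...] = ("bird", "mammal")

#: The nine land-use classes at which species intactness is tabulated.
LAND_USES: tuple[str, ...] = (
    "strict_protected",
    "near_natural",
    "rangeland",
    "intensive_cropland",
    "smallholder_cropland",
    "tree_cropland",
    "timber_plantation",
    "dense_settlement",
    "urban",
)

#: Classes whose intactness scales along a land-use intensity gradient,
#: anchored at the near-natural mean at intensity 0. The remaining classes
#: (strict protected, near-natural, timber plantation) apply categorically.
GRADIENT_LAND_USES: frozenset[str] = frozenset(
    {
        "rangeland",
        "intensive_cropland",
        "smallholder_cropland",
        "tree_cropland",
        "dense_settlement",
        "urban",
    }
)

#: Historical (pre-land-use-change) biome of each cell. ``excluded`` marks
#: cells outside the study region (open water, bare rock); ``fynbos_thicket``
#: and ``mosaic`` exist so biome-stratified summaries can drop them.
BIOMES: tuple[str, ...] = (
    "forest",
    "grassy",
    "arid",
    "fynbos_thicket",
    "mosaic",
    "excluded",
)

#: Biomes entering biome-stratified flow summaries.
ANALYSIS_BIOMES: tuple[str, ...] = ("forest", "grassy", "arid")

#: Four-way land-use stratification used for headline comparisons.
ANALYSIS_LAND_USES: tuple[str, ...] = (
    "strict_protected",
    "settlements",
    "croplands",
    "unprotected_untransformed",
)

#: Body-size class bounds (grams). Strictly below the small bound is
#: "small"; strictly above the megafauna bound is "megafauna"; the bounds
#: themselves fall in "medium".
SMALL_MASS_G: float = 3_000.0
MEGAFAUNA_MASS_G: float = 65_000.0

SIZE_CLASSES: tuple[str, ...] = ("small", "medium", "megafauna")

#: Two-sided 95% normal quantile, kept at full precision rather than 2.
Z95: float = 1.959964


def biome_code(name: str) -> int:
    """Integer code for a biome name (raster encoding)."""
    return BIOMES.index(name)


def landuse_code(name: str) -> int:
    """Integer code for a land-use class name (raster encoding)."""
    return LAND_USES.index(name)
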
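"""Aggregation of species flows into group, biome and land-use summaries.

Guild totals partition the per-cell flow exactly; functional-group totals
may double-count species that perform several functions (by design, so
each function sees its full energy supply). Strata are the three
aggregated historical biomes (forest, grassy, arid; fynbos/thicket and
mosaic cells are excluded) and a four-way land-use classification
(strict protected, settlements, croplands, unprotected untransformed).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import vocab
from .core import EnergyLayer, Landscape, ValidationError


def cell_totals_by_group(
    layer: EnergyLayer, assignments, grouping: str = "guild"
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-cell (historical, current) totals per group.

    ``assignments`` is either a Series mapping species_id -> group (a
    partition: guilds, size classes, taxon classes) or a boolean
    species x group DataFrame (overlapping membership: functions). For
    partition groupings every species with flow must be assigned.
    """
    if isinstance(assignments, pd.Series):
        missing = [s for s in layer.species_ids if s not in assignments.index]
        if missing:
            raise ValidationError(
                f"{grouping} assignment missing species {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        membership = pd.get_dummies(assignments.loc[layer.species_ids])
    else:
        membership = assignments.loc[layer.species_ids].astype(bool)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for group in membership.columns:
        mask = membership[group].to_numpy()
        out[str(group)] = (
            layer.historical[mask].sum(axis=0),
            layer.current[mask].sum(axis=0),
        )
    return out


def map_landuse_to_analysis_class(
    land_use: np.ndarray,
    protected: np.ndarray,
    urban_share: np.ndarray,
    pop_density: np.ndarray,
    crop_share: np.ndarray,
    urban_threshold: float = 0.20,
    pop_threshold: float = 1000.0,
    crop_threshold: float = 0.20,
) -> np.ndarray:
    """Four-way land-use class per cell, evaluated in precedence order:

    strict protected areas; then settlements (> 20% urban cover or
    population density above 1,000 km^-2); then croplands (> 20% crop
    cover); remaining cells are unprotected untransformed land.
    Returns an object array of names from ``vocab.ANALYSIS_LAND_USES``.
    """
    out = np.full(np.shape(land_use), "unprotected_untransformed", dtype=object)
    crop = np.asarray(crop_share) > crop_threshold
    out[crop] = "croplands"
    settle = (np.asarray(urban_share) > urban_threshold) | (
        np.asarray(pop_density) > pop_threshold
    )
    out[settle] = "settlements"
    out[np.asarray(protected, dtype=bool)] = "strict_protected"
    return out


def analysis_landuse_grid(landscape: Landscape) -> np.ndarray:
    """Four-way land-use class per cell derived from the nine-class map.

    Urban and crop cover shares are proxied by land-use intensity within
    the urban/settlement and cropland classes respectively (the synthetic
    landscape carries no independent cover rasters); population density
    is not modelled and enters as zero.
    """
    names = landscape.landuse_names()
    urban_share = np.where(
        np.isin(names, ("urban", "dense_settlement")), landscape.intensity, 0.0
    )
    crop_share = np.where(
        np.isin(names, ("intensive_cropland", "smallholder_cropland", "tree_cropland")),
        landscape.intensity,
        0.0,
    )
    return map_landuse_to_analysis_class(
        landscape.land_use,
        landscape.protected,
        urban_share,
        np.zeros(landscape.shape),
        crop_share,
    )


def stratified_mean(
    values: np.ndarray, labels: np.ndarray, include: np.ndarray | None = None
) -> dict[str, float]:
    """Unweighted mean of cell values per stratum label.

    ``include`` masks cells out of every stratum (e.g. excluded biomes or
    out-of-study cells). Empty strata are omitted from the result.
    """
    mask = np.ones(values.shape, dtype=bool) if include is None else np.asarray(include, bool)
    out = {}
    for label in pd.unique(np.asarray(labels)[mask].ravel()):
        sel = mask & (labels == label)
        if sel.any():
            out[str(label)] = float(values[sel].mean())
    return out


def biome_strata(landscape: Landscape) -> tuple[np.ndarray, np.ndarray]:
    """(labels, include mask) for biome-stratified summaries.

    Fynbos/thicket, mosaic and excluded cells are masked out.
    """
    names = landscape.biome_names()
    include = np.isin(names, vocab.ANALYSIS_BIOMES)
    return names, include


def energetic_intactness(current_sum: float, historical_sum: float) -> float:
    """Current / historical summed flow; may exceed 1; NaN when undefined.

    This is a ratio of sums (flows aggregated first), not a mean of
    per-cell ratios; groups with zero historical flow have no defined
    intactness and return NaN so callers can flag and exclude them.
    """
    if historical_sum < 0 or current_sum < 0:
        raise ValidationError("flow sums must be >= 0")
    if historical_sum == 0:
        return math.nan
    return current_sum / historical_sum


def richness(occupancy: dict[str, np.ndarray], species: pd.DataFrame | None = None) -> dict[str, np.ndarray]:
    """Per-cell species counts, total and per taxon class.

    Counts occurrences only; intactness plays no role.
    """
    grids = list(occupancy.values())
    if not grids:
        raise ValidationError("no occupancy grids supplied")
    shape = grids[0].shape
    out = {"all": np.zeros(shape, dtype=int)}
    for g in grids:
        out["all"] += np.asarray(g, dtype=bool)
    if species is not None:
        cls = dict(zip(species["species_id"].astype(str), species["taxon_class"]))
        for taxon in vocab.TAXON_CLASSES:
            acc = np.zeros(shape, dtype=int)
            for sid, g in occupancy.items():
                if cls.get(str(sid)) == taxon:
                    acc += np.asarray(g, dtype=bool)
            out[taxon] = acc
    return out


def dominance_shares(
    flows, top_fraction: float = 0.05, bottom_fraction: float = 0.5
) -> dict[str, float]:
    """Share of total flow by the top and bottom tails of the species rank.

    Species are sorted by flow descending; the top share covers the
    ceil(top_fraction * n) largest consumers and the bottom share the
    floor(bottom_fraction * n) smallest, making both deterministic.
    """
    arr = np.sort(np.asarray(flows, dtype=float))[::-1]
    if arr.size == 0 or np.any(arr < 0):
        raise ValidationError("flows must be nonnegative and nonempty")
    total = arr.sum()
    if total == 0:
        raise ValidationError("dominance shares undefined for all-zero flows")
    n_top = math.ceil(top_fraction * arr.size)
    n_bot = math.floor(bottom_fraction * arr.size)
    return {
        "top_share": float(arr[:n_top].sum() / total),
        "bottom_share": float(arr[arr.size - n_bot:].sum() / total) if n_bot else 0.0,
    }


def flow_summary(
    layer: EnergyLayer,
    assignments,
    landscape: Landscape,
    grouping: str = "guild",
) -> pd.DataFrame:
    """Tidy group x stratum table of mean flows and energetic intactness.

    Strata are "all" cells, the three aggregated biomes and the four
    analysis land uses. Means are unweighted over the included cells of
    each stratum; intactness is the ratio of the summed current to summed
    historical flow over those cells.
    """
    totals = cell_totals_by_group(layer, assignments, grouping)
    biome_labels, biome_ok = biome_strata(landscape)
    lu_labels = analysis_landuse_grid(landscape)
    in_study = landscape.analysis_mask()
    strata: list[tuple[str, np.ndarray]] = [("all", in_study)]
    for b in vocab.ANALYSIS_BIOMES:
        strata.append((f"biome:{b}", biome_ok & (biome_labels == b)))
    for lu in vocab.ANALYSIS_LAND_USES:
        strata.append((f"landuse:{lu}", in_study & (lu_labels == lu)))
    rows = []
    for group, (hist, cur) in totals.items():
        for name, mask in strata:
            if not mask.any():
                continue
            h, c = hist[mask], cur[mask]
            rows.append(
                {
                    "grouping": grouping,
                    "group": group,
                    "stratum": name,
                    "n_cells": int(mask.sum()),
                    "historical_mean_flow": float(h.mean()),
                    "current_mean_flow": float(c.mean()),
                    "energetic_intactness": energetic_intactness(float(c.sum()), float(h.sum())),
                }
            )
    return pd.DataFrame(rows)
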
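"""Historical and current species abundances.

Historical per-cell densities come from published median densities with
95% uncertainty intervals, converted to log-normal means, spread over
habitat-filtered range grids. Current densities multiply the historical
ones by a per-species, per-cell proportional-intactness factor looked up
from a response-group x land-use table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import vocab
from .core import BLOCK, Landscape, ValidationError


def lognormal_sigma_from_ci(ci_low, ci_high):
    """Log-scale (natural log) sd implied by a 95% interval of a log-normal."""
    ci_low = np.asarray(ci_low, dtype=float)
    ci_high = np.asarray(ci_high, dtype=float)
    return (np.log(ci_high) - np.log(ci_low)) / (2.0 * vocab.Z95)


def lognormal_mean_from_median_ci(median, ci_low, ci_high):
    """Mean of a log-normal given its median and 95% interval.

    sigma = (ln ci_high - ln ci_low) / (2 * 1.959964) and
    mean = median * exp(sigma^2 / 2); the mean exceeds the median whenever
    the interval has positive width (right-skew of the log-normal).
    Accepts scalars or aligned arrays.
    """
    median = np.asarray(median, dtype=float)
    ci_low = np.asarray(ci_low, dtype=float)
    ci_high = np.asarray(ci_high, dtype=float)
    if np.any(ci_low <= 0):
        raise ValidationError("ci_low must be positive")
    if np.any(ci_low > median) or np.any(median > ci_high):
        raise ValidationError("density bounds must satisfy 0 < ci_low <= median <= ci_high")
    sigma = lognormal_sigma_from_ci(ci_low, ci_high)
    out = median * np.exp(sigma**2 / 2.0)
    return float(out) if out.ndim == 0 else out


def add_density_means(densities: pd.DataFrame) -> pd.DataFrame:
    """Return the density table with a derived log-normal ``mean`` column."""
    out = densities.copy()
    out["mean"] = lognormal_mean_from_median_ci(
        out["median"].to_numpy(), out["ci_low"].to_numpy(), out["ci_high"].to_numpy()
    )
    return out


def habitat_filter_range(
    raw_range: np.ndarray,
    biome_map: np.ndarray,
    habitat_biomes: set[str] | frozenset[str],
) -> np.ndarray:
    """Filter a fine-resolution range by historical biome, at block grain.

    Fine (1/12-degree) cells whose historical biome is not among the
    species' habitat biomes are dropped; a 1/2-degree block stays occupied
    if at least one fine cell of habitat survives, and block occupancy is
    broadcast back to every analysis cell of the block. If filtering would
    empty the whole range, the unadjusted raw range (block-aggregated) is
    used instead, so no species loses its range to the filter.
    """
    raw_range = np.asarray(raw_range, dtype=bool)
    if raw_range.shape != biome_map.shape:
        raise ValidationError(
            f"range grid {raw_range.shape} and biome map {biome_map.shape} are misaligned"
        )
    codes = {vocab.biome_code(b) for b in habitat_biomes}
    habitat_ok = np.isin(biome_map, sorted(codes))
    filtered = raw_range & habitat_ok
    if not filtered.any():
        filtered = raw_range  # fallback: keep the unadjusted range
    return _broadcast_blocks(filtered)


def _broadcast_blocks(fine: np.ndarray) -> np.ndarray:
    """Block-aggregate (any) then broadcast back to analysis cells."""
    r, c = fine.shape
    blocks = fine.reshape(r // BLOCK, BLOCK, c // BLOCK, BLOCK).any(axis=(1, 3))
    return np.repeat(np.repeat(blocks, BLOCK, axis=0), BLOCK, axis=1)


class IntactnessLookup:
    """Response-group x land-use intactness factors, with gradient scaling.

    For categorical land uses the tabled mean applies directly; for
    gradient land uses (croplands, rangelands, settlements) the factor is
    interpolated linearly between the group's near-natural mean at
    intensity 0 and the tabled class mean at intensity 1. Factors may
    exceed 1 for disturbance-tolerant groups.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"response_group", "land_use", "mean", "sd"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"intactness table missing columns {sorted(missing)}")
        bad_lu = set(table["land_use"]) - set(vocab.LAND_USES)
        if bad_lu:
            raise ValidationError(f"intactness table has unknown land uses {sorted(bad_lu)}")
        if (table["mean"] < 0).any():
            raise ValidationError("intactness means must be >= 0")
        self.table = table
        self._mean = {
            (r.response_group, r.land_use): float(r.mean) for r in table.itertuples()
        }
        self._sd = {(r.response_group, r.land_use): float(r.sd) for r in table.itertuples()}

    def groups(self) -> list[str]:
        return sorted(set(self.table["response_group"]))

    def mean(self, response_group: str, land_use: str) -> float:
        try:
            return self._mean[(response_group, land_use)]
        except KeyError:
            raise ValidationError(
                f"no intactness entry for response group {response_group!r} "
                f"under land use {land_use!r}"
            ) from None

    def sd(self, response_group: str, land_use: str) -> float:
        return self._sd[(response_group, land_use)]

    def factor(self, response_group: str, land_use: str, intensity: float) -> float:
        """Point-estimate intactness factor for one cell."""
        m = self.mean(response_group, land_use)
        if land_use in vocab.GRADIENT_LAND_USES:
            nn = self.mean(response_group, "near_natural")
            return nn + (m - nn) * float(intensity)
        return m

    def factor_grid(self, response_group: str, landscape: Landscape) -> np.ndarray:
        """Per-cell intactness factors for one response group."""
        out = np.empty(landscape.shape, dtype=float)
        nn = self.mean(response_group, "near_natural")
        for code, name in enumerate(vocab.LAND_USES):
            mask = landscape.land_use == code
            if not mask.any():
                continue
            m = self.mean(response_group, name)
            if name in vocab.GRADIENT_LAND_USES:
                out[mask] = nn + (m - nn) * landscape.intensity[mask]
            else:
                out[mask] = m
        return out


def species_intactness_at_cell(
    species: pd.Series, land_use: str, intensity: float, table: IntactnessLookup
) -> float:
    """Intactness factor for one species in one cell."""
    return table.factor(str(species["response_group"]), land_use, intensity)


def contemporary_density(historical_density, intactness_factor):
    """Current density = historical density x proportional intactness.

    Both inputs must be nonnegative; factors above 1 (species that benefit
    from land-use change) yield densities above the historical baseline.
    """
    hist = np.asarray(historical_density, dtype=float)
    fac = np.asarray(intactness_factor, dtype=float)
    if np.any(hist < 0) or np.any(fac < 0):
        raise ValidationError("historical density and intactness factor must be >= 0")
    out = hist * fac
    return float(out) if out.ndim == 0 else out


def cell_bii(factors, clamp: bool = True) -> float:
    """Biodiversity intactness of one cell: equal-weight mean over species.

    Each species present contributes its proportional-intactness factor
    with equal weight. By default factors are clamped at 1 before
    averaging (standard intactness-index convention); pass ``clamp=False``
    to average raw factors.
    """
    arr = np.asarray(factors, dtype=float)
    if arr.size == 0:
        raise ValidationError("cell_bii undefined for a cell with no species present")
    if clamp:
        arr = np.minimum(arr, 1.0)
    return float(arr.mean())


def bii_grid(
    world_ranges: dict[str, np.ndarray],
    species: pd.DataFrame,
    lookup: IntactnessLookup,
    landscape: Landscape,
    clamp: bool = True,
    taxon_class: str | None = None,
) -> np.ndarray:
    """Per-cell biodiversity intactness over the species present.

    Cells where no species of the requested class occurs are NaN.
    """
    total = np.zeros(landscape.shape)
    count = np.zeros(landscape.shape)
    group_grids: dict[str, np.ndarray] = {}
    for row in species.itertuples():
        if taxon_class is not None and row.taxon_class != taxon_class:
            continue
        occ = world_ranges[row.species_id]
        rg = str(row.response_group)
        if rg not in group_grids:
            g = lookup.factor_grid(rg, landscape)
            group_grids[rg] = np.minimum(g, 1.0) if clamp else g
        total += np.where(occ, group_grids[rg], 0.0)
        count += occ
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out
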
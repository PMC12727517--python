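"""Shared in-memory containers: the nested lattice, landscapes and flow layers.

The analysis lattice is a grid of 1/12-degree cells (identified with the
8 km intactness cell). Cells nest exactly into 1/2-degree blocks (6 x 6
cells, the range-map resolution) and 1-degree squares (12 x 12 cells, the
unit of spatially independent natural variability), so grid dimensions
must be divisible by 12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vocab

BLOCK = 6  # analysis cells per 1/2-degree block edge
SQUARE = 12  # analysis cells per 1-degree square edge


class ValidationError(ValueError):
    """An input violated a documented invariant; the message names the field."""


@dataclass
class Landscape:
    """Per-cell historical biome, land use, intensity and protection.

    ``biome`` and ``land_use`` are integer-coded rasters (codes index
    :data:`ecoflow.vocab.BIOMES` / :data:`ecoflow.vocab.LAND_USES`);
    ``intensity`` is the land-use intensity in [0, 1]; ``protected`` flags
    strictly protected cells.
    """

    biome: np.ndarray
    land_use: np.ndarray
    intensity: np.ndarray
    protected: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.biome, self.land_use, self.intensity, self.protected)}
        if len(shapes) != 1:
            raise ValidationError(f"landscape rasters disagree on shape: {sorted(shapes)}")
        rows, cols = self.biome.shape
        if rows % SQUARE or cols % SQUARE:
            raise ValidationError(
                f"grid dims ({rows}, {cols}) must be divisible by {SQUARE} "
                "so 1/2-degree blocks and 1-degree squares nest exactly"
            )
        if self.intensity.min() < 0 or self.intensity.max() > 1:
            raise ValidationError("intensity outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.biome.shape

    @property
    def n_cells(self) -> int:
        return self.biome.size

    @property
    def n_squares(self) -> int:
        r, c = self.shape
        return (r // SQUARE) * (c // SQUARE)

    def square_id(self) -> np.ndarray:
        """Per-cell id of the enclosing 1-degree square (row-major)."""
        r, c = np.indices(self.shape)
        return (r // SQUARE) * (self.shape[1] // SQUARE) + (c // SQUARE)

    def block_id(self) -> np.ndarray:
        """Per-cell id of the enclosing 1/2-degree block (row-major)."""
        r, c = np.indices(self.shape)
        return (r // BLOCK) * (self.shape[1] // BLOCK) + (c // BLOCK)

    def biome_names(self) -> np.ndarray:
        return np.asarray(vocab.BIOMES, dtype=object)[self.biome]

    def landuse_names(self) -> np.ndarray:
        return np.asarray(vocab.LAND_USES, dtype=object)[self.land_use]

    def analysis_mask(self) -> np.ndarray:
        """Cells inside the study region (biome not 'excluded')."""
        return self.biome != vocab.biome_code("excluded")


@dataclass
class EnergyLayer:
    """Species-by-cell annual energy flow, historical and current.

    Flows are kJ m^-2 yr^-1. Arrays are shaped (n_species, rows, cols) and
    aligned with ``species_ids``.
    """

    species_ids: list[str]
    historical: np.ndarray
    current: np.ndarray

    def __post_init__(self) -> None:
        if self.historical.shape != self.current.shape:
            raise ValidationError("historical/current flow arrays disagree on shape")
        if len(self.species_ids) != self.historical.shape[0]:
            raise ValidationError("species_ids length does not match flow array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.historical.shape[1:]

    def index_of(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    def total(self, period: str = "historical") -> np.ndarray:
        """Per-cell total flow summed over species."""
        arr = self.historical if period == "historical" else self.current
        return arr.sum(axis=0)


@dataclass
class WorldData:
    """The full input bundle the pipeline consumes.

    One object holds everything a run needs: the species trait table, the
    density table (median + 95% CI), the assimilation-efficiency table,
    the intactness table, the landscape and per-species raw range grids.
    Synthetic and real-data runs both arrive in this shape.
    """

    species: pd.DataFrame
    densities: pd.DataFrame
    assimilation: pd.DataFrame
    intactness: pd.DataFrame
    landscape: Landscape
    ranges: dict[str, np.ndarray] = field(default_factory=dict)
    #: optional per-species per-cell density rasters (ind km^-2) overriding
    #: the range-wide constant density (variable-density sensitivity hook)
    density_overrides: dict[str, np.ndarray] = field(default_factory=dict)

    def species_ids(self) -> list[str]:
        return list(self.species["species_id"])
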
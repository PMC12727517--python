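"""Esri ASCII grid raster I/O.

Rasters are written in the plain-text Esri ASCII grid dialect (north-up,
row-major, space-separated) with an explicit header carrying the grid
origin and cell size, so outputs are self-describing and round-trip
exactly through ``repr`` float formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


@dataclass
class GridSpec:
    """Geometry of a raster: lower-left corner, cell size, nodata marker."""

    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0 / 12.0  # degrees; analysis-cell resolution
    nodata: float = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, spec: GridSpec | None = None) -> None:
    """Write a 2-D array as an Esri ASCII grid (row 0 = northernmost)."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"raster must be 2-D, got shape {values.shape}")
    spec = spec or GridSpec()
    nrows, ncols = values.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {spec.xllcorner!r}\n")
        fh.write(f"yllcorner {spec.yllcorner!r}\n")
        fh.write(f"cellsize {spec.cellsize!r}\n")
        fh.write(f"NODATA_value {spec.nodata!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an Esri ASCII grid; returns (values, grid spec)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] in _HEADER_KEYS and len(parts) == 2:
                header[parts[0]] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    missing = [k for k in ("ncols", "nrows") if k not in header]
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing {missing}")
    values = np.asarray(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {values.shape} disagrees with header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    spec = GridSpec(
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0 / 12.0),
        nodata=header.get("NODATA_value", -9999.0),
    )
    return values, spec
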
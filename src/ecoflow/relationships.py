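"""Biodiversity intactness as a proxy for energetic intactness.

Per-cell diagnostics join biodiversity intactness (equal-weight mean of
species intactness factors), energetic intactness (flow-weighted), species
richness and total historical flow; ordinary least squares across cells
quantifies how well one predicts the other, and a slope/R^2 rule labels
the proxy quality of each relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import abundance, aggregation
from .core import EnergyLayer, ValidationError, WorldData
from .energetics import filtered_occupancy


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    n_dropped: int = 0


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares of y on x with a free intercept.

    NaN pairs are dropped and counted; a constant predictor is an error.
    R^2 = 1 - SSE/SST.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("predictor is constant; regression undefined")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        n_dropped=dropped,
    )


def classify_proxy(
    slope: float,
    r_squared: float,
    slope_tolerance: float = 0.15,
    r2_threshold: float = 0.7,
) -> str:
    """Label a biodiversity-vs-energetics relationship.

    'strong' when the slope is near 1 and R^2 is high (intactness
    predicts flows cell by cell); 'noisy' when the slope is near 1 but
    R^2 is low (right on average, wrong in any given cell); 'poor'
    otherwise (the proxy mis-estimates even the average response).
    """
    if not (np.isfinite(slope) and np.isfinite(r_squared)):
        raise ValidationError("slope and r_squared must be finite")
    near_one = abs(slope - 1.0) <= slope_tolerance
    if near_one and r_squared >= r2_threshold:
        return "strong"
    if near_one:
        return "noisy"
    return "poor"


def build_cell_diagnostics(
    world: WorldData,
    layer: EnergyLayer,
    function_membership: pd.DataFrame | None = None,
    clamp_bii: bool = True,
) -> pd.DataFrame:
    """Per-cell table of BII, energetic intactness, richness and flow.

    One row per in-study analysis cell with per-taxon-class biodiversity
    intactness, per-taxon-class and total energetic intactness, species
    richness, total historical flow, and (optionally) per-function
    energetic intactness columns. Cells with zero historical flow have
    NaN energetic intactness and are excluded from regressions by
    :func:`fit_linear`'s NaN handling.
    """
    landscape = world.landscape
    lookup = abundance.IntactnessLookup(world.intactness)
    occupancy = filtered_occupancy(world)
    mask = landscape.analysis_mask()
    rows_idx, cols_idx = np.nonzero(mask)
    rich = aggregation.richness(occupancy, world.species)

    taxon = dict(zip(world.species["species_id"].astype(str), world.species["taxon_class"]))
    is_bird = np.array([taxon[s] == "bird" for s in layer.species_ids])

    def intact_grid(hist: np.ndarray, cur: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = cur / hist
        out[hist == 0] = np.nan
        return out

    hist_bird = layer.historical[is_bird].sum(axis=0)
    cur_bird = layer.current[is_bird].sum(axis=0)
    hist_mam = layer.historical[~is_bird].sum(axis=0)
    cur_mam = layer.current[~is_bird].sum(axis=0)
    hist_all = hist_bird + hist_mam
    cur_all = cur_bird + cur_mam

    data = {
        "row": rows_idx,
        "col": cols_idx,
        "bii_bird": abundance.bii_grid(
            occupancy, world.species, lookup, landscape, clamp=clamp_bii, taxon_class="bird"
        )[mask],
        "bii_mammal": abundance.bii_grid(
            occupancy, world.species, lookup, landscape, clamp=clamp_bii, taxon_class="mammal"
        )[mask],
        "bii_all": abundance.bii_grid(
            occupancy, world.species, lookup, landscape, clamp=clamp_bii
        )[mask],
        "energetic_intactness_bird": intact_grid(hist_bird, cur_bird)[mask],
        "energetic_intactness_mammal": intact_grid(hist_mam, cur_mam)[mask],
        "energetic_intactness_total": intact_grid(hist_all, cur_all)[mask],
        "richness_bird": rich["bird"][mask],
        "richness_mammal": rich["mammal"][mask],
        "richness_all": rich["all"][mask],
        "historical_flow_bird": hist_bird[mask],
        "historical_flow_mammal": hist_mam[mask],
        "historical_flow_total": hist_all[mask],
    }
    if function_membership is not None:
        totals = aggregation.cell_totals_by_group(layer, function_membership, "function")
        for fn, (h, c) in totals.items():
            data[f"energetic_intactness_fn_{fn}"] = intact_grid(h, c)[mask]
    return pd.DataFrame(data)


def regression_report(diagnostics: pd.DataFrame) -> dict:
    """Headline regressions: energetic intactness on BII and flow on richness.

    Returns a dict of fits (slope, intercept, R^2, n, proxy label where a
    slope-1 reading is meaningful); relationships whose predictor is
    degenerate (e.g. a fully intact world) are reported as 'degenerate'.
    """
    pairs = {
        "energetic_vs_bii_bird": ("bii_bird", "energetic_intactness_bird", True),
        "energetic_vs_bii_mammal": ("bii_mammal", "energetic_intactness_mammal", True),
        "energetic_vs_bii_total": ("bii_all", "energetic_intactness_total", True),
        "flow_vs_richness_bird": ("richness_bird", "historical_flow_bird", False),
        "flow_vs_richness_mammal": ("richness_mammal", "historical_flow_mammal", False),
    }
    out: dict[str, dict] = {}
    for name, (xcol, ycol, proxy) in pairs.items():
        try:
            fit = fit_linear(diagnostics[xcol], diagnostics[ycol])
        except ValidationError as err:
            out[name] = {"status": "degenerate", "detail": str(err)}
            continue
        entry = {
            "status": "ok",
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "n": fit.n,
            "n_dropped": fit.n_dropped,
        }
        if proxy:
            entry["proxy_quality"] = classify_proxy(fit.slope, fit.r_squared)
        out[name] = entry
    return out
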
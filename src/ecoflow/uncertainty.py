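"""Monte Carlo uncertainty propagation with spatial variance partitioning.

Six variables carry uncertainty: body mass (truncated normal, sd 15% of
the mean, lower bound 1 g), population density (log-normal around the
published median with the sd its 95% interval implies), the DEE equation
(log10-normal multiplier), assimilation efficiency (moment-matched beta),
diet composition (symmetric beta windows, renormalized) and per-land-use
intactness (moment-matched beta rescaled to [0, upper_bound]).

Each variable's uncertainty is split between a *natural* component,
redrawn independently in every 1-degree square a species occupies (it
averages out over area), and an *absolute* component about the species
mean, drawn once per species per simulation (it does not). The split is
implemented on each sampler's link scale through a shared standard-normal
score: z = sqrt(1-split) * z_abs + sqrt(split) * z_nat is standard normal
marginally, and feeds the variable's quantile transform, so marginal
distributions are exact for any split.

Confidence intervals are the 2.5th/97.5th percentiles (linear
interpolation) of the per-simulation spatially averaged flows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from . import abundance, aggregation, vocab
from .core import ValidationError, WorldData
from .energetics import (
    DAYS_PER_YEAR,
    KM2_TO_M2,
    AllometricModel,
    AssimilationLookup,
    filtered_occupancy,
)

logger = logging.getLogger(__name__)


@dataclass
class MonteCarloConfig:
    """Knobs of the Monte Carlo engine.

    ``variance_split`` is the fraction of each variable's (link-scale)
    variance assigned to natural, per-square variability; the remainder
    is absolute, shared across a species' whole range. ``n_sims``
    defaults to the full production count; tests and demo runs pass
    smaller values.
    """

    n_sims: int = 10_000
    seed: int = 0
    variance_split: float = 0.5
    mass_sd_fraction: float = 0.15
    mass_lower_bound_g: float = 1.0
    dee_se_log10: float | None = None  # None -> per-class model residual
    intactness_upper_bound: float = 2.0
    diet_halfwidth: float = 0.1
    use_mass: bool = True
    use_density: bool = True
    use_dee: bool = True
    use_ae: bool = True
    use_diet: bool = True
    use_intactness: bool = True
    chunk_size: int = 500
    keep_traces: bool = False

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValidationError("n_sims must be >= 1")
        if not 0.0 <= self.variance_split <= 1.0:
            raise ValidationError("variance_split must lie in [0, 1]")
        if self.mass_sd_fraction < 0 or self.diet_halfwidth < 0:
            raise ValidationError("sd fractions must be >= 0")


# ---------------------------------------------------------------------------
# samplers


def sample_mass(mean_g: float, cfg: MonteCarloConfig, rng, size=None):
    """Truncated-normal body mass draw(s): sd = 15% of mean, floor 1 g."""
    if mean_g <= 0:
        raise ValidationError("mean mass must be > 0")
    sd = cfg.mass_sd_fraction * mean_g
    if sd == 0:
        return mean_g if size is None else np.full(size, mean_g)
    a = (cfg.mass_lower_bound_g - mean_g) / sd
    out = stats.truncnorm.rvs(a, np.inf, loc=mean_g, scale=sd, size=size, random_state=rng)
    return out


def beta_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched beta shape parameters for a mean/sd pair.

    alpha = m * (m(1-m)/v - 1), beta = (1-m) * (m(1-m)/v - 1). Infeasible
    variances (v >= m(1-m)) are clamped to 0.99 of the feasible bound and
    logged rather than silently dropped.
    """
    if not 0 < mean < 1:
        raise ValidationError(f"beta moment matching needs mean in (0, 1), got {mean}")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    v = sd * sd
    vmax = mean * (1 - mean)
    if v >= vmax:
        logger.warning(
            "beta moment matching: sd %.4g infeasible for mean %.4g; clamped", sd, mean
        )
        v = (0.99**2) * vmax
    k = vmax / v - 1.0
    return mean * k, (1 - mean) * k


def draw_beta(mean: float, sd: float, rng, size=None):
    """Beta draw(s) moment-matched to (mean, sd); degenerate when sd = 0."""
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    a, b = beta_from_mean_sd(mean, sd)
    return rng.beta(a, b, size=size)


def sample_diet(diet_fractions, halfwidth: float, rng, size=None):
    """Perturbed diet vector(s) on the simplex.

    Each nonzero component is drawn from a symmetric beta(2, 2) over the
    window [max(0, p - w), min(1, p + w)], then the vector is renormalized
    to sum 1; zero components stay zero. ``size`` draws that many vectors
    (rows).
    """
    p = np.asarray(diet_fractions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError("diet must lie on the simplex")
    n = 1 if size is None else int(size)
    if halfwidth == 0:
        out = np.tile(p, (n, 1))
    else:
        lo = np.maximum(0.0, p - halfwidth)
        hi = np.minimum(1.0, p + halfwidth)
        draws = rng.beta(2.0, 2.0, size=(n, p.size))
        out = np.where(p > 0, lo + (hi - lo) * draws, 0.0)
        out /= out.sum(axis=1, keepdims=True)
    return out[0] if size is None else out


def sample_intactness(mean: float, sd: float, upper_bound: float, rng, size=None):
    """Intactness factor draw(s) in [0, upper_bound].

    The variable is rescaled by the upper bound, moment-matched to a beta
    and scaled back, which supports means above 1 (disturbance winners)
    within the bound.
    """
    if mean < 0 or mean >= upper_bound:
        raise ValidationError(
            f"intactness mean must lie in [0, upper_bound={upper_bound}), got {mean}"
        )
    if mean == 0 or sd == 0:
        return mean if size is None else np.full(size, float(mean))
    return upper_bound * draw_beta(mean / upper_bound, sd / upper_bound, rng, size=size)


def sample_dee_multiplier(se_log10: float, rng, size=None):
    """Multiplicative DEE-equation error: 10^z, z ~ N(0, se_log10)."""
    if se_log10 < 0:
        raise ValidationError("se_log10 must be >= 0")
    z = rng.standard_normal(size) if size is not None else rng.standard_normal()
    return 10.0 ** (se_log10 * z)


def percentile_ci(samples, levels: tuple[float, float] = (2.5, 97.5)) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValidationError("percentile_ci needs at least one sample")
    lo, hi = np.percentile(arr, levels, method="linear")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# copula helpers: map a standard-normal score through a quantile transform


def _beta_ppf_from_z(z, a, b):
    return stats.beta.ppf(ndtr(z), a, b)


def _combine(z_abs, z_nat, split: float):
    """sqrt(1-split) * z_abs + sqrt(split) * z_nat; standard normal marginally."""
    return np.sqrt(1.0 - split) * z_abs + np.sqrt(split) * z_nat


# ---------------------------------------------------------------------------
# the engine


@dataclass
class MonteCarloResult:
    summary: pd.DataFrame
    traces: dict = field(default_factory=dict)


def _prepare_strata(world: WorldData):
    landscape = world.landscape
    in_study = landscape.analysis_mask()
    biome_labels, biome_ok = aggregation.biome_strata(landscape)
    lu_labels = aggregation.analysis_landuse_grid(landscape)
    strata = [("all", in_study)]
    for b in vocab.ANALYSIS_BIOMES:
        mask = biome_ok & (biome_labels == b)
        if mask.any():
            strata.append((f"biome:{b}", mask))
    for lu in vocab.ANALYSIS_LAND_USES:
        mask = in_study & (lu_labels == lu)
        if mask.any():
            strata.append((f"landuse:{lu}", mask))
    return strata


def run_monte_carlo(
    world: WorldData,
    cfg: MonteCarloConfig,
    model: AllometricModel | None = None,
    groupings: dict | None = None,
) -> MonteCarloResult:
    """Propagate all enabled uncertainties through the flow pipeline.

    Returns a tidy summary with, per (grouping, group, stratum), the
    deterministic point estimate, the Monte Carlo mean and 95% percentile
    CIs of the stratum-mean historical flow, current flow and energetic
    intactness. ``groupings`` maps a grouping name to either a
    species_id -> group Series (partition) or a boolean species x group
    membership frame (overlapping functions); the total community is
    always included.
    """
    if cfg.n_sims < 40:
        warnings.warn(
            "n_sims < 40 gives unreliable 95% percentile intervals", stacklevel=2
        )
    model = model or AllometricModel()
    # separate streams so absolute-draw sequences do not depend on the
    # number of squares: with variance_split = 0 results are then exactly
    # invariant to the spatial decomposition
    rng_abs = np.random.default_rng([int(cfg.seed), 101])
    rng_nat = np.random.default_rng([int(cfg.seed), 102])
    landscape = world.landscape
    pool = world.species.reset_index(drop=True)
    S = len(pool)
    F = len(vocab.FOOD_TYPES)
    n_sq_rows = landscape.shape[0] // 12
    n_sq_cols = landscape.shape[1] // 12
    Q = n_sq_rows * n_sq_cols
    LU = len(vocab.LAND_USES)
    square = landscape.square_id()

    # --- per-species parameters -------------------------------------------
    mass_mu = pool["body_mass_g"].to_numpy(float)
    is_mammal = (pool["taxon_class"] == "mammal").to_numpy()
    a_coef = np.where(is_mammal, model.mammal.a, model.bird.a)
    b_exp = np.where(is_mammal, model.mammal.b, model.bird.b)
    dee_se = np.where(
        is_mammal, model.mammal.residual_se_log10, model.bird.residual_se_log10
    )
    if cfg.dee_se_log10 is not None:
        dee_se = np.full(S, cfg.dee_se_log10)
    diet = pool[list(vocab.DIET_COLUMNS)].to_numpy(float)

    ae_lookup = AssimilationLookup(world.assimilation)
    ae_mean = np.ones((S, F))
    ae_sd = np.zeros((S, F))
    for i in range(S):
        ae_mean[i], ae_sd[i] = ae_lookup.vectors(pool.iloc[i])
    ae_sd = np.where(diet > 0, ae_sd, 0.0)
    ae_a = np.ones((S, F))
    ae_b = np.ones((S, F))
    ae_random = (ae_sd > 0) & (ae_mean < 1.0)
    for i, j in zip(*np.nonzero(ae_random)):
        ae_a[i, j], ae_b[i, j] = beta_from_mean_sd(ae_mean[i, j], ae_sd[i, j])

    dens = world.densities.set_index("species_id")
    median = dens.loc[pool["species_id"], "median"].to_numpy(float)
    sigma_ln = abundance.lognormal_sigma_from_ci(
        dens.loc[pool["species_id"], "ci_low"].to_numpy(float),
        dens.loc[pool["species_id"], "ci_high"].to_numpy(float),
    )
    density_point = median * np.exp(sigma_ln**2 / 2.0)

    # intactness parameters per species x land use (via response group)
    lut = abundance.IntactnessLookup(world.intactness)
    ub = cfg.intactness_upper_bound
    int_mean = np.zeros((S, LU))
    int_sd = np.zeros((S, LU))
    for i in range(S):
        rg = str(pool.loc[i, "response_group"])
        for j, lu in enumerate(vocab.LAND_USES):
            int_mean[i, j] = lut.mean(rg, lu)
            int_sd[i, j] = lut.sd(rg, lu)
    if (int_mean >= ub).any():
        raise ValidationError(
            f"intactness means must stay below the upper bound {ub}"
        )
    int_a = np.ones((S, LU))
    int_b = np.ones((S, LU))
    int_random = (int_sd > 0) & (int_mean > 0)
    for i, j in zip(*np.nonzero(int_random)):
        int_a[i, j], int_b[i, j] = beta_from_mean_sd(int_mean[i, j] / ub, int_sd[i, j] / ub)

    # --- spatial bookkeeping ----------------------------------------------
    occupancy = filtered_occupancy(world)
    strata = _prepare_strata(world)
    ST = len(strata)
    n_cells_stratum = np.array([mask.sum() for _, mask in strata], dtype=float)

    names = landscape.landuse_names()
    gradient = np.isin(names, sorted(vocab.GRADIENT_LAND_USES))
    w_class = np.where(gradient, landscape.intensity, 1.0)
    w_nn = np.where(gradient, 1.0 - landscape.intensity, 0.0)
    lu_code = landscape.land_use
    nn_idx = vocab.landuse_code("near_natural")

    n_occ = np.zeros((S, Q, ST))
    W_nn = np.zeros((S, Q, ST))
    W_lu = np.zeros((S, Q, ST, LU))
    for i, sid in enumerate(pool["species_id"]):
        occ = occupancy[str(sid)]
        for k, (_, mask) in enumerate(strata):
            sel = occ & mask
            if not sel.any():
                continue
            q = square[sel]
            np.add.at(n_occ[i, :, k], q, 1.0)
            np.add.at(W_nn[i, :, k], q, w_nn[sel])
            np.add.at(W_lu[i, :, k], (q, lu_code[sel]), w_class[sel])

    # --- point estimates ---------------------------------------------------
    def _unit_flow(mass, dee_mult, diet_sqf, ae_sqf, density):
        extra = (1,) * (np.ndim(mass) - 1)
        a = a_coef.reshape(-1, *extra)
        b = b_exp.reshape(-1, *extra)
        dee_val = a * mass**b * dee_mult
        intake = dee_val * (diet_sqf / ae_sqf).sum(axis=-1)
        return density * intake * DAYS_PER_YEAR / KM2_TO_M2

    point_unit = _unit_flow(
        mass_mu[:, None],
        1.0,
        diet[:, None, :],
        ae_mean[:, None, :],
        density_point[:, None],
    )  # (S, 1) broadcast over squares -> use directly
    point_unit = np.broadcast_to(point_unit, (S, Q)).copy()
    point_hist = np.einsum("sq,sqk->sk", point_unit, n_occ) / n_cells_stratum
    point_factor = (
        W_nn * int_mean[:, None, None, nn_idx]
        + np.einsum("sqkl,sl->sqk", W_lu, int_mean)
    )
    # W arrays encode per-cell weights, so this sums unit_flow * factor
    # over occupied cells per stratum
    point_cur = np.einsum("sq,sqk->sk", point_unit, point_factor) / n_cells_stratum

    # --- groupings ---------------------------------------------------------
    groupings = dict(groupings or {})
    memberships: dict[str, pd.DataFrame] = {}
    total = pd.DataFrame(
        {"community": np.ones(S, dtype=bool)}, index=pool["species_id"].astype(str)
    )
    memberships["total"] = total
    for name, assignment in groupings.items():
        if isinstance(assignment, pd.Series):
            memberships[name] = pd.get_dummies(assignment).astype(bool)
        else:
            memberships[name] = assignment.astype(bool)
    mats = {
        name: memb.loc[pool["species_id"].astype(str)].to_numpy(bool).T
        for name, memb in memberships.items()
    }  # (G, S)

    # --- simulate ----------------------------------------------------------
    T = cfg.n_sims
    split = cfg.variance_split
    sims_hist = {name: np.zeros((m.shape[0], ST, T)) for name, m in mats.items()}
    sims_cur = {name: np.zeros((m.shape[0], ST, T)) for name, m in mats.items()}

    mass_sd = cfg.mass_sd_fraction * mass_mu
    trunc_a = np.where(mass_sd > 0, (cfg.mass_lower_bound_g - mass_mu) / np.where(mass_sd > 0, mass_sd, 1.0), -np.inf)

    start = 0
    while start < T:
        t = min(cfg.chunk_size, T - start)

        def zc(shape_abs, shape_nat):
            za = rng_abs.standard_normal(shape_abs)
            zn = rng_nat.standard_normal(shape_nat)
            return _combine(za, zn, split)

        # body mass
        if cfg.use_mass and cfg.mass_sd_fraction > 0:
            z = zc((S, 1, t), (S, Q, t))
            u = ndtr(z)
            mass = stats.truncnorm.ppf(
                u, trunc_a[:, None, None], np.inf, loc=mass_mu[:, None, None],
                scale=np.where(mass_sd > 0, mass_sd, 1.0)[:, None, None],
            )
            mass = np.where(mass_sd[:, None, None] > 0, mass, mass_mu[:, None, None])
        else:
            mass = np.broadcast_to(mass_mu[:, None, None], (S, Q, t))

        # DEE equation multiplier
        if cfg.use_dee:
            dee_mult = 10.0 ** (dee_se[:, None, None] * zc((S, 1, t), (S, Q, t)))
        else:
            dee_mult = 1.0

        # assimilation efficiency
        if cfg.use_ae and ae_random.any():
            z = zc((S, F, 1, t), (S, F, Q, t))
            ae_draw = np.empty((S, F, Q, t))
            sel = ae_random
            ae_draw[~sel] = np.broadcast_to(
                ae_mean[:, :, None, None], (S, F, Q, t)
            )[~sel]
            ae_draw[sel] = _beta_ppf_from_z(
                z[sel], ae_a[sel][:, None, None], ae_b[sel][:, None, None]
            )
            ae_vals = np.moveaxis(ae_draw, 1, -1)  # (S, Q, t, F)
        else:
            ae_vals = np.broadcast_to(ae_mean[:, None, None, :], (S, Q, t, F))

        # diet composition
        if cfg.use_diet and cfg.diet_halfwidth > 0:
            z = zc((S, F, 1, t), (S, F, Q, t))
            lo = np.maximum(0.0, diet - cfg.diet_halfwidth)[:, :, None, None]
            hi = np.minimum(1.0, diet + cfg.diet_halfwidth)[:, :, None, None]
            comp = lo + (hi - lo) * _beta_ppf_from_z(z, 2.0, 2.0)
            comp = np.where(diet[:, :, None, None] > 0, comp, 0.0)
            comp /= comp.sum(axis=1, keepdims=True)
            diet_vals = np.moveaxis(comp, 1, -1)  # (S, Q, t, F)
        else:
            diet_vals = np.broadcast_to(diet[:, None, None, :], (S, Q, t, F))

        # population density
        if cfg.use_density:
            dens_vals = median[:, None, None] * np.exp(
                sigma_ln[:, None, None] * zc((S, 1, t), (S, Q, t))
            )
        else:
            dens_vals = np.broadcast_to(density_point[:, None, None], (S, Q, t))

        unit = _unit_flow(mass, dee_mult, diet_vals, ae_vals, dens_vals)  # (S, Q, t)

        # intactness factors
        if cfg.use_intactness and int_random.any():
            z = zc((S, LU, 1, t), (S, LU, Q, t))
            x = np.empty((S, LU, Q, t))
            sel = int_random
            x[~sel] = np.broadcast_to(int_mean[:, :, None, None], (S, LU, Q, t))[~sel]
            x[sel] = ub * _beta_ppf_from_z(
                z[sel], int_a[sel][:, None, None], int_b[sel][:, None, None]
            )
        else:
            x = np.broadcast_to(int_mean[:, :, None, None], (S, LU, Q, t))

        # current-flow factor summed over occupied cells per (s, q, stratum)
        fac = np.einsum("sqk,sqt->sqkt", W_nn, x[:, nn_idx]) + np.einsum(
            "sqkl,slqt->sqkt", W_lu, x
        )
        hist_c = np.einsum("sqt,sqk->skt", unit, n_occ)
        cur_c = np.einsum("sqt,sqkt->skt", unit, fac)

        for name, B in mats.items():
            sims_hist[name][:, :, start : start + t] = (
                np.einsum("gs,skt->gkt", B, hist_c) / n_cells_stratum[None, :, None]
            )
            sims_cur[name][:, :, start : start + t] = (
                np.einsum("gs,skt->gkt", B, cur_c) / n_cells_stratum[None, :, None]
            )
        start += t

    # --- summarize ----------------------------------------------------------
    rows = []
    traces = {}
    for name, memb in memberships.items():
        B = mats[name]
        ph = B @ point_hist
        pc = B @ point_cur
        for gi, group in enumerate(memb.columns):
            for k, (stratum, _) in enumerate(strata):
                h = sims_hist[name][gi, k]
                c = sims_cur[name][gi, k]
                h_lo, h_hi = percentile_ci(h)
                c_lo, c_hi = percentile_ci(c)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(h > 0, c / np.where(h > 0, h, 1.0), np.nan)
                valid = ratio[~np.isnan(ratio)]
                if valid.size:
                    i_lo, i_hi = percentile_ci(valid)
                    i_mean = float(valid.mean())
                else:
                    i_lo = i_hi = i_mean = float("nan")
                point_h = float(ph[gi, k])
                point_c = float(pc[gi, k])
                rows.append(
                    {
                        "grouping": name,
                        "group": str(group),
                        "stratum": stratum,
                        "point_historical": point_h,
                        "point_current": point_c,
                        "point_intactness": aggregation.energetic_intactness(point_c, point_h),
                        "mc_mean_historical": float(h.mean()),
                        "mc_mean_current": float(c.mean()),
                        "historical_ci_low": h_lo,
                        "historical_ci_high": h_hi,
                        "current_ci_low": c_lo,
                        "current_ci_high": c_hi,
                        "intactness_mc_mean": i_mean,
                        "intactness_ci_low": i_lo,
                        "intactness_ci_high": i_hi,
                        "n_sims": T,
                    }
                )
                if cfg.keep_traces:
                    traces[(name, str(group), stratum)] = {
                        "historical": h.copy(),
                        "current": c.copy(),
                    }
    return MonteCarloResult(summary=pd.DataFrame(rows), traces=traces)
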
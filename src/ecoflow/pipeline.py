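"""End-to-end orchestration shared by the CLI stages and the `all` command."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import aggregation, classification, energetics, io, relationships
from .config import RunConfig
from .core import WorldData
from .uncertainty import run_monte_carlo

logger = logging.getLogger(__name__)


def run_all(cfg: RunConfig, world: WorldData, seed: int | None = None, n_sims: int | None = None) -> dict:
    """Run flows, classification, aggregation, uncertainty and diagnostics.

    Writes every output table/raster under ``cfg.out_dir`` and returns the
    in-memory results for callers that keep going.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = cfg.allometry.to_model()

    logger.info("computing energy layers for %d species", len(world.species))
    layer = energetics.compute_energy_layers(world, model, per_food=cfg.per_food_intake)
    per_species = energetics.per_species_energetics(world, model, per_food=cfg.per_food_intake)
    per_species.columns = [
        "species_id",
        "taxon_class",
        "body_mass_g",
        "density_ind_km2",
        "dee_kj_day",
        "gross_intake_kj_day",
        "flow_kj_m2_yr",
    ]
    per_species.to_csv(out / "per_species_energetics.csv", index=False)

    logger.info("classifying species")
    guild_rules = classification.load_default_guild_rules()
    function_rules = classification.load_default_function_rules()
    guilds = classification.assign_guilds(world.species, guild_rules)
    functions = classification.function_membership(world.species, function_rules)
    agg_functions = classification.function_membership(
        world.species, function_rules, aggregate=True
    )
    sizes = classification.size_classes(world.species)
    taxa = pd.Series(
        world.species["taxon_class"].to_numpy(),
        index=world.species["species_id"].astype(str),
        name="taxon_class",
    )
    report = classification.validate_rules(guild_rules, function_rules, world.species)
    (out / "rule_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    assignments = pd.DataFrame({"guild": guilds, "size_class": sizes, "taxon_class": taxa})
    assignments.index.name = "species_id"
    assignments.to_csv(out / "assignments.csv")
    functions.to_csv(out / "function_membership.csv")

    logger.info("aggregating flows")
    summaries = []
    for name, assignment in (
        ("guild", guilds),
        ("taxon_class", taxa),
        ("size_class", sizes),
        ("function", agg_functions),
    ):
        summaries.append(
            aggregation.flow_summary(layer, assignment, world.landscape, grouping=name)
        )
    flow_summary = pd.concat(summaries, ignore_index=True)
    flow_summary.to_csv(out / "flow_summary.csv", index=False)

    logger.info("exporting rasters")
    io.export_layers(out / "rasters", layer, world.species)

    mc_kwargs = {}
    if seed is not None:
        mc_kwargs["seed"] = seed
    if n_sims is not None:
        mc_kwargs["n_sims"] = n_sims
    mc_cfg = cfg.monte_carlo.to_config(**mc_kwargs)
    logger.info("running %d Monte Carlo simulations", mc_cfg.n_sims)
    mc = run_monte_carlo(
        world,
        mc_cfg,
        model=model,
        groupings={"guild": guilds, "taxon_class": taxa, "function": agg_functions},
    )
    mc.summary.to_csv(out / "mc_summary.csv", index=False)

    logger.info("building cell diagnostics")
    diagnostics = relationships.build_cell_diagnostics(
        world, layer, function_membership=agg_functions, clamp_bii=cfg.clamp_bii
    )
    diagnostics.to_csv(out / "cell_diagnostics.csv", index=False)
    regressions = relationships.regression_report(diagnostics)
    (out / "regressions.json").write_text(json.dumps(regressions, indent=2))

    io.write_run_metadata(
        out,
        {
            "config": cfg.model_dump(),
            "seed": mc_cfg.seed,
            "n_sims": mc_cfg.n_sims,
            "n_species": len(world.species),
            "grid_shape": list(world.landscape.shape),
        },
    )
    return {
        "layer": layer,
        "per_species": per_species,
        "guilds": guilds,
        "functions": functions,
        "aggregate_functions": agg_functions,
        "flow_summary": flow_summary,
        "mc": mc,
        "diagnostics": diagnostics,
        "regressions": regressions,
    }
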
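"""Allocation of species to trophic guilds, functional groups and size classes.

Guilds partition the species pool: every species lands in exactly one
guild, decided by declarative rules over taxonomic class, dominant diet,
lifestyle and the large-herbivore flag, with explicit priorities for
tie-breaking. Functional groups may overlap: a species joins every
function whose predicate it satisfies (diet thresholds, lifestyle, mass
bounds, grass/leaf split, herd size), and each of the 23 class-level
functions maps to exactly one of 10 aggregate functions. The rule tables
are shipped data (CSV), not code, so a different classification scheme is
a table edit away.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import vocab
from .core import ValidationError

#: dominant-diet share required before a species counts as a dietary
#: specialist for guild assignment; below it the species is an omnivore
GUILD_DIET_THRESHOLD = 0.5

_FOOD_TO_CATEGORY = {
    "vertebrate": "carnivore",
    "invertebrate": "invertivore",
    "carrion": "scavenger",
    "fruit": "frugivore",
    "nectar": "nectarivore",
    "seed": "granivore",
    "foliage": "folivore",
}


def load_default_guild_rules() -> pd.DataFrame:
    with resources.files("ecoflow.data").joinpath("guild_rules.csv").open() as fh:
        return pd.read_csv(fh, dtype=str).assign(priority=lambda d: d["priority"].astype(int))


def load_default_function_rules() -> pd.DataFrame:
    with resources.files("ecoflow.data").joinpath("function_rules.csv").open() as fh:
        return pd.read_csv(fh)


def dominant_diet(
    species: pd.Series,
    threshold: float = GUILD_DIET_THRESHOLD,
    priority: tuple[str, ...] = vocab.FOOD_PRIORITY,
) -> str:
    """Diet category of a species: specialist food class or 'omnivore'.

    The dominant food type is the argmax of the diet vector, ties broken
    by the configured food-priority order; the species is a specialist
    only if that share reaches ``threshold``.
    """
    fractions = {f: float(species[c]) for f, c in zip(vocab.FOOD_TYPES, vocab.DIET_COLUMNS)}
    best = max(priority, key=lambda f: (fractions[f], -priority.index(f)))
    if fractions[best] >= threshold:
        return _FOOD_TO_CATEGORY[best]
    return "omnivore"


def _guild_rule_matches(rule, species: pd.Series, diet_category: str) -> bool:
    if rule.taxon_class != species["taxon_class"]:
        return False
    if rule.diet_category != diet_category:
        return False
    if rule.lifestyle != "*" and rule.lifestyle != species["lifestyle"]:
        return False
    if rule.large_herbivore != "*":
        want = rule.large_herbivore == "true"
        if bool(species["large_herbivore"]) != want:
            return False
    return True


def assign_guild(species: pd.Series, rules: pd.DataFrame | None = None) -> str:
    """The single trophic guild of a species, by priority-resolved rules."""
    rules = load_default_guild_rules() if rules is None else rules
    category = dominant_diet(species)
    matches = [r for r in rules.itertuples() if _guild_rule_matches(r, species, category)]
    if not matches:
        raise ValidationError(
            f"species {species.get('species_id')!r} (class {species['taxon_class']}, "
            f"diet {category}, lifestyle {species['lifestyle']}) matches no guild rule"
        )
    best_priority = min(r.priority for r in matches)
    winners = {r.guild_id for r in matches if r.priority == best_priority}
    if len(winners) > 1:
        raise ValidationError(
            f"species {species.get('species_id')!r} matches guilds {sorted(winners)} "
            f"at equal priority {best_priority}"
        )
    return winners.pop()


def assign_guilds(pool: pd.DataFrame, rules: pd.DataFrame | None = None) -> pd.Series:
    """Guild per species, indexed by species_id."""
    rules = load_default_guild_rules() if rules is None else rules
    out = {
        str(sp["species_id"]): assign_guild(sp, rules) for _, sp in pool.iterrows()
    }
    return pd.Series(out, name="guild")


def _function_rule_matches(rule, species: pd.Series) -> bool:
    if rule.taxon_class != species["taxon_class"]:
        return False
    food = rule.food_type
    if isinstance(food, str) and food:
        col = f"diet_{food}"
        if float(species[col]) < float(rule.diet_min):
            return False
    if rule.lifestyles != "*":
        if species["lifestyle"] not in str(rule.lifestyles).split("|"):
            return False
    mass = float(species["body_mass_g"])
    if not np.isnan(rule.mass_min_g) and not mass > float(rule.mass_min_g):
        return False
    if not np.isnan(rule.mass_max_g) and not mass < float(rule.mass_max_g):
        return False
    if not np.isnan(rule.grass_min) or not np.isnan(rule.grass_max):
        grass = species.get("grass_fraction")
        if grass is None or (isinstance(grass, float) and np.isnan(grass)):
            return False
        if not np.isnan(rule.grass_min) and float(grass) < float(rule.grass_min):
            return False
        if not np.isnan(rule.grass_max) and float(grass) > float(rule.grass_max):
            return False
    if not np.isnan(rule.herd_min):
        herd = float(species.get("herd_size", 1) or 1)
        if herd < float(rule.herd_min):
            return False
    if isinstance(rule.requires_large_herbivore, str) and rule.requires_large_herbivore:
        if not bool(species["large_herbivore"]):
            return False
    return True


def assign_functions(species: pd.Series, rules: pd.DataFrame | None = None) -> set[str]:
    """All class-level functions a species performs (possibly empty)."""
    rules = load_default_function_rules() if rules is None else rules
    return {r.function_id for r in rules.itertuples() if _function_rule_matches(r, species)}


def function_membership(
    pool: pd.DataFrame, rules: pd.DataFrame | None = None, aggregate: bool = False
) -> pd.DataFrame:
    """Boolean species x function membership matrix.

    With ``aggregate=True`` columns are the 10 aggregate functions (a
    species belongs if it performs any member class-level function).
    """
    rules = load_default_function_rules() if rules is None else rules
    functions = list(rules["function_id"])
    rows = {}
    for _, sp in pool.iterrows():
        hits = assign_functions(sp, rules)
        rows[str(sp["species_id"])] = [f in hits for f in functions]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=functions)
    if aggregate:
        agg_of = dict(zip(rules["function_id"], rules["aggregate_id"]))
        grouped = {}
        for agg in dict.fromkeys(rules["aggregate_id"]):
            members = [f for f in functions if agg_of[f] == agg]
            grouped[agg] = out[members].any(axis=1)
        out = pd.DataFrame(grouped)
    out.index.name = "species_id"
    return out


def size_class(mass_g: float) -> str:
    """Body-size class: small (< 3 kg), megafauna (> 65 kg), else medium.

    Both boundaries are strict, so masses of exactly 3 kg or 65 kg fall
    in the middle class.
    """
    if mass_g <= 0:
        raise ValidationError("mass must be > 0")
    if mass_g < vocab.SMALL_MASS_G:
        return "small"
    if mass_g > vocab.MEGAFAUNA_MASS_G:
        return "megafauna"
    return "medium"


def size_classes(pool: pd.DataFrame) -> pd.Series:
    out = {
        str(sp["species_id"]): size_class(float(sp["body_mass_g"]))
        for _, sp in pool.iterrows()
    }
    return pd.Series(out, name="size_class")


@dataclass
class RuleReport:
    """Validation report for a guild + function rule set against a pool."""

    guild_violations: list[str]
    unmatched_species: list[str]
    ambiguous_species: list[str]
    guild_match_counts: dict[str, int]
    function_match_counts: dict[str, int]
    aggregates: list[str]
    missing_aggregates: list[str]

    @property
    def ok(self) -> bool:
        return not (self.guild_violations or self.unmatched_species or self.ambiguous_species or self.missing_aggregates)

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "guild_violations": self.guild_violations,
            "unmatched_species": self.unmatched_species,
            "ambiguous_species": self.ambiguous_species,
            "guild_match_counts": self.guild_match_counts,
            "function_match_counts": self.function_match_counts,
            "aggregates": self.aggregates,
            "missing_aggregates": self.missing_aggregates,
        }


def validate_rules(
    guild_rules: pd.DataFrame,
    function_rules: pd.DataFrame,
    pool: pd.DataFrame,
    expected_aggregates: tuple[str, ...] | None = None,
) -> RuleReport:
    """Check guild totality/uniqueness and function->aggregate coverage."""
    unmatched, ambiguous = [], []
    guild_counts: dict[str, int] = {g: 0 for g in guild_rules["guild_id"]}
    for _, sp in pool.iterrows():
        try:
            guild_counts[assign_guild(sp, guild_rules)] += 1
        except ValidationError as err:
            if "matches no guild rule" in str(err):
                unmatched.append(str(sp["species_id"]))
            else:
                ambiguous.append(str(sp["species_id"]))
    fn_counts = {f: 0 for f in function_rules["function_id"]}
    for _, sp in pool.iterrows():
        for f in assign_functions(sp, function_rules):
            fn_counts[f] += 1
    present = list(dict.fromkeys(function_rules["aggregate_id"]))
    expected = list(expected_aggregates) if expected_aggregates else present
    missing = [a for a in expected if a not in present]
    violations = []
    if unmatched:
        violations.append(f"{len(unmatched)} species match no guild rule")
    if ambiguous:
        violations.append(f"{len(ambiguous)} species match multiple guilds at equal priority")
    return RuleReport(
        guild_violations=violations,
        unmatched_species=unmatched,
        ambiguous_species=ambiguous,
        guild_match_counts=guild_counts,
        function_match_counts=fn_counts,
        aggregates=present,
        missing_aggregates=missing,
    )
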
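"""Data model and file I/O for food lists, donor tables, nutrient references
and the compiled nutrient database.

Foods are identified by 8-digit codes whose 2-, 3- and 5-digit prefixes
encode a nested food-group hierarchy (major group, sub-group, minor group),
as in the Australian food-composition survey database layout. All
composition fields are expressed per 100 g edible portion; choline and
betaine are in mg/100 g and may be absent (unknown), which is distinct from
a literal zero.

Files are comma-separated UTF-8 text with one header row. Column names can
be remapped through a small configuration dictionary so differently-labelled
exports can be read without code changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, RowParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

FOOD_ID_LENGTH = 8

#: Allowed provenance labels for a compiled value.
SOURCES = ("analytical", "borrowed", "recipe", "unmatched_zero")
#: Match-quality grades, best to worst; "none" for values that are not matches.
CONFIDENCE_CODES = ("A", "B", "C", "D", "none")

# Default column names for each reader; a config mapping {field: column}
# overrides individual entries.
FOOD_TABLE_COLUMNS = {
    "food_id": "food_id",
    "name": "name",
    "moisture": "moisture_g_100g",
    "protein": "protein_g_100g",
    "energy": "energy_kj_100g",
    "choline": "choline_mg_100g",
    "betaine": "betaine_mg_100g",
    "source": "source",
    "confidence": "confidence",
    "unmatched_zero_flag": "unmatched_zero_flag",
    "donor_id": "donor_id",
}

DONOR_TABLE_COLUMNS = {
    "donor_id": "donor_id",
    "donor_name": "donor_name",
    "moisture": "moisture_g_100g",
    "protein": "protein_g_100g",
    "choline": "choline_mg_100g",
    "betaine": "betaine_mg_100g",
    "donor_source": "donor_source",
}

RECIPE_FILE_COLUMNS = {
    "recipe_id": "recipe_id",
    "ingredient_id": "ingredient_id",
    "raw_weight": "raw_weight_g",
    "retention": "retention",
    "weight_change_factor": "weight_change_factor",
}

AI_TABLE_COLUMNS = {
    "group_label": "group_label",
    "sex": "sex",
    "age_min": "age_min",
    "age_max": "age_max",
    "life_stage": "life_stage",
    "ai": "ai_mg_day",
}


def _validate_food_id(food_id: str) -> None:
    if len(food_id) != FOOD_ID_LENGTH or not food_id.isdigit():
        raise ValidationError(
            f"food_id {food_id!r} must be exactly {FOOD_ID_LENGTH} digits"
        )


@dataclass(frozen=True)
class FoodRecord:
    """One food of the target database: composition per 100 g plus
    provenance and match-confidence metadata for the compiled nutrient value.
    """

    food_id: str
    name: str
    moisture: float  # g/100 g
    protein: float  # g/100 g
    energy: float  # kJ/100 g
    choline: Optional[float] = None  # mg/100 g; None = no value assigned
    betaine: Optional[float] = None  # mg/100 g
    source: Optional[str] = None  # one of SOURCES once a value is assigned
    confidence: str = "none"
    unmatched_zero_flag: bool = False
    donor_id: Optional[str] = None

    def __post_init__(self):
        _validate_food_id(self.food_id)
        if self.moisture < 0 or self.moisture > 100:
            raise ValidationError(
                f"{self.food_id}: moisture {self.moisture} outside [0, 100]"
            )
        if self.protein < 0:
            raise ValidationError(f"{self.food_id}: negative protein")
        if self.choline is not None and self.choline < 0:
            raise ValidationError(f"{self.food_id}: negative choline")
        if self.betaine is not None and self.betaine < 0:
            raise ValidationError(f"{self.food_id}: negative betaine")
        if self.source is not None and self.source not in SOURCES:
            raise ValidationError(f"{self.food_id}: unknown source {self.source!r}")
        if self.confidence not in CONFIDENCE_CODES:
            raise ValidationError(
                f"{self.food_id}: unknown confidence {self.confidence!r}"
            )
        if self.source == "unmatched_zero" and (
            self.choline != 0 or not self.unmatched_zero_flag
        ):
            raise ValidationError(
                f"{self.food_id}: unmatched_zero requires choline 0 and flag set"
            )

    @property
    def group2(self) -> str:
        """Major food-group code (first 2 digits of the food id)."""
        return self.food_id[:2]

    @property
    def group3(self) -> str:
        """Sub-group code (first 3 digits)."""
        return self.food_id[:3]

    @property
    def group5(self) -> str:
        """Minor-group code (first 5 digits)."""
        return self.food_id[:5]

    @property
    def has_value(self) -> bool:
        """True when a genuine nutrient value (not an unmatched zero) exists."""
        return self.choline is not None and self.source != "unmatched_zero"

    def with_value(self, **kwargs) -> "FoodRecord":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DonorRecord:
    """A candidate donor food from an external nutrient database or study."""

    donor_id: str
    donor_name: str
    moisture: float
    protein: float
    choline: float
    betaine: Optional[float] = None
    donor_source: str = "donor database"

    def __post_init__(self):
        if self.moisture < 0 or self.moisture > 100:
            raise ValidationError(f"{self.donor_id}: moisture outside [0, 100]")
        if self.protein < 0 or self.choline < 0:
            raise ValidationError(f"{self.donor_id}: negative composition value")
        if self.betaine is not None and self.betaine < 0:
            raise ValidationError(f"{self.donor_id}: negative betaine")


@dataclass(frozen=True)
class AIReference:
    """One Adequate-Intake reference band (mg/day) by sex, age and life stage."""

    group_label: str
    sex: str  # male / female / any
    age_min: int
    age_max: int
    life_stage: str = "none"  # none / pregnant / lactating
    ai: float = 0.0

    def __post_init__(self):
        if self.ai <= 0:
            raise ValidationError(f"{self.group_label}: AI must be positive")
        if self.age_min > self.age_max:
            raise ValidationError(f"{self.group_label}: age_min > age_max")
        if self.sex not in ("male", "female", "any"):
            raise ValidationError(f"{self.group_label}: bad sex {self.sex!r}")
        if self.life_stage not in ("none", "pregnant", "lactating"):
            raise ValidationError(
                f"{self.group_label}: bad life_stage {self.life_stage!r}"
            )

    def matches(self, age: int, sex: str, life_stage: str = "none") -> bool:
        if not (self.age_min <= age <= self.age_max):
            return False
        if self.sex != "any" and self.sex != sex:
            return False
        return self.life_stage == life_stage


def default_ai_references() -> list[AIReference]:
    """The Australian Adequate-Intake bands for choline (mg/day).

    Age bands are closed intervals of integer years at interview.
    """
    rows = [
        ("2-3 years", "any", 2, 3, "none", 200),
        ("4-8 years", "any", 4, 8, "none", 250),
        ("9-13 years", "any", 9, 13, "none", 375),
        ("Male 14-18 years", "male", 14, 18, "none", 550),
        ("Male 19-85 years", "male", 19, 85, "none", 550),
        ("Female 14-18 years", "female", 14, 18, "none", 400),
        ("Female 19-85 years", "female", 19, 85, "none", 425),
        ("Pregnant 14-18 years", "female", 14, 18, "pregnant", 415),
        ("Pregnant 19-50 years", "female", 19, 50, "pregnant", 440),
        ("Lactating 14-18 years", "female", 14, 18, "lactating", 550),
        ("Lactating 19-50 years", "female", 19, 50, "lactating", 550),
    ]
    return [AIReference(*r) for r in rows]


def lookup_ai(respondent, ai_table: Sequence[AIReference]) -> Optional[float]:
    """Return the unique AI (mg/day) applying to a respondent, or None.

    A life-stage-specific band (pregnant/lactating) takes precedence over the
    plain sex/age band. Respondents with no applicable band return None and
    are excluded from attainment summaries by the caller.
    """
    stage = getattr(respondent, "life_stage", "none") or "none"
    age, sex = respondent.age, respondent.sex
    if stage != "none":
        staged = [r for r in ai_table if r.matches(age, sex, stage)]
        if len(staged) > 1:
            raise ConfigError(
                f"overlapping AI bands for age={age} sex={sex} stage={stage}"
            )
        if staged:
            return staged[0].ai
    plain = [r for r in ai_table if r.matches(age, sex, "none")]
    if len(plain) > 1:
        raise ConfigError(f"overlapping AI bands for age={age} sex={sex}")
    if plain:
        return plain[0].ai
    logger.info("no AI band for age=%s sex=%s life_stage=%s", age, sex, stage)
    return None


# ---------------------------------------------------------------------------
# CSV I/O


def _resolve_columns(df: pd.DataFrame, defaults: Mapping[str, str],
                     config: Optional[Mapping[str, str]],
                     mandatory: Sequence[str]) -> Mapping[str, str]:
    cols = dict(defaults)
    if config:
        cols.update(config)
    for fieldname in mandatory:
        if cols[fieldname] not in df.columns:
            raise SchemaError(
                f"missing mandatory column {cols[fieldname]!r} (field {fieldname})"
            )
    return cols


def _opt_float(value) -> Optional[float]:
    """Parse an optional numeric cell; empty string / NaN means absent."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "":
        return None
    return float(s)


def read_food_table(path, config: Optional[Mapping[str, str]] = None
                    ) -> list[FoodRecord]:
    """Read a target food list (optionally with compiled nutrient columns).

    Mandatory fields: food_id, name, moisture, protein, energy. The nutrient,
    provenance and confidence columns are read when present so the same
    reader round-trips the compiled database.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_columns(
        df, FOOD_TABLE_COLUMNS, config,
        mandatory=["food_id", "name", "moisture", "protein", "energy"],
    )
    records, bad_rows, messages = [], [], []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            kwargs = dict(
                food_id=row[cols["food_id"]].strip(),
                name=row[cols["name"]],
                moisture=float(row[cols["moisture"]]),
                protein=float(row[cols["protein"]]),
                energy=float(row[cols["energy"]]),
            )
            for opt in ("choline", "betaine"):
                if cols[opt] in df.columns:
                    kwargs[opt] = _opt_float(row[cols[opt]])
            if cols["source"] in df.columns:
                src = row[cols["source"]].strip()
                kwargs["source"] = src or None
            if cols["confidence"] in df.columns:
                kwargs["confidence"] = row[cols["confidence"]].strip() or "none"
            if cols["unmatched_zero_flag"] in df.columns:
                kwargs["unmatched_zero_flag"] = (
                    str(row[cols["unmatched_zero_flag"]]).strip().lower()
                    in ("1", "true", "yes")
                )
            if cols["donor_id"] in df.columns:
                kwargs["donor_id"] = row[cols["donor_id"]].strip() or None
            records.append(FoodRecord(**kwargs))
        except (ValueError, ValidationError) as exc:
            bad_rows.append(i)
            messages.append(f"row {i}: {exc}")
    if bad_rows:
        raise RowParseError(
            "failed to parse food table rows: " + "; ".join(messages),
            rows=bad_rows,
        )
    return records


def write_nutrient_db(records: Iterable[FoodRecord], path,
                      round_decimals: Optional[int] = None) -> None:
    """Write the compiled nutrient database as CSV.

    Values are stored unrounded by default; pass ``round_decimals`` for
    report-style output.
    """
    def fmt(v):
        if v is None:
            return ""
        if round_decimals is not None:
            return round(v, round_decimals)
        return repr(float(v))

    rows = []
    for r in records:
        rows.append({
            "food_id": r.food_id,
            "name": r.name,
            "moisture_g_100g": fmt(r.moisture),
            "protein_g_100g": fmt(r.protein),
            "energy_kj_100g": fmt(r.energy),
            "choline_mg_100g": fmt(r.choline),
            "betaine_mg_100g": fmt(r.betaine),
            "source": r.source or "",
            "confidence": r.confidence,
            "unmatched_zero_flag": int(r.unmatched_zero_flag),
            "donor_id": r.donor_id or "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_nutrient_db(path) -> list[FoodRecord]:
    """Read a compiled nutrient database written by :func:`write_nutrient_db`."""
    return read_food_table(path)


def read_donor_table(path, config: Optional[Mapping[str, str]] = None
                     ) -> list[DonorRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_columns(
        df, DONOR_TABLE_COLUMNS, config,
        mandatory=["donor_id", "donor_name", "moisture", "protein", "choline"],
    )
    records, bad_rows, messages = [], [], []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            betaine = None
            if cols["betaine"] in df.columns:
                betaine = _opt_float(row[cols["betaine"]])
            source = "donor database"
            if cols["donor_source"] in df.columns:
                source = row[cols["donor_source"]] or source
            records.append(DonorRecord(
                donor_id=row[cols["donor_id"]].strip(),
                donor_name=row[cols["donor_name"]],
                moisture=float(row[cols["moisture"]]),
                protein=float(row[cols["protein"]]),
                choline=float(row[cols["choline"]]),
                betaine=betaine,
                donor_source=source,
            ))
        except (ValueError, ValidationError) as exc:
            bad_rows.append(i)
            messages.append(f"row {i}: {exc}")
    if bad_rows:
        raise RowParseError(
            "failed to parse donor table rows: " + "; ".join(messages),
            rows=bad_rows,
        )
    return records


def write_donor_table(records: Iterable[DonorRecord], path) -> None:
    rows = [{
        "donor_id": r.donor_id,
        "donor_name": r.donor_name,
        "moisture_g_100g": repr(float(r.moisture)),
        "protein_g_100g": repr(float(r.protein)),
        "choline_mg_100g": repr(float(r.choline)),
        "betaine_mg_100g": "" if r.betaine is None else repr(float(r.betaine)),
        "donor_source": r.donor_source,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_recipe_file(path, config: Optional[Mapping[str, str]] = None):
    """Read a recipe file: one row per ingredient, grouped by recipe id.

    Returns a list of :class:`~nutricompile.compilation.RecipeSpec` in first-
    appearance order; ingredient order within a recipe is preserved. Whether
    each ingredient id resolves against a food table is checked later, at
    recipe computation time.
    """
    from .compilation import RecipeSpec  # deferred: RecipeSpec lives with the engine

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_columns(
        df, RECIPE_FILE_COLUMNS, config,
        mandatory=["recipe_id", "ingredient_id", "raw_weight",
                   "weight_change_factor"],
    )
    grouped: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        rid = row[cols["recipe_id"]].strip()
        wcf = float(row[cols["weight_change_factor"]])
        retention = 1.0
        if cols["retention"] in df.columns:
            retention = _opt_float(row[cols["retention"]]) or 1.0
        entry = grouped.setdefault(rid, {"wcf": wcf, "ingredients": []})
        if entry["wcf"] != wcf:
            raise ValidationError(
                f"recipe {rid}: inconsistent weight_change_factor across rows"
            )
        entry["ingredients"].append(
            (row[cols["ingredient_id"]].strip(),
             float(row[cols["raw_weight"]]), retention)
        )
    return [
        RecipeSpec(recipe_id=rid, ingredients=e["ingredients"],
                   weight_change_factor=e["wcf"])
        for rid, e in grouped.items()
    ]


def write_recipe_file(recipes, path) -> None:
    rows = []
    for rec in recipes:
        for ing_id, weight, retention in rec.ingredients:
            rows.append({
                "recipe_id": rec.recipe_id,
                "ingredient_id": ing_id,
                "raw_weight_g": repr(float(weight)),
                "retention": repr(float(retention)),
                "weight_change_factor": repr(float(rec.weight_change_factor)),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ai_table(path, config: Optional[Mapping[str, str]] = None
                  ) -> list[AIReference]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_columns(
        df, AI_TABLE_COLUMNS, config,
        mandatory=["group_label", "sex", "age_min", "age_max", "ai"],
    )
    refs = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        stage = "none"
        if cols["life_stage"] in df.columns:
            stage = row[cols["life_stage"]].strip() or "none"
        refs.append(AIReference(
            group_label=row[cols["group_label"]],
            sex=row[cols["sex"]].strip(),
            age_min=int(row[cols["age_min"]]),
            age_max=int(row[cols["age_max"]]),
            life_stage=stage,
            ai=float(row[cols["ai"]]),
        ))
    _check_ai_overlap(refs)
    return refs


def write_ai_table(refs: Iterable[AIReference], path) -> None:
    rows = [{
        "group_label": r.group_label,
        "sex": r.sex,
        "age_min": r.age_min,
        "age_max": r.age_max,
        "life_stage": r.life_stage,
        "ai_mg_day": repr(float(r.ai)),
    } for r in refs]
    pd.DataFrame(rows).to_csv(path, index=False)


def _check_ai_overlap(refs: Sequence[AIReference]) -> None:
    for i, a in enumerate(refs):
        for b in refs[i + 1:]:
            if a.life_stage != b.life_stage:
                continue
            if "any" not in (a.sex, b.sex) and a.sex != b.sex:
                continue
            if a.age_min <= b.age_max and b.age_min <= a.age_max:
                raise ConfigError(
                    f"overlapping AI bands: {a.group_label!r} and {b.group_label!r}"
                )


def load_column_config(path) -> dict:
    """Load a YAML column-mapping / dialect configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("column config must be a mapping")
    return cfg
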
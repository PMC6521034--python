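"""End-to-end pipeline runner.

Stages run in order — simulate, compile, intakes, summarise, sources,
models — each reading its inputs from and writing its outputs to a single
run directory, so any stage can also be re-run individually from the
intermediate files. A reproducibility manifest (config snapshot, seed,
SHA-256 digests of every file touched) is written last; it contains no
timestamps, so re-running an identical configuration yields an identical
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import compilation, food_db, intake_pipeline, models, sources, survey_stats
from .errors import ConfigError
from .synthetic_data import (
    events_to_csv_frame,
    generate_food_db,
    generate_survey,
    respondents_from_frame,
    respondents_to_frame,
    SCENARIOS,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "compile", "intakes", "summarise", "sources",
              "models")

DEFAULT_CONFIG = {
    "seed": 0,
    "scenario": "paper-like",
    "stages": list(ALL_STAGES),
    "coverage_fraction": 0.9751,
    "sigma2_between": 400.0,
    "sigma2_within": 1600.0,
    "covariates": ["age", "sex"],
    "qa_fraction": 0.10,
    "top_n": 20,
    "source_level": 3,
    "models_max_groups": 8,
    "exclude_groups": [],
    "ai_table": "default",
    "ci_multiplier": 2.0,
}

_TYPES = {
    "seed": int, "scenario": str, "stages": list,
    "coverage_fraction": float, "sigma2_between": float,
    "sigma2_within": float, "covariates": list, "qa_fraction": float,
    "top_n": int, "source_level": int, "models_max_groups": int,
    "exclude_groups": list, "ai_table": str, "ci_multiplier": float,
}


def validate_config(config: Optional[Mapping] = None) -> dict:
    """Merge with defaults and validate; raises ConfigError before any work."""
    cfg = dict(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"unknown config key {key!r}")
        want = _TYPES[key]
        if want is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, want):
            raise ConfigError(
                f"config key {key!r}: expected {want.__name__}, "
                f"got {type(value).__name__}"
            )
        cfg[key] = value
    unknown = set(cfg["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    if cfg["scenario"] not in SCENARIOS:
        raise ConfigError(f"unknown scenario {cfg['scenario']!r}")
    if not (0 < cfg["qa_fraction"] <= 1):
        raise ConfigError("qa_fraction must be in (0, 1]")
    if cfg["source_level"] not in (2, 3, 5):
        raise ConfigError("source_level must be 2, 3 or 5")
    return cfg


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")
    return validate_config(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(cfg: dict, outdir: Path) -> None:
    """Check cross-stage file dependencies before any computation."""
    stages = cfg["stages"]
    produced = set()
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        needs = {
            "simulate": [],
            "compile": ["foods.csv", "donors.csv", "matches.csv",
                        "recipes.csv", "analytical.csv"],
            "intakes": ["compiled_db.csv", "respondents.csv", "events.csv"],
            "summarise": ["usual_intakes.csv", "respondents.csv",
                          "ai_reference.csv"],
            "sources": ["compiled_db.csv", "respondents.csv", "events.csv"],
            "models": ["usual_intakes.csv", "respondents.csv",
                       "events.csv", "compiled_db.csv"],
        }[stage]
        if stage == "summarise" and cfg["ai_table"] == "default":
            needs = [n for n in needs if n != "ai_reference.csv"]
        for name in needs:
            if name in produced or (outdir / name).exists():
                continue
            raise ConfigError(
                f"stage {stage!r} needs {name} but no earlier stage "
                f"produces it and it is not in {outdir}"
            )
        produced.update(_stage_outputs(stage))


def _stage_outputs(stage: str) -> list[str]:
    return {
        "simulate": ["foods.csv", "donors.csv", "matches.csv", "recipes.csv",
                     "analytical.csv", "unmatched.csv", "ai_reference.csv",
                     "respondents.csv", "events.csv", "ground_truth.json"],
        "compile": ["compiled_db.csv", "qa_report.csv", "qa_log.txt"],
        "intakes": ["usual_intakes.csv", "variance_components.json"],
        "summarise": ["group_summaries.csv"],
        "sources": ["food_sources.csv"],
        "models": ["group_models.csv"],
    }[stage]


# ---------------------------------------------------------------------------
# Stage implementations


def stage_simulate(cfg: dict, outdir: Path) -> None:
    food = generate_food_db(
        n_foods=SCENARIOS[cfg["scenario"]]["n_foods"],
        coverage_fraction=cfg["coverage_fraction"], seed=cfg["seed"],
    )
    compiled = {r.food_id: r.choline for r in food.compile() if r.has_value}
    survey = generate_survey(
        n_respondents=SCENARIOS[cfg["scenario"]]["n_respondents"],
        seed=cfg["seed"] + 1,
        sigma2_between=cfg["sigma2_between"],
        sigma2_within=cfg["sigma2_within"],
        r_replicates=SCENARIOS[cfg["scenario"]]["r_replicates"],
        compiled_db=compiled,
    )

    rows = [{
        "food_id": f.food_id, "name": f.name,
        "moisture_g_100g": repr(f.moisture),
        "protein_g_100g": repr(f.protein),
        "energy_kj_100g": repr(f.energy),
    } for f in food.foods]
    pd.DataFrame(rows).to_csv(outdir / "foods.csv", index=False)

    food_db.write_donor_table(food.donors, outdir / "donors.csv")
    match_rows = [{
        "target_id": tid, "donor_id": donor.donor_id,
        "adjustment": pol.adjustment,
        "same_species": int(pol.same_species),
        "same_part_or_cut": int(pol.same_part_or_cut),
        "same_processing_or_cooking": int(pol.same_processing_or_cooking),
    } for tid, donor, pol in food.donor_matches]
    pd.DataFrame(match_rows).to_csv(outdir / "matches.csv", index=False)
    food_db.write_recipe_file(food.recipes, outdir / "recipes.csv")
    pd.DataFrame([
        {"food_id": fid, "choline_mg_100g": repr(float(ch)),
         "betaine_mg_100g": "" if bet is None else repr(float(bet))}
        for fid, (ch, bet) in sorted(food.analytical.items())
    ]).to_csv(outdir / "analytical.csv", index=False)
    pd.DataFrame({"food_id": food.unmatched}).to_csv(
        outdir / "unmatched.csv", index=False)
    food_db.write_ai_table(food_db.default_ai_references(),
                           outdir / "ai_reference.csv")
    respondents_to_frame(survey.respondents).to_csv(
        outdir / "respondents.csv", index=False)
    events_to_csv_frame(survey.events).to_csv(
        outdir / "events.csv", index=False)

    truth = {"food": food.truth.to_dict(), "survey": survey.truth.to_dict()}
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8")


def stage_compile(cfg: dict, outdir: Path) -> None:
    foods = food_db.read_food_table(outdir / "foods.csv")
    donors = {d.donor_id: d
              for d in food_db.read_donor_table(outdir / "donors.csv")}
    matches_df = pd.read_csv(outdir / "matches.csv", dtype=str)
    donor_matches = [
        (row["target_id"], donors[row["donor_id"]], compilation.MatchPolicy(
            adjustment=row["adjustment"],
            same_species=row["same_species"] == "1",
            same_part_or_cut=row["same_part_or_cut"] == "1",
            same_processing_or_cooking=row["same_processing_or_cooking"] == "1",
        ))
        for _, row in matches_df.iterrows()
    ]
    recipes = food_db.read_recipe_file(outdir / "recipes.csv")
    analytical = {}
    adf = pd.read_csv(outdir / "analytical.csv", dtype=str,
                      keep_default_na=False)
    for _, row in adf.iterrows():
        bet = row.get("betaine_mg_100g", "")
        analytical[row["food_id"]] = (
            float(row["choline_mg_100g"]),
            float(bet) if bet else None,
        )
    compiled = compilation.compile_database(
        foods, donor_matches, recipes, analytical)
    food_db.write_nutrient_db(compiled, outdir / "compiled_db.csv")

    report = compilation.qa_checks(
        compiled, fraction=cfg["qa_fraction"], seed=cfg["seed"])
    pd.DataFrame(
        [{"food_id": f, "value": v, "low": b[0], "high": b[1]}
         for f, v, b in report.range_violations]
    ).to_csv(outdir / "qa_report.csv", index=False)
    n_value, pct, n_betaine = compilation.coverage_stats(compiled)
    (outdir / "qa_log.txt").write_text(
        f"foods compiled: {len(compiled)}\n"
        f"foods with a value: {n_value} ({pct:.2f}%)\n"
        f"foods with betaine: {n_betaine}\n"
        f"range violations: {len(report.range_violations)}\n"
        f"verification sample ({len(report.verification_sample)} ids): "
        + ",".join(report.verification_sample) + "\n",
        encoding="utf-8",
    )


def _load_survey(outdir: Path):
    compiled = food_db.read_nutrient_db(outdir / "compiled_db.csv")
    db = {r.food_id: r.choline for r in compiled if r.choline is not None}
    respondents = respondents_from_frame(
        pd.read_csv(outdir / "respondents.csv"))
    events = pd.read_csv(outdir / "events.csv",
                         dtype={"food_id": str, "resp_id": str})
    return compiled, db, respondents, events


def stage_intakes(cfg: dict, outdir: Path) -> None:
    _, db, respondents, events = _load_survey(outdir)
    usual, comps = intake_pipeline.estimate_usual_intakes(
        events, db, respondents, covariates=tuple(cfg["covariates"]))
    out = usual.copy()
    for col in ("usual_mg", "mean_mg", "pred_mg", "lambda"):
        out[col] = out[col].map(repr)
    out.to_csv(outdir / "usual_intakes.csv", index=False)
    (outdir / "variance_components.json").write_text(json.dumps({
        "sigma2_between": comps.sigma2_between,
        "sigma2_within": comps.sigma2_within,
        "lambda_1": comps.shrinkage(1),
        "lambda_2": comps.shrinkage(2),
    }, indent=1, sort_keys=True), encoding="utf-8")


def _load_ai(cfg: dict, outdir: Path):
    if cfg["ai_table"] == "default" and not (outdir / "ai_reference.csv").exists():
        return food_db.default_ai_references()
    path = (outdir / "ai_reference.csv" if cfg["ai_table"] == "default"
            else Path(cfg["ai_table"]))
    return food_db.read_ai_table(path)


def stage_summarise(cfg: dict, outdir: Path) -> None:
    usual = pd.read_csv(outdir / "usual_intakes.csv",
                        dtype={"resp_id": str})
    respondents = respondents_from_frame(
        pd.read_csv(outdir / "respondents.csv"))
    ai_table = _load_ai(cfg, outdir)
    summaries = survey_stats.build_group_summaries(
        usual, respondents, ai_table, multiplier=cfg["ci_multiplier"])
    survey_stats.summaries_to_frame(summaries).to_csv(
        outdir / "group_summaries.csv", index=False)


def stage_sources(cfg: dict, outdir: Path) -> None:
    compiled, db, respondents, events = _load_survey(outdir)
    labels = {}
    for r in compiled:
        code = r.food_id[:cfg["source_level"]]
        labels.setdefault(code, r.name.split(" item ")[0])
    records = sources.group_contributions(
        events, db, respondents, level=cfg["source_level"], labels=labels)
    head, cumulative = sources.top_n(records, cfg["top_n"])
    frame = sources.contributions_to_frame(records)
    frame["in_top_n"] = frame["rank"] <= cfg["top_n"]
    frame.to_csv(outdir / "food_sources.csv", index=False)
    logger.info("top %d groups cover %.2f%% of intake",
                cfg["top_n"], cumulative)


def stage_models(cfg: dict, outdir: Path) -> None:
    compiled, db, respondents, events = _load_survey(outdir)
    usual = pd.read_csv(outdir / "usual_intakes.csv", dtype={"resp_id": str})
    level = cfg["source_level"]
    events = events.assign(group=events["food_id"].str[:level])

    # grams/day of each group per respondent, averaged over observed days
    n_days = events.groupby("resp_id")["day"].nunique()
    grams = (events.groupby(["resp_id", "group"])["grams"].sum()
             .unstack(fill_value=0.0))
    grams = grams.div(n_days, axis=0)

    by_id = {r.resp_id: r for r in respondents}
    ids = [i for i in grams.index if i in by_id]
    usual_map = dict(zip(usual["resp_id"], usual["usual_mg"]))
    base = pd.DataFrame({
        "total_mg": [usual_map[i] for i in ids],
        "energy": [by_id[i].energy for i in ids],
        "activity_level": [float(by_id[i].activity_level) for i in ids],
        "sex": [1.0 if by_id[i].sex == "female" else 0.0 for i in ids],
        "age": [float(by_id[i].age) for i in ids],
        "education_level": [float(by_id[i].education_level) for i in ids],
    }, index=ids)
    weights = pd.Series({i: by_id[i].weight for i in ids})
    rw = pd.DataFrame(
        {i: by_id[i].replicate_weights for i in ids}).T.loc[ids]

    # largest contributors first, capped for runtime
    order = (events.assign(
        mg=events["grams"] * events["food_id"].map(db) / 100.0)
        .groupby("group")["mg"].sum().sort_values(ascending=False))
    candidates = [g for g in order.index
                  if g not in set(cfg["exclude_groups"])]
    results = []
    for code in candidates[:cfg["models_max_groups"]]:
        data = base.assign(group_g=grams.loc[ids, code])
        if (data["group_g"] > 0).sum() < 10:
            continue
        results.append(models.fit_group_model(
            data, code, weights.to_numpy(), rw.to_numpy()))
    ranked = models.rank_models(results, exclude=cfg["exclude_groups"])
    models.models_to_frame(ranked).to_csv(
        outdir / "group_models.csv", index=False)


def run_all(config: Optional[Mapping] = None, outdir="runs/latest") -> dict:
    """Run the configured stages in order and write the manifest.

    Returns the manifest dictionary. Any stage failure aborts the run with
    the stage name in the raised error's message.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _preflight(cfg, outdir)

    stage_fns = {
        "simulate": stage_simulate, "compile": stage_compile,
        "intakes": stage_intakes, "summarise": stage_summarise,
        "sources": stage_sources, "models": stage_models,
    }
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}
    for stage in ALL_STAGES:
        if stage not in cfg["stages"]:
            continue
        logger.info("running stage %s", stage)
        try:
            stage_fns[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for name in _stage_outputs(stage):
            path = outdir / name
            if path.exists():
                outputs[name] = _sha256(path)

    manifest = {
        "config": cfg,
        "seed": cfg["seed"],
        "inputs": inputs,
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
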
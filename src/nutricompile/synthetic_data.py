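"""Seeded generators for every pipeline input.

No survey microdata or licensed food-composition tables ship with the
package, so every stage is exercised on synthetic inputs with known ground
truth: a food table with a realistic 2/3/5-digit group hierarchy and
log-normal within-group nutrient densities, donor tables constructed so
that moisture-adjusted borrowing reproduces the intended values exactly,
recipes with closed-form composite values, and a weighted two-day survey
whose person-day intakes follow a linear age/sex mean structure with known
between- and within-person variance components. Intake events are built to
reproduce the simulated person-day totals exactly, so event-level,
person-level and population-level quantities all have checkable truths.

All randomness flows through one ``numpy`` generator per call; the same
seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .compilation import MatchPolicy, RecipeSpec, compile_database, resolve_recipes
from .food_db import DonorRecord, FoodRecord
from .intake_pipeline import IntakeEvent, Respondent

# Two-digit food groups: label, typical choline density (median mg/100 g of
# a log-normal) and relative consumption popularity. Loosely animal-source-
# heavy the way real food supplies are: eggs and meat rich and frequently
# eaten, beverages and fruit poor.
GROUP2_PROFILE = {
    "11": ("Non-alcoholic beverages", 4.0, 1.5),
    "12": ("Cereals and cereal products", 20.0, 1.5),
    "13": ("Cereal-based products and dishes", 30.0, 1.5),
    "14": ("Fats and oils", 8.0, 0.6),
    "15": ("Fish and seafood products and dishes", 80.0, 0.8),
    "16": ("Fruit products and dishes", 8.0, 1.2),
    "17": ("Egg products and dishes", 230.0, 2.5),
    "18": ("Meat, poultry and game products and dishes", 85.0, 2.2),
    "19": ("Milk products and dishes", 16.0, 2.0),
    "20": ("Dairy and meat substitutes", 25.0, 0.3),
    "21": ("Soup", 12.0, 0.5),
    "22": ("Seed and nut products and dishes", 45.0, 0.6),
    "23": ("Savoury sauces and condiments", 10.0, 0.8),
    "24": ("Vegetable products and dishes", 15.0, 1.5),
    "25": ("Legume and pulse products and dishes", 35.0, 0.5),
    "26": ("Snack foods", 20.0, 0.7),
    "27": ("Sugar products and dishes", 5.0, 0.6),
    "28": ("Confectionery", 12.0, 0.7),
    "29": ("Alcoholic beverages", 6.0, 0.8),
    "30": ("Special dietary foods", 18.0, 0.2),
}

#: Within-group log-scale spread of nutrient density.
LOG_SIGMA = 0.55

# Population age-band sampling probabilities, shaped like a national survey.
AGE_BANDS = (
    ((2, 3), 0.05),
    ((4, 8), 0.07),
    ((9, 13), 0.06),
    ((14, 18), 0.06),
    ((19, 64), 0.60),
    ((65, 85), 0.16),
)

# True mean structure of daily intake (mg/day): linear in age, sex offset.
TRUE_INTERCEPT = 230.0
TRUE_AGE_SLOPE = 0.9
TRUE_FEMALE_OFFSET = -35.0


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    sigma2_between: Optional[float] = None
    sigma2_within: Optional[float] = None
    coefficients: dict = field(default_factory=dict)  # mean-structure betas
    group_effects: dict = field(default_factory=dict)  # per-group densities
    stratum_means: dict = field(default_factory=dict)  # label -> mg/day
    coverage_fraction: Optional[float] = None
    recipe_values: dict = field(default_factory=dict)  # recipe_id -> mg/100 g
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sigma2_between": self.sigma2_between,
            "sigma2_within": self.sigma2_within,
            "coefficients": self.coefficients,
            "group_effects": self.group_effects,
            "stratum_means": self.stratum_means,
            "coverage_fraction": self.coverage_fraction,
            "recipe_values": self.recipe_values,
            "extras": self.extras,
        }


@dataclass
class FoodDbBundle:
    """A target food list plus everything needed to compile it."""

    foods: list  # FoodRecord, no nutrient values assigned
    donors: list  # DonorRecord
    donor_matches: list  # (target_id, DonorRecord, MatchPolicy)
    recipes: list  # RecipeSpec
    analytical: dict  # food_id -> (choline, betaine)
    unmatched: list  # food ids left without any value
    truth: GroundTruth

    def compile(self):
        """Run the compilation stage on the bundle's own inputs."""
        return compile_database(
            self.foods, self.donor_matches, self.recipes, self.analytical
        )


def _make_food_ids(n: int, rng: np.random.Generator) -> list[str]:
    codes = list(GROUP2_PROFILE)
    ids: list[str] = []
    seen = set()
    while len(ids) < n:
        g2 = codes[rng.integers(len(codes))]
        tail = "".join(str(d) for d in rng.integers(0, 10, size=6))
        fid = g2 + tail
        if fid not in seen:
            seen.add(fid)
            ids.append(fid)
    return ids


def generate_food_db(
    n_foods: int = 400,
    coverage_fraction: float = 0.9751,
    seed: int = 0,
    analytical_fraction: float = 0.02,
    recipe_count: int = 6,
    betaine_fraction: float = 0.7,
) -> FoodDbBundle:
    """Generate a food list, donor table, recipes and unmatched set.

    Exactly ``round(coverage_fraction * n_foods)`` foods end up with a
    nutrient value after compilation: a small analytical share, a few
    recipe composites, and the rest borrowed from donors whose moisture and
    density are constructed so that the moisture adjustment lands exactly
    on the intended target value. The remaining foods form the unmatched
    set (flagged zeros downstream).
    """
    rng = np.random.default_rng(seed)
    ids = _make_food_ids(n_foods, rng)

    foods, density = [], {}
    for fid in ids:
        label, median, _ = GROUP2_PROFILE[fid[:2]]
        moisture = float(np.round(rng.uniform(3.0, 92.0), 2))
        protein = float(np.round(rng.uniform(0.5, 30.0), 2))
        energy = float(np.round(rng.uniform(100.0, 2500.0), 1))
        foods.append(FoodRecord(
            food_id=fid, name=f"{label} item {fid[5:]}",
            moisture=moisture, protein=protein, energy=energy,
        ))
        density[fid] = float(median * rng.lognormal(0.0, LOG_SIGMA))

    n_valued = round(coverage_fraction * n_foods)
    valued_ids = list(rng.choice(ids, size=n_valued, replace=False))
    unmatched = sorted(set(ids) - set(valued_ids))

    n_recipe = min(recipe_count, max(n_valued - 10, 0))
    recipe_ids = valued_ids[:n_recipe]
    n_analytical = max(1, round(analytical_fraction * n_valued))
    analytical_ids = valued_ids[n_recipe:n_recipe + n_analytical]
    borrowed_ids = valued_ids[n_recipe + n_analytical:]

    by_id = {f.food_id: f for f in foods}
    has_betaine = {
        fid: bool(rng.random() < betaine_fraction) for fid in valued_ids
    }

    analytical = {}
    for fid in analytical_ids:
        # analytical sources report to 4 decimals; the rounded figure IS the value
        density[fid] = round(density[fid], 4)
        bet = (round(density[fid] * float(rng.uniform(0.1, 0.8)), 4)
               if has_betaine[fid] else None)
        analytical[fid] = (density[fid], bet)

    donors, donor_matches = [], []
    for k, fid in enumerate(borrowed_ids):
        tgt = by_id[fid]
        donor_moisture = float(np.clip(
            tgt.moisture + rng.normal(0.0, 6.0), 0.0, 98.0))
        # Invert the moisture adjustment so borrowing reproduces density[fid].
        donor_choline = (density[fid] * (100.0 - donor_moisture)
                         / (100.0 - tgt.moisture))
        donor_betaine = None
        if has_betaine[fid]:
            donor_betaine = donor_choline * float(rng.uniform(0.1, 0.8))
        donor = DonorRecord(
            donor_id=f"D{k:05d}",
            donor_name=f"donor match for {tgt.name}",
            moisture=donor_moisture,
            protein=float(np.round(rng.uniform(0.5, 30.0), 2)),
            choline=donor_choline,
            betaine=donor_betaine,
            donor_source="donor database",
        )
        same = rng.random(3) < 0.8
        donors.append(donor)
        donor_matches.append((fid, donor, MatchPolicy(
            adjustment="moisture",
            same_species=bool(same[0]),
            same_part_or_cut=bool(same[1]),
            same_processing_or_cooking=bool(same[2]),
        )))

    ingredient_pool = borrowed_ids + analytical_ids
    recipes = []
    for rid in recipe_ids:
        k = int(rng.integers(2, 5))
        ing = rng.choice(ingredient_pool, size=k, replace=False)
        recipes.append(RecipeSpec(
            recipe_id=rid,
            ingredients=[
                (str(i), float(np.round(rng.uniform(20.0, 300.0), 1)),
                 float(np.round(rng.uniform(0.7, 1.0), 2)))
                for i in ing
            ],
            weight_change_factor=float(np.round(rng.uniform(0.7, 1.2), 3)),
        ))

    base_lookup = {fid: density[fid] for fid in borrowed_ids + analytical_ids}
    recipe_values = resolve_recipes(recipes, base_lookup)
    for rid, value in recipe_values.items():
        density[rid] = value

    truth = GroundTruth(
        coverage_fraction=coverage_fraction,
        recipe_values={k: float(v) for k, v in recipe_values.items()},
        group_effects={
            g2: float(np.mean([density[f] for f in valued_ids
                               if f.startswith(g2)]))
            for g2 in GROUP2_PROFILE
            if any(f.startswith(g2) for f in valued_ids)
        },
        extras={
            "n_foods": n_foods,
            "n_valued": n_valued,
            "density": {fid: float(density[fid]) for fid in valued_ids},
            "unmatched": unmatched,
        },
    )
    return FoodDbBundle(
        foods=foods, donors=donors, donor_matches=donor_matches,
        recipes=recipes, analytical=analytical, unmatched=unmatched,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Survey generation


@dataclass
class SurveyBundle:
    """Respondents, intake events and the truth behind them."""

    respondents: list  # Respondent
    events: list  # IntakeEvent
    person_days: list  # (resp_id, day) pairs in the design
    truth: GroundTruth


def true_mean_intake(age: float, sex: str) -> float:
    """The generator's expected daily intake for given demographics."""
    return (TRUE_INTERCEPT + TRUE_AGE_SLOPE * age
            + (TRUE_FEMALE_OFFSET if sex == "female" else 0.0))


def _replicate_weights(weights: np.ndarray, R: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Delete-a-group columns: group g zeroed, the rest scaled by R/(R-1)."""
    n = len(weights)
    groups = rng.permutation(np.arange(n) % R)
    rw = np.repeat(weights[:, None], R, axis=1) * R / (R - 1)
    rw[np.arange(n), groups] = 0.0
    return rw


def generate_survey(
    n_respondents: int = 2000,
    seed: int = 0,
    sigma2_between: float = 400.0,
    sigma2_within: float = 1600.0,
    r_replicates: int = 30,
    day2_fraction: float = 0.8,
    weight_scale: float = 1000.0,
    weight_dispersion: float = 0.3,
    compiled_db: Optional[Mapping[str, float]] = None,
    max_events_per_day: int = 5,
) -> SurveyBundle:
    """Generate a weighted two-day survey with known variance components.

    Person-day intake is ``mu(age, sex) + u_i + e_ij`` with
    ``u_i ~ N(0, sigma2_between)`` and ``e_ij ~ N(0, sigma2_within)``; a
    ``day2_fraction`` subset reports a second day. Events are constructed
    (2-5 foods per day, Dirichlet shares, grams back-solved through each
    food's density) so that summing event nutrient masses reproduces the
    simulated person-day intake to floating-point accuracy.

    ``compiled_db`` maps food_id to mg/100 g; when omitted a small fully-
    covered food bundle is generated internally (sub-seeded from ``seed``).
    """
    rng = np.random.default_rng(seed)
    if r_replicates < 2:
        raise ValueError("need at least 2 replicate-weight groups")

    if compiled_db is None:
        bundle = generate_food_db(
            n_foods=120, coverage_fraction=1.0,
            seed=int(rng.integers(2 ** 31)),
        )
        compiled_db = {
            r.food_id: r.choline for r in bundle.compile() if r.has_value
        }
    consumable = sorted(
        fid for fid, v in compiled_db.items() if v is not None and v > 0
    )
    if not consumable:
        raise ValueError("compiled_db has no foods with positive density")
    cons_density = np.array([compiled_db[f] for f in consumable])
    # Pick foods with probability following group popularity, split evenly
    # within a group, so source rankings have realistic structure.
    group_sizes: dict[str, int] = {}
    for fid in consumable:
        group_sizes[fid[:2]] = group_sizes.get(fid[:2], 0) + 1
    pick_p = np.array([
        GROUP2_PROFILE.get(f[:2], ("", 0.0, 1.0))[2] / group_sizes[f[:2]]
        for f in consumable
    ])
    pick_p = pick_p / pick_p.sum()

    bands, probs = zip(*AGE_BANDS)
    band_idx = rng.choice(len(bands), size=n_respondents, p=np.array(probs))
    ages = np.array([
        int(rng.integers(bands[b][0], bands[b][1] + 1)) for b in band_idx
    ])
    sexes = np.where(rng.random(n_respondents) < 0.5, "female", "male")
    stages = np.full(n_respondents, "none", dtype=object)
    fertile = (sexes == "female") & (ages >= 14) & (ages <= 50)
    draw = rng.random(n_respondents)
    stages[fertile & (draw < 0.03)] = "pregnant"
    stages[fertile & (draw >= 0.03) & (draw < 0.06)] = "lactating"

    weights = weight_scale * rng.lognormal(0.0, weight_dispersion,
                                           size=n_respondents)
    rw = _replicate_weights(weights, r_replicates, rng)
    education = rng.integers(1, 6, size=n_respondents)
    activity = rng.integers(1, 6, size=n_respondents)
    energy = np.clip(rng.normal(8700.0, 1800.0, size=n_respondents),
                     2000.0, None)

    respondents = [
        Respondent(
            resp_id=f"R{i:05d}", age=int(ages[i]), sex=str(sexes[i]),
            life_stage=str(stages[i]), weight=float(weights[i]),
            replicate_weights=tuple(np.round(rw[i], 6)),
            education_level=int(education[i]),
            activity_level=int(activity[i]),
            energy=float(np.round(energy[i], 1)),
        )
        for i in range(n_respondents)
    ]

    u = rng.normal(0.0, np.sqrt(sigma2_between), size=n_respondents)
    has_day2 = rng.random(n_respondents) < day2_fraction
    events: list[IntakeEvent] = []
    person_days: list[tuple] = []
    true_usual = {}
    day_intakes = {}
    for i, r in enumerate(respondents):
        mu = true_mean_intake(r.age, r.sex)
        true_usual[r.resp_id] = mu + u[i]
        days = (1, 2) if has_day2[i] else (1,)
        for day in days:
            person_days.append((r.resp_id, day))
            intake = mu + u[i] + rng.normal(0.0, np.sqrt(sigma2_within))
            intake = max(intake, 1.0)  # daily intake cannot be negative
            day_intakes[f"{r.resp_id}:{day}"] = float(intake)
            k = int(rng.integers(2, max_events_per_day + 1))
            picks = rng.choice(len(consumable), size=k, p=pick_p)
            shares = rng.dirichlet(np.ones(k))
            for j in range(k):
                fid = consumable[picks[j]]
                mg = shares[j] * intake
                grams = mg / cons_density[picks[j]] * 100.0
                events.append(IntakeEvent(
                    resp_id=r.resp_id, day=day, food_id=fid,
                    grams=float(grams),
                ))

    # Expected weighted stratum means, from the generated design itself.
    stratum_means = {}
    for label, mask in _default_strata(ages, sexes, stages).items():
        if mask.any():
            mus = np.array([
                true_mean_intake(int(a), str(s))
                for a, s in zip(ages[mask], sexes[mask])
            ])
            stratum_means[label] = float(
                np.sum(weights[mask] * mus) / np.sum(weights[mask])
            )

    truth = GroundTruth(
        sigma2_between=sigma2_between,
        sigma2_within=sigma2_within,
        coefficients={
            "const": TRUE_INTERCEPT,
            "age": TRUE_AGE_SLOPE,
            "sex": TRUE_FEMALE_OFFSET,
        },
        stratum_means=stratum_means,
        extras={
            "n_respondents": n_respondents,
            "r_replicates": r_replicates,
            "day2_fraction": day2_fraction,
            "true_usual": {k: float(v) for k, v in true_usual.items()},
            "day_intakes": day_intakes,
            "lambda_2": sigma2_between / (sigma2_between + sigma2_within / 2),
        },
    )
    return SurveyBundle(
        respondents=respondents, events=events, person_days=person_days,
        truth=truth,
    )


def _default_strata(ages, sexes, stages) -> dict:
    strata = {
        "Children 2-3 years": (ages >= 2) & (ages <= 3),
        "Children 4-8 years": (ages >= 4) & (ages <= 8),
    }
    plain = stages == "none"
    for sex in ("male", "female"):
        for lo, hi in ((9, 13), (14, 18), (19, 64), (65, 85)):
            label = f"{sex.capitalize()} {lo}-{hi} years"
            strata[label] = ((sexes == sex) & (ages >= lo) & (ages <= hi)
                             & plain)
    return strata


# ---------------------------------------------------------------------------
# Regression-model scenario


def generate_regression_dataset(
    n: int = 3000,
    coefficient: float = 48.2,
    seed: int = 0,
    r_replicates: int = 30,
    noise_sd: float = 40.0,
    consumer_fraction: float = 0.6,
    covariate_effects: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, GroundTruth]:
    """Respondent-level data with a known food-group effect.

    Total intake is generated as ``intercept + coefficient * (grams/100) +
    covariate effects + N(0, noise_sd)``; ``noise_sd=0`` gives a noiseless
    design that the fit must recover exactly. Returns (data, weights,
    replicate_weights, truth).
    """
    rng = np.random.default_rng(seed)
    effects = {
        "energy": 0.005, "activity_level": 1.0, "sex": -10.0,
        "age": 0.5, "education_level": 2.0,
    }
    if covariate_effects:
        effects.update(covariate_effects)
    intercept = 150.0

    consumes = rng.random(n) < consumer_fraction
    grams = np.where(consumes, rng.gamma(2.0, 60.0, size=n), 0.0)
    data = pd.DataFrame({
        "group_g": grams,
        "energy": np.clip(rng.normal(8700.0, 1500.0, size=n), 2000.0, None),
        "activity_level": rng.integers(1, 6, size=n).astype(float),
        "sex": (rng.random(n) < 0.5).astype(float),  # female = 1
        "age": rng.integers(19, 86, size=n).astype(float),
        "education_level": rng.integers(1, 6, size=n).astype(float),
    })
    signal = intercept + coefficient * grams / 100.0
    for name, eff in effects.items():
        signal = signal + eff * data[name].to_numpy()
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    data["total_mg"] = signal + noise

    weights = rng.lognormal(0.0, 0.3, size=n)
    rw = _replicate_weights(weights, r_replicates, rng)
    truth = GroundTruth(
        coefficients={"const": intercept, "group_per_100g": coefficient,
                      **effects},
        extras={"noise_sd": noise_sd, "n": n, "r_replicates": r_replicates},
    )
    return data, weights, rw, truth


# ---------------------------------------------------------------------------
# Scenario presets and file output


SCENARIOS = {
    "tiny": dict(n_foods=60, n_respondents=150, r_replicates=8),
    "paper-like": dict(n_foods=400, n_respondents=2000, r_replicates=30),
}


def simulate_bundle(scenario: str = "paper-like", seed: int = 0,
                    coverage_fraction: float = 0.9751,
                    sigma2_between: float = 400.0,
                    sigma2_within: float = 1600.0) -> tuple:
    """(FoodDbBundle, SurveyBundle) for a named scenario preset."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {sorted(SCENARIOS)}")
    cfg = SCENARIOS[scenario]
    food = generate_food_db(
        n_foods=cfg["n_foods"], coverage_fraction=coverage_fraction,
        seed=seed,
    )
    compiled = {
        r.food_id: r.choline for r in food.compile() if r.has_value
    }
    survey = generate_survey(
        n_respondents=cfg["n_respondents"], seed=seed + 1,
        sigma2_between=sigma2_between, sigma2_within=sigma2_within,
        r_replicates=cfg["r_replicates"], compiled_db=compiled,
    )
    return food, survey


def respondents_to_frame(respondents: Sequence[Respondent]) -> pd.DataFrame:
    rows = []
    for r in respondents:
        row = {
            "resp_id": r.resp_id, "age": r.age, "sex": r.sex,
            "life_stage": r.life_stage, "weight": repr(r.weight),
            "education_level": r.education_level,
            "activity_level": r.activity_level, "energy": repr(r.energy),
        }
        for g, w in enumerate(r.replicate_weights):
            row[f"repw_{g}"] = repr(float(w))
        rows.append(row)
    return pd.DataFrame(rows)


def respondents_from_frame(df: pd.DataFrame) -> list[Respondent]:
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("repw_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return [
        Respondent(
            resp_id=str(row["resp_id"]), age=int(row["age"]),
            sex=str(row["sex"]), life_stage=str(row["life_stage"]),
            weight=float(row["weight"]),
            replicate_weights=tuple(float(row[c]) for c in rep_cols),
            education_level=int(row["education_level"]),
            activity_level=int(row["activity_level"]),
            energy=float(row["energy"]),
        )
        for _, row in df.iterrows()
    ]


def events_to_csv_frame(events: Sequence[IntakeEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {"resp_id": e.resp_id, "day": e.day, "food_id": e.food_id,
         "grams": repr(e.grams)}
        for e in events
    ])
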
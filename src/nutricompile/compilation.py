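"""Compilation of the nutrient database.

Borrowed values are taken from donor foods in external databases or studies
and rescaled for compositional differences between donor and target food:
choline and betaine are water-soluble, so the default rescaling preserves
the concentration in dry matter (moisture adjustment); a protein adjustment
is available for food pairs where the nutrient tracks protein content.
Each borrowed value carries an A-D confidence code grading the quality of
the food match. Composite foods are computed from recipes with a
weight-change (yield) factor and optional per-ingredient retention factors.
Foods for which no value can be found receive a flagged zero, distinct from
a true analytical zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import (
    AdjustmentError,
    CompilationError,
    ConfigError,
    CycleError,
    ValidationError,
)
from .food_db import DonorRecord, FoodRecord

logger = logging.getLogger(__name__)

ADJUSTMENTS = ("none", "moisture", "protein", "moisture+protein")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of borrowing a donor value for one target food."""

    target_id: str
    donor_id: str
    adjustment: str  # one of ADJUSTMENTS
    confidence: str  # A-D
    adjusted_choline: float  # mg/100 g
    adjusted_betaine: Optional[float] = None
    rationale: str = ""

    def __post_init__(self):
        if self.adjustment not in ADJUSTMENTS:
            raise ValidationError(f"unknown adjustment {self.adjustment!r}")
        if self.adjusted_choline < 0:
            raise ValidationError("adjusted choline must be >= 0")
        if self.adjusted_betaine is not None and self.adjusted_betaine < 0:
            raise ValidationError("adjusted betaine must be >= 0")
        if self.confidence not in ("A", "B", "C", "D"):
            raise ValidationError(
                f"borrowed value needs a confidence code, got {self.confidence!r}"
            )


@dataclass(frozen=True)
class RecipeSpec:
    """A composite food defined by ingredient weights and a yield factor.

    ``ingredients`` is an ordered sequence of (food_id, raw_weight_g,
    retention) triples; retention is the fraction of the nutrient surviving
    cooking, in (0, 1], defaulting to 1. ``weight_change_factor`` is the
    ratio of cooked to raw total weight (> 0), accounting for moisture loss
    or gain during cooking.
    """

    recipe_id: str
    ingredients: tuple
    weight_change_factor: float

    def __init__(self, recipe_id, ingredients, weight_change_factor):
        norm = []
        for entry in ingredients:
            if len(entry) == 2:
                ing_id, weight = entry
                retention = 1.0
            else:
                ing_id, weight, retention = entry
            if weight <= 0:
                raise ValidationError(
                    f"recipe {recipe_id}: non-positive ingredient weight"
                )
            if not (0 < retention <= 1):
                raise ValidationError(
                    f"recipe {recipe_id}: retention {retention} outside (0, 1]"
                )
            norm.append((str(ing_id), float(weight), float(retention)))
        if not norm:
            raise ValidationError(f"recipe {recipe_id}: no ingredients")
        if weight_change_factor <= 0:
            raise ValidationError(
                f"recipe {recipe_id}: weight_change_factor must be > 0"
            )
        object.__setattr__(self, "recipe_id", str(recipe_id))
        object.__setattr__(self, "ingredients", tuple(norm))
        object.__setattr__(self, "weight_change_factor", float(weight_change_factor))


@dataclass(frozen=True)
class MatchPolicy:
    """How one donor-target pair is borrowed.

    The sameness flags come from the (human) matcher and drive the
    confidence code; ``adjustment`` selects which compositional rescaling to
    apply. When a protein adjustment is impossible (donor protein 0) and
    ``allow_fallback`` is set, the moisture adjustment is used instead.
    ``energy_ratio_tolerance``, when set, rejects pairs whose energy
    densities differ by more than the given ratio.
    """

    adjustment: str = "moisture"
    same_species: bool = True
    same_part_or_cut: bool = True
    same_processing_or_cooking: bool = True
    allow_fallback: bool = True
    energy_ratio_tolerance: Optional[float] = None

    def __post_init__(self):
        if self.adjustment not in ADJUSTMENTS:
            raise ConfigError(f"unknown adjustment {self.adjustment!r}")


def moisture_adjust(value: float, moisture_src: float, moisture_tgt: float
                    ) -> float:
    """Rescale a per-100 g value from donor to target moisture.

    The nutrient concentration in dry matter is preserved:
    ``adjusted = value * (100 - moisture_tgt) / (100 - moisture_src)``.
    """
    if value < 0:
        raise ValidationError("value must be >= 0")
    if moisture_src >= 100:
        raise AdjustmentError(
            f"donor moisture {moisture_src} >= 100 g/100 g: no dry matter"
        )
    if moisture_tgt >= 100:
        raise AdjustmentError(
            f"target moisture {moisture_tgt} >= 100 g/100 g: no dry matter"
        )
    return value * (100.0 - moisture_tgt) / (100.0 - moisture_src)


def protein_adjust(value: float, protein_src: float, protein_tgt: float
                   ) -> float:
    """Rescale a per-100 g value proportionally to protein content.

    ``adjusted = value * protein_tgt / protein_src``. Applicable only to
    food pairs where the nutrient is protein-associated.
    """
    if protein_src <= 0:
        raise AdjustmentError(
            "donor protein is 0: protein adjustment not applicable"
        )
    if value < 0:
        raise ValidationError("value must be >= 0")
    return value * protein_tgt / protein_src


def assign_confidence(same_species: bool, same_part_or_cut: bool,
                      same_processing_or_cooking: bool,
                      adjustment_needed: bool) -> str:
    """Grade a food match from A (exact) to D (weak).

    Rubric (fixed in the package documentation): A - all three sameness
    criteria hold and no compositional adjustment was needed; B - all three
    hold but an adjustment was applied, or exactly one criterion relaxed;
    C - two criteria relaxed; D - all three relaxed. Relaxing any criterion
    never improves the code.
    """
    relaxed = 3 - sum(
        (same_species, same_part_or_cut, same_processing_or_cooking)
    )
    if relaxed == 0:
        return "B" if adjustment_needed else "A"
    if relaxed == 1:
        return "B"
    if relaxed == 2:
        return "C"
    return "D"


def borrow_value(target: FoodRecord, donor: DonorRecord,
                 policy: MatchPolicy = MatchPolicy()) -> MatchResult:
    """Borrow the donor's nutrient values for the target food.

    Applies the policy's adjustment to choline, and the same adjustment to
    betaine when the donor reports it; assigns a confidence code from the
    policy's sameness flags.
    """
    if policy.energy_ratio_tolerance is not None and target.energy > 0:
        # Energy screen for substitutions justified by similar energy density.
        ratio = donor_energy_ratio(target, donor)
        if ratio is not None and ratio > policy.energy_ratio_tolerance:
            raise CompilationError(
                f"{target.food_id}: donor {donor.donor_id} rejected, energy "
                f"ratio {ratio:.3f} exceeds tolerance "
                f"{policy.energy_ratio_tolerance:.3f}"
            )

    adjustment = policy.adjustment

    def apply(value: float) -> tuple[float, str]:
        if adjustment == "none":
            return value, "none"
        adj = value
        applied = []
        if "moisture" in adjustment:
            adj = moisture_adjust(adj, donor.moisture, target.moisture)
            applied.append("moisture")
        if "protein" in adjustment:
            try:
                adj = protein_adjust(adj, donor.protein, target.protein)
                applied.append("protein")
            except AdjustmentError:
                if not policy.allow_fallback:
                    raise
                if "moisture" not in applied:
                    adj = moisture_adjust(value, donor.moisture, target.moisture)
                    applied = ["moisture"]
                logger.warning(
                    "%s: protein adjustment impossible for donor %s, "
                    "fell back to %s", target.food_id, donor.donor_id,
                    "+".join(applied) or "none",
                )
        return adj, "+".join(applied) if applied else "none"

    choline_adj, applied = apply(donor.choline)
    betaine_adj = None
    if donor.betaine is not None:
        betaine_adj, _ = apply(donor.betaine)

    adjustment_needed = applied != "none" and not _is_identity(
        target, donor, applied
    )
    confidence = assign_confidence(
        policy.same_species, policy.same_part_or_cut,
        policy.same_processing_or_cooking, adjustment_needed,
    )
    return MatchResult(
        target_id=target.food_id,
        donor_id=donor.donor_id,
        adjustment=applied,
        confidence=confidence,
        adjusted_choline=choline_adj,
        adjusted_betaine=betaine_adj,
        rationale=(
            f"borrowed from {donor.donor_name!r} ({donor.donor_source}), "
            f"adjustment={applied}"
        ),
    )


def _is_identity(target: FoodRecord, donor: DonorRecord, applied: str) -> bool:
    """True when the applied adjustment did not change the value."""
    ok = True
    if "moisture" in applied:
        ok &= target.moisture == donor.moisture
    if "protein" in applied:
        ok &= target.protein == donor.protein
    return ok


def donor_energy_ratio(target: FoodRecord, donor: DonorRecord
                       ) -> Optional[float]:
    """Max/min ratio of energy densities, or None if donor energy unknown."""
    donor_energy = getattr(donor, "energy", None)
    if donor_energy in (None, 0) or target.energy == 0:
        return None
    hi, lo = max(donor_energy, target.energy), min(donor_energy, target.energy)
    return hi / lo


# ---------------------------------------------------------------------------
# Recipe engine


def compute_recipe(recipe: RecipeSpec, lookup: Mapping[str, float]) -> float:
    """Nutrient density (mg/100 g) of the cooked composite food.

    ``100 * sum_i(raw_weight_i * value_i / 100 * retention_i)`` divided by
    the cooked mass ``weight_change_factor * sum_i raw_weight_i``. The
    lookup maps ingredient food ids to their per-100 g values; nested
    recipes must have been resolved into the lookup beforehand (see
    :func:`resolve_recipes`).
    """
    missing = [i for i, _, _ in recipe.ingredients if i not in lookup]
    if missing:
        raise CompilationError(
            f"recipe {recipe.recipe_id}: unresolved ingredients "
            f"{', '.join(missing)}", ids=missing,
        )
    raw_total = sum(w for _, w, _ in recipe.ingredients)
    nutrient_mass = sum(
        w * lookup[i] / 100.0 * ret for i, w, ret in recipe.ingredients
    )
    cooked_mass = recipe.weight_change_factor * raw_total
    return 100.0 * nutrient_mass / cooked_mass


def resolve_recipes(recipes: Sequence[RecipeSpec],
                    base_lookup: Mapping[str, float]) -> dict[str, float]:
    """Compute all recipes, resolving nesting in topological order.

    Returns {recipe_id: mg/100 g}. A recipe may use another recipe's id as
    an ingredient; cycles (including self-reference) are hard errors naming
    the cycle.
    """
    by_id = {r.recipe_id: r for r in recipes}
    resolved: dict[str, float] = {}
    state: dict[str, int] = {}  # 1 = in progress, 2 = done

    def visit(rid: str, stack: list[str]) -> None:
        if state.get(rid) == 2:
            return
        if state.get(rid) == 1:
            cycle = stack[stack.index(rid):] + [rid]
            raise CycleError(
                f"cyclic recipe nesting: {' -> '.join(cycle)}", cycle=cycle,
            )
        state[rid] = 1
        stack.append(rid)
        for ing_id, _, _ in by_id[rid].ingredients:
            if ing_id in by_id and ing_id not in base_lookup:
                visit(ing_id, stack)
        stack.pop()
        lookup = dict(base_lookup)
        lookup.update(resolved)
        resolved[rid] = compute_recipe(by_id[rid], lookup)
        state[rid] = 2

    for rid in by_id:
        visit(rid, [])
    return resolved


# ---------------------------------------------------------------------------
# Zero policy, QA, coverage


def apply_zero_policy(unmatched: Iterable[str],
                      records: Sequence[FoodRecord]) -> list[FoodRecord]:
    """Assign a flagged zero to each unmatched food.

    The zero marks "no value identified", not an analytical zero; the flag
    keeps the two distinguishable downstream. Foods that already carry a
    value may not be listed as unmatched.
    """
    unmatched = set(unmatched)
    by_id = {r.food_id: r for r in records}
    missing = unmatched - set(by_id)
    if missing:
        raise CompilationError(
            f"unmatched ids not in database: {sorted(missing)}",
            ids=sorted(missing),
        )
    already = [i for i in unmatched if by_id[i].choline is not None]
    if already:
        raise CompilationError(
            f"foods already valued cannot be zero-filled: {sorted(already)}",
            ids=sorted(already),
        )
    out = []
    for r in records:
        if r.food_id in unmatched:
            r = r.with_value(choline=0.0, source="unmatched_zero",
                             unmatched_zero_flag=True)
        out.append(r)
    return out


@dataclass
class QAReport:
    """Quality-assurance summary of a compiled database."""

    ranked_ids: list  # food ids, descending by choline value
    range_violations: list  # (food_id, value, (low, high))
    duplicate_mismatches: list  # (food_id, value, recomputed)
    verification_sample: list  # food ids drawn for manual source checking

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"food_id": f, "value": v, "low": b[0], "high": b[1]}
             for f, v, b in self.range_violations]
        )


def qa_checks(records: Sequence[FoodRecord],
              bounds: Optional[Mapping[str, tuple]] = None,
              default_bound: tuple = (0.0, 2000.0),
              fraction: float = 0.10,
              seed: int = 0,
              recomputed: Optional[Mapping[str, float]] = None) -> QAReport:
    """Rank-order foods, apply per-group range checks and draw a
    verification sample.

    ``bounds`` maps 2-digit group codes to (low, high) mg/100 g; groups
    without an entry use ``default_bound``. The verification sample of
    ``round(fraction * n)`` foods is drawn without replacement with a seeded
    generator, so identical seeds give identical samples. ``recomputed``,
    when given, holds independently recalculated values for
    duplicate-calculation checking.
    """
    if not (0 < fraction <= 1):
        raise ConfigError(f"fraction {fraction} outside (0, 1]")
    valued = [r for r in records if r.choline is not None]
    ranked = sorted(valued, key=lambda r: (-r.choline, r.food_id))
    violations = []
    for r in valued:
        low, high = (bounds or {}).get(r.group2, default_bound)
        if not (low <= r.choline <= high):
            violations.append((r.food_id, r.choline, (low, high)))
    mismatches = []
    if recomputed:
        by_id = {r.food_id: r for r in records}
        for fid, value in recomputed.items():
            if fid in by_id and by_id[fid].choline is not None:
                if abs(by_id[fid].choline - value) > 1e-9:
                    mismatches.append((fid, by_id[fid].choline, value))
    rng = np.random.default_rng(seed)
    ids = sorted(r.food_id for r in records)
    k = round(fraction * len(ids))
    sample = sorted(rng.choice(ids, size=k, replace=False)) if k else []
    return QAReport(
        ranked_ids=[r.food_id for r in ranked],
        range_violations=violations,
        duplicate_mismatches=mismatches,
        verification_sample=list(sample),
    )


def coverage_stats(records: Sequence[FoodRecord]) -> tuple[int, float, int]:
    """(foods with a genuine value, percent of total to 2 dp, foods with
    betaine).

    Flagged zeros for unmatched foods do not count as values.
    """
    total = len(records)
    n_value = sum(1 for r in records if r.has_value)
    n_betaine = sum(1 for r in records if r.betaine is not None)
    pct = round(100.0 * n_value / total, 2) if total else 0.0
    return n_value, pct, n_betaine


# ---------------------------------------------------------------------------
# End-to-end compilation


def compile_database(
    foods: Sequence[FoodRecord],
    donor_matches: Sequence[tuple] = (),
    recipes: Sequence[RecipeSpec] = (),
    analytical: Optional[Mapping[str, tuple]] = None,
    fill_unmatched_zero: bool = True,
) -> list[FoodRecord]:
    """Build the compiled nutrient database.

    Precedence: analytical values, then borrowed donor values, then recipe
    composites (which may consume both), then flagged zeros for whatever
    remains. ``donor_matches`` is a sequence of (target_id, DonorRecord,
    MatchPolicy) triples; ``analytical`` maps food_id to (choline, betaine).
    """
    by_id: dict[str, FoodRecord] = {}
    for r in foods:
        if r.food_id in by_id:
            raise CompilationError(f"duplicate food_id {r.food_id}")
        by_id[r.food_id] = r

    for fid, values in (analytical or {}).items():
        choline, betaine = values if isinstance(values, tuple) else (values, None)
        if fid not in by_id:
            raise CompilationError(f"analytical value for unknown food {fid}")
        by_id[fid] = by_id[fid].with_value(
            choline=float(choline),
            betaine=None if betaine is None else float(betaine),
            source="analytical", confidence="none",
        )

    for target_id, donor, policy in donor_matches:
        if target_id not in by_id:
            raise CompilationError(f"match target {target_id} not in food list")
        if by_id[target_id].has_value:
            continue  # analytical data wins over borrowing
        match = borrow_value(by_id[target_id], donor, policy)
        by_id[target_id] = by_id[target_id].with_value(
            choline=match.adjusted_choline, betaine=match.adjusted_betaine,
            source="borrowed", confidence=match.confidence,
            donor_id=match.donor_id,
        )

    if recipes:
        base_lookup = {
            fid: r.choline for fid, r in by_id.items() if r.choline is not None
        }
        computed = resolve_recipes(recipes, base_lookup)
        betaine_lookup = {
            fid: r.betaine for fid, r in by_id.items() if r.betaine is not None
        }
        for rec in recipes:
            if rec.recipe_id not in by_id:
                raise CompilationError(
                    f"recipe id {rec.recipe_id} not in food list"
                )
            betaine = None
            if all(i in betaine_lookup or i in {x.recipe_id for x in recipes}
                   for i, _, _ in rec.ingredients):
                try:
                    betaine = resolve_recipes(
                        [r for r in recipes], betaine_lookup
                    ).get(rec.recipe_id)
                except CompilationError:
                    betaine = None
            by_id[rec.recipe_id] = by_id[rec.recipe_id].with_value(
                choline=computed[rec.recipe_id], betaine=betaine,
                source="recipe", confidence="none",
            )

    records = list(by_id.values())
    if fill_unmatched_zero:
        unmatched = [r.food_id for r in records if r.choline is None]
        records = apply_zero_policy(unmatched, records)
    return records
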
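"""Value borrowing, adjustments, recipes, zero policy, QA and coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutricompile.compilation import (
    MatchPolicy,
    RecipeSpec,
    apply_zero_policy,
    assign_confidence,
    borrow_value,
    compute_recipe,
    coverage_stats,
    moisture_adjust,
    protein_adjust,
    qa_checks,
    resolve_recipes,
)
from nutricompile.errors import (
    AdjustmentError,
    CompilationError,
    ConfigError,
    CycleError,
)
from nutricompile.food_db import DonorRecord, FoodRecord
from nutricompile.synthetic_data import generate_food_db


def food(fid="18000001", moisture=60.0, protein=20.0, **kw):
    return FoodRecord(fid, "test food", moisture, protein, 800.0, **kw)


def donor(moisture=60.0, protein=20.0, choline=100.0, betaine=None):
    return DonorRecord("D1", "donor food", moisture, protein, choline,
                       betaine=betaine)


class TestMoistureAdjust:
    def test_identity_when_moistures_equal(self):
        assert moisture_adjust(100.0, 60.0, 60.0) == 100.0

    def test_dry_matter_rescaling(self):
        # 100 mg in 40 g dry matter -> 20 g dry matter keeps the ratio
        assert moisture_adjust(100.0, 60.0, 80.0) == pytest.approx(50.0)

    def test_zero_preserved(self):
        assert moisture_adjust(0.0, 30.0, 70.0) == 0.0

    def test_saturated_donor_rejected(self):
        with pytest.raises(AdjustmentError):
            moisture_adjust(10.0, 100.0, 50.0)

    @given(
        value=st.floats(0, 1e4),
        a=st.floats(0, 99.5),
        b=st.floats(0, 99.5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_conserves_dry_matter(self, value, a, b):
        back = moisture_adjust(moisture_adjust(value, a, b), b, a)
        assert back == pytest.approx(value, rel=1e-9, abs=1e-9)


class TestProteinAdjust:
    def test_proportional_rescale(self):
        assert protein_adjust(80.0, 20.0, 10.0) == pytest.approx(40.0)

    def test_identity(self):
        assert protein_adjust(80.0, 15.0, 15.0) == 80.0

    def test_zero_donor_protein_not_applicable(self):
        with pytest.raises(AdjustmentError):
            protein_adjust(80.0, 0.0, 10.0)


class TestAssignConfidence:
    @pytest.mark.parametrize("flags,expected", [
        ((True, True, True, False), "A"),
        ((True, True, True, True), "B"),
        ((False, True, True, False), "B"),
        ((False, False, True, True), "C"),
        ((False, False, False, True), "D"),
        ((False, False, False, False), "D"),
    ])
    def test_rubric(self, flags, expected):
        assert assign_confidence(*flags) == expected

    @given(st.booleans(), st.booleans(), st.booleans(), st.booleans())
    @settings(derandomize=True)
    def test_relaxing_a_flag_never_improves(self, s1, s2, s3, adj):
        code = assign_confidence(s1, s2, s3, adj)
        for i, flag in enumerate((s1, s2, s3)):
            if flag:
                relaxed = [s1, s2, s3]
                relaxed[i] = False
                assert assign_confidence(*relaxed, adj) >= code


class TestBorrowValue:
    def test_exact_match_confidence_a_value_unchanged(self):
        match = borrow_value(food(moisture=60), donor(moisture=60),
                             MatchPolicy(adjustment="moisture"))
        assert match.adjusted_choline == 100.0
        assert match.confidence == "A"

    def test_moisture_adjustment_halves_value(self):
        match = borrow_value(food(moisture=80), donor(moisture=60),
                             MatchPolicy(adjustment="moisture"))
        assert match.adjusted_choline == pytest.approx(50.0)
        assert match.adjustment == "moisture"
        assert match.confidence == "B"  # adjustment downgrades an exact match

    def test_missing_betaine_propagates_as_absent(self):
        match = borrow_value(food(), donor(betaine=None))
        assert match.adjusted_betaine is None

    def test_betaine_gets_same_adjustment(self):
        match = borrow_value(food(moisture=80), donor(moisture=60,
                                                      betaine=40.0))
        assert match.adjusted_betaine == pytest.approx(20.0)

    def test_protein_fallback_to_moisture(self):
        match = borrow_value(
            food(moisture=80), donor(moisture=60, protein=0.0),
            MatchPolicy(adjustment="protein", allow_fallback=True))
        assert match.adjustment == "moisture"

    def test_protein_failure_without_fallback_rejected(self):
        with pytest.raises(AdjustmentError):
            borrow_value(food(), donor(protein=0.0),
                         MatchPolicy(adjustment="protein",
                                     allow_fallback=False))


class TestComputeRecipe:
    def test_closed_form_two_ingredient_composite(self):
        # 50 mg of nutrient ends up in 80 g of cooked food -> 62.5 mg/100 g
        recipe = RecipeSpec("13900001",
                            [("A", 50.0, 1.0), ("B", 50.0, 1.0)], 0.8)
        assert compute_recipe(recipe, {"A": 100.0, "B": 0.0}) == \
            pytest.approx(62.5)

    def test_identity_recipe(self):
        recipe = RecipeSpec("13900001", [("A", 120.0, 1.0)], 1.0)
        assert compute_recipe(recipe, {"A": 77.7}) == pytest.approx(77.7)

    def test_linear_in_retention(self):
        full = RecipeSpec("13900001", [("A", 120.0, 1.0)], 1.0)
        cooked = RecipeSpec("13900001", [("A", 120.0, 0.7)], 1.0)
        assert compute_recipe(cooked, {"A": 100.0}) == \
            pytest.approx(0.7 * compute_recipe(full, {"A": 100.0}))

    @given(
        weights=st.lists(st.floats(1.0, 500.0), min_size=1, max_size=6),
        values=st.lists(st.floats(0.0, 500.0), min_size=6, max_size=6),
        wcf=st.floats(0.5, 1.5),
        scale=st.sampled_from([2.0, 4.0, 0.5]),
    )
    @settings(max_examples=60, derandomize=True)
    def test_mass_balance_and_weight_scale_invariance(
            self, weights, values, wcf, scale):
        lookup = {f"ing{i}": v for i, v in enumerate(values)}
        ingredients = [(f"ing{i}", w, 1.0) for i, w in enumerate(weights)]
        recipe = RecipeSpec("13900001", ingredients, wcf)
        per100 = compute_recipe(recipe, lookup)
        cooked_mass = wcf * sum(weights)
        nutrient_out = per100 * cooked_mass / 100.0
        nutrient_in = sum(w * lookup[i] / 100.0 for i, w, _ in ingredients)
        assert nutrient_out == pytest.approx(nutrient_in, rel=1e-12)
        doubled = RecipeSpec(
            "13900001", [(i, w * scale, r) for i, w, r in ingredients], wcf)
        assert compute_recipe(doubled, lookup) == \
            pytest.approx(per100, rel=1e-12)

    def test_unresolved_ingredient_listed(self):
        recipe = RecipeSpec("13900001", [("A", 50.0), ("B", 50.0)], 1.0)
        with pytest.raises(CompilationError) as err:
            compute_recipe(recipe, {"A": 10.0})
        assert err.value.ids == ["B"]

    def test_nested_recipes_resolved_topologically(self):
        inner = RecipeSpec("20000001", [("A", 100.0)], 1.0)
        outer = RecipeSpec("20000002", [("20000001", 100.0)], 1.0)
        values = resolve_recipes([outer, inner], {"A": 42.0})
        assert values["20000002"] == pytest.approx(42.0)

    def test_cycle_detected_and_named(self):
        a = RecipeSpec("20000001", [("20000002", 100.0)], 1.0)
        b = RecipeSpec("20000002", [("20000001", 100.0)], 1.0)
        with pytest.raises(CycleError) as err:
            resolve_recipes([a, b], {})
        assert set(err.value.cycle) >= {"20000001", "20000002"}


class TestZeroPolicy:
    def make_db(self):
        return [food(f"1800000{i}", choline=(100.0 if i < 7 else None),
                     source=("borrowed" if i < 7 else None),
                     confidence=("B" if i < 7 else "none"))
                for i in range(10)]

    def test_unmatched_get_flagged_zeros(self):
        db = self.make_db()
        unmatched = [r.food_id for r in db if r.choline is None]
        out = apply_zero_policy(unmatched, db)
        assert len(out) == 10
        flagged = [r for r in out if r.unmatched_zero_flag]
        assert len(flagged) == 3
        assert all(r.choline == 0.0 and r.source == "unmatched_zero"
                   for r in flagged)

    def test_empty_unmatched_is_noop(self):
        db = self.make_db()
        assert apply_zero_policy([], db) == db

    def test_valued_food_refused(self):
        db = self.make_db()
        with pytest.raises(CompilationError):
            apply_zero_policy([db[0].food_id], db)


class TestQAChecks:
    def test_sample_reproducible_under_seed(self, compiled_db):
        a = qa_checks(compiled_db, fraction=0.10, seed=42)
        b = qa_checks(compiled_db, fraction=0.10, seed=42)
        c = qa_checks(compiled_db, fraction=0.10, seed=43)
        assert a.verification_sample == b.verification_sample
        assert len(a.verification_sample) == round(0.10 * len(compiled_db))
        assert a.verification_sample != c.verification_sample

    def test_out_of_range_value_flagged(self):
        db = [food("18000001", choline=10000.0, source="borrowed",
                   confidence="D"),
              food("18000002", choline=100.0, source="borrowed",
                   confidence="B")]
        report = qa_checks(db, default_bound=(0.0, 2000.0), seed=0)
        assert report.range_violations == [
            ("18000001", 10000.0, (0.0, 2000.0))]
        assert report.ranked_ids[0] == "18000001"

    def test_all_within_bounds_no_violations(self, compiled_db):
        hi = max(r.choline for r in compiled_db if r.choline is not None)
        report = qa_checks(compiled_db, default_bound=(0.0, hi + 1), seed=0)
        assert report.range_violations == []

    @pytest.mark.parametrize("fraction", [0.0, 1.5, -0.1])
    def test_bad_fraction_rejected(self, fraction):
        with pytest.raises(ConfigError):
            qa_checks([food()], fraction=fraction)


class TestCoverageStats:
    def test_direct_count(self):
        db = [food(f"1800000{i}",
                   choline=(50.0 if i < 9 else 0.0),
                   source=("borrowed" if i < 9 else "unmatched_zero"),
                   confidence=("C" if i < 9 else "none"),
                   unmatched_zero_flag=(i >= 9))
              for i in range(10)]
        n, pct, _ = coverage_stats(db)
        assert (n, pct) == (9, 90.00)

    def test_full_coverage_is_100(self):
        db = [food("18000001", choline=50.0, source="borrowed",
                   confidence="C")]
        assert coverage_stats(db)[1] == 100.00

    def test_constructed_coverage_reported_exactly(self):
        bundle = generate_food_db(n_foods=1000, coverage_fraction=0.9751,
                                  seed=3)
        n, pct, _ = coverage_stats(bundle.compile())
        assert n == round(0.9751 * 1000)
        assert pct == 97.50  # 975 of 1000: the rounding of the achievable count

    def test_synthetic_compilation_reproduces_truth_densities(
            self, food_bundle, compiled_db):
        truth = food_bundle.truth.extras["density"]
        by_id = {r.food_id: r for r in compiled_db}
        for fid, value in truth.items():
            assert by_id[fid].choline == pytest.approx(value, rel=1e-9)
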
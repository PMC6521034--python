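"""Weighted means, jackknife SEs, quartiles, AI attainment, group tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutricompile.food_db import default_ai_references
from nutricompile.intake_pipeline import Respondent
from nutricompile.survey_stats import (
    GroupDef,
    ai_attainment,
    build_group_summaries,
    confidence_interval,
    default_groups,
    jackknife_se,
    summaries_to_frame,
    weighted_mean,
    weighted_quartiles,
)


class TestWeightedMean:
    @pytest.mark.parametrize("values,weights,expected", [
        ((100.0, 200.0), (1.0, 1.0), 150.0),
        ((100.0, 200.0), (3.0, 1.0), 125.0),
        ((151.5,), (7.0,), 151.5),
    ])
    def test_examples(self, values, weights, expected):
        assert weighted_mean(values, weights) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([], [])


def _delete_one_columns(n):
    """Replicate-weight matrix deleting one unit per column."""
    rw = np.full((n, n), n / (n - 1))
    np.fill_diagonal(rw, 0.0)
    return rw


class TestJackknifeSE:
    def test_constant_statistic_gives_zero(self):
        rw = _delete_one_columns(5)
        se = jackknife_se(lambda v, w: 7.0, np.ones(5), np.ones(5), rw)
        assert se == 0.0

    def test_two_replicates_unit_deviation(self):
        # theta_(1) = full + 1, theta_(2) = full - 1 -> SE = 1
        calls = iter([1.0, 2.0, 0.0])  # full, rep1, rep2

        def stat(v, w):
            return next(calls)

        se = jackknife_se(stat, np.zeros(2), np.ones(2), np.ones((2, 2)))
        assert se == pytest.approx(1.0)

    def test_matches_brute_force_delete_one_mean(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(50, 400, size=9)
        rw = _delete_one_columns(9)
        se = jackknife_se(weighted_mean, v, np.ones(9), rw)
        # independent oracle: enumerate every leave-one-out subset
        loo = np.array([np.mean(np.delete(v, i)) for i in range(9)])
        oracle = np.sqrt((9 - 1) / 9 * np.sum((loo - loo.mean()) ** 2))
        assert se == pytest.approx(oracle, rel=1e-10)

    def test_all_zero_column_warns_and_contributes_no_deviation(self):
        v = np.array([1.0, 2.0, 3.0])
        rw = np.ones((3, 3))
        rw[:, 0] = 0.0  # whole group deleted: undefined replicate mean
        with pytest.warns(UserWarning, match="all zero"):
            se = jackknife_se(weighted_mean, v, np.ones(3), rw)
        clean = jackknife_se(weighted_mean, v, np.ones(3), np.ones((3, 3)))
        assert se == clean == 0.0


class TestConfidenceInterval:
    @pytest.mark.parametrize("mean,se,lo,hi", [
        (185.36, 3.43, 178.50, 192.22),
        (275.37, 6.24, 262.89, 287.85),
    ])
    def test_mean_plus_minus_two_se(self, mean, se, lo, hi):
        got_lo, got_hi = confidence_interval(mean, se)
        assert round(got_lo, 2) == lo
        assert round(got_hi, 2) == hi

    def test_zero_se_degenerate(self):
        assert confidence_interval(100.0, 0.0) == (100.0, 100.0)

    def test_normal_theory_multiplier_available(self):
        lo, hi = confidence_interval(100.0, 10.0, multiplier=1.96)
        assert (lo, hi) == (80.4, 119.6)


class TestWeightedQuartiles:
    def test_equal_weights_one_to_eight(self):
        got = weighted_quartiles(np.arange(1, 9, dtype=float), np.ones(8))
        assert got == (1.0, 2.0, 4.0, 6.0, 8.0)

    def test_point_mass_degenerate(self):
        assert weighted_quartiles([5.0, 5.0], [1.0, 3.0]) == (5.0,) * 5

    def test_doubling_weights_leaves_bounds_unchanged(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 500, size=40)
        w = rng.integers(1, 9, size=40).astype(float)
        assert weighted_quartiles(v, w) == weighted_quartiles(v, 2.0 * w)

    @given(st.lists(st.floats(0, 1000), min_size=1, max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_bounds_nondecreasing_and_cover_range(self, values):
        got = weighted_quartiles(values, np.ones(len(values)))
        assert list(got) == sorted(got)
        assert got[0] == min(values) and got[4] == max(values)

    def test_quartile_containment(self):
        # weighted mass in each quartile interval within one max weight of 25%
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 500, size=200)
        w = rng.uniform(0.5, 2.0, size=200)
        b = weighted_quartiles(v, w)
        total = w.sum()
        edges = [(b[0], b[1]), (b[1], b[2]), (b[2], b[3]), (b[3], b[4])]
        prev = -np.inf
        for lo, hi in edges:
            mass = w[(v > prev) & (v <= hi)].sum()
            prev = hi
            assert abs(mass - total / 4) <= w.max() + 1e-9


def make_group(n, n_at, ai, age, sex, stage="none", start=0):
    """n respondents of one AI band, n_at of them at/above the AI."""
    respondents, intakes = [], []
    for i in range(n):
        rid = f"g{start + i:06d}"
        respondents.append(Respondent(rid, age, sex, life_stage=stage,
                                      weight=2.0))
        intakes.append((rid, ai + 10.0 if i < n_at else ai - 10.0))
    usual = pd.DataFrame(intakes, columns=["resp_id", "usual_mg"])
    return respondents, usual


class TestAIAttainment:
    def test_counts_and_percent(self):
        respondents, usual = make_group(464, 311, 200.0, age=2, sex="male")
        got = ai_attainment(usual, respondents, default_ai_references())
        assert got["n_at_or_above_ai"] == 311
        assert got["pct_at_or_above_ai"] == 67.03
        assert got["pop_equivalent_at_or_above_ai"] == pytest.approx(622.0)

    def test_boundaries(self):
        respondents, usual = make_group(10, 0, 550.0, age=30, sex="male")
        assert ai_attainment(usual, respondents,
                             default_ai_references())["pct_at_or_above_ai"] == 0.0
        respondents, usual = make_group(10, 10, 550.0, age=30, sex="male")
        got = ai_attainment(usual, respondents, default_ai_references())
        assert got["pct_at_or_above_ai"] == 100.0

    def test_member_without_band_excluded(self):
        respondents, usual = make_group(4, 4, 550.0, age=30, sex="male")
        baby = Respondent("baby", 1, "male")
        usual = pd.concat([usual, pd.DataFrame(
            [("baby", 500.0)], columns=["resp_id", "usual_mg"])])
        got = ai_attainment(usual, respondents + [baby],
                            default_ai_references())
        assert got["n"] == 4 and got["n_excluded"] == 1


class TestBuildGroupSummaries:
    def test_partition_of_exclusive_groups(self, survey, density):
        usual = pd.DataFrame({
            "resp_id": [r.resp_id for r in survey.respondents],
            "usual_mg": [survey.truth.extras["true_usual"][r.resp_id]
                         for r in survey.respondents],
        })
        rows = build_group_summaries(usual, survey.respondents,
                                     default_ai_references())
        by_label = {r.group_label: r for r in rows}
        exclusive = [g.label for g in default_groups() if g.exclusive]
        n_sum = sum(by_label[lbl].n for lbl in exclusive if lbl in by_label)
        assert n_sum == by_label["Total"].n == len(survey.respondents)
        pop_sum = sum(by_label[lbl].pop_equivalent
                      for lbl in exclusive if lbl in by_label)
        assert pop_sum == pytest.approx(by_label["Total"].pop_equivalent)

    def test_two_person_group_unweighted_se(self):
        # sd/sqrt(n) fallback without replicate weights: mean 151.50, SE 26.94
        respondents = [
            Respondent("p1", 16, "female", life_stage="pregnant", weight=1.0),
            Respondent("p2", 17, "female", life_stage="pregnant", weight=1.0),
        ]
        usual = pd.DataFrame({"resp_id": ["p1", "p2"],
                              "usual_mg": [124.56, 178.44]})
        rows = build_group_summaries(
            usual, respondents, default_ai_references(),
            groups=[GroupDef("Pregnant 14-18 years", "female", 14, 18,
                             "pregnant")])
        (row,) = rows
        assert round(row.mean, 2) == 151.50
        assert round(row.se, 2) == 26.94

    def test_pregnancy_precedence_over_female_band(self):
        respondents = [
            Respondent("plain", 30, "female"),
            Respondent("preg", 30, "female", life_stage="pregnant"),
        ]
        usual = pd.DataFrame({"resp_id": ["plain", "preg"],
                              "usual_mg": [200.0, 210.0]})
        rows = build_group_summaries(usual, respondents,
                                     default_ai_references())
        by_label = {r.group_label: r for r in rows}
        assert by_label["Female 19-64 years"].n == 1
        assert by_label["Pregnant 19-50 years"].n == 1

    def test_empty_group_omitted(self, caplog):
        respondents = [Respondent("p1", 30, "male")]
        usual = pd.DataFrame({"resp_id": ["p1"], "usual_mg": [250.0]})
        rows = build_group_summaries(usual, respondents,
                                     default_ai_references())
        labels = {r.group_label for r in rows}
        assert "Pregnant 19-50 years" not in labels

    def test_weight_scale_invariance(self, survey):
        usual = pd.DataFrame({
            "resp_id": [r.resp_id for r in survey.respondents],
            "usual_mg": [survey.truth.extras["true_usual"][r.resp_id]
                         for r in survey.respondents],
        })
        import dataclasses
        scaled = [dataclasses.replace(
            r, weight=3.0 * r.weight,
            replicate_weights=tuple(3.0 * w for w in r.replicate_weights))
            for r in survey.respondents]
        a = build_group_summaries(usual, survey.respondents)
        b = build_group_summaries(usual, scaled)
        for ra, rb in zip(a, b):
            assert rb.pop_equivalent == pytest.approx(3.0 * ra.pop_equivalent)
            assert rb.mean == pytest.approx(ra.mean)
            assert rb.se == pytest.approx(ra.se)
            assert rb.quartile_bounds == pytest.approx(ra.quartile_bounds)

    def test_report_frame_rounding(self):
        respondents, usual = make_group(3, 2, 200.0, age=2, sex="male")
        frame = summaries_to_frame(build_group_summaries(
            usual, respondents, default_ai_references(),
            groups=[GroupDef("Children 2-3 years", None, 2, 3)]))
        assert frame.loc[0, "pct_at_or_above_ai"] == 66.67
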
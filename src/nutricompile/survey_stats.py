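"""Design-based descriptive statistics for weighted survey data.

Weighted means, delete-a-group jackknife standard errors from replicate
weights, 95% confidence intervals, weighted quartile bounds, population
equivalents (sums of weights) and Adequate-Intake attainment, summarised by
age/sex/life-stage group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .food_db import AIReference, lookup_ai
from .intake_pipeline import Respondent

logger = logging.getLogger(__name__)

#: Multiplier for the 95% confidence interval; 2 by convention here, the
#: normal-theory 1.96 is available via the ``multiplier`` argument.
CI_MULTIPLIER = 2.0


@dataclass
class GroupSummary:
    """One row of a population intake summary table."""

    group_label: str
    n: int  # unweighted respondent count
    pop_equivalent: float  # sum of weights
    mean: float  # mg/day
    se: float  # mg/day
    ci_low: float
    ci_high: float
    quartile_bounds: tuple  # (min, Q1, median, Q3, max)
    ai: Optional[float] = None  # mg/day, None when the group spans bands
    pct_at_or_above_ai: Optional[float] = None  # unweighted %
    n_at_or_above_ai: Optional[int] = None
    pop_equivalent_at_or_above_ai: Optional[float] = None


def weighted_mean(values, weights) -> float:
    """Design-weighted mean: sum(w v) / sum(w)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    if v.shape != w.shape:
        raise ValueError("values and weights differ in length")
    # Zero weights are tolerated so replicate-weight columns (which delete a
    # group by zeroing it) can reuse this statistic.
    if np.any(w < 0) or np.sum(w) <= 0:
        raise ValueError("weights must be >= 0 with a positive total")
    return float(np.sum(w * v) / np.sum(w))


def jackknife_se(statistic: Callable, values, weights, replicate_weights
                 ) -> float:
    """Delete-a-group jackknife standard error.

    Recomputes ``statistic(values, column_g)`` under each of the R replicate
    weight columns and combines deviations from the full-sample estimate:

        SE = sqrt( (R - 1) / R * sum_g (theta_g - theta_full)^2 )

    A replicate column that is all zero over these records (the deletion
    group covered the whole subset, as can happen for small domains) leaves
    the statistic undefined; it is still used, with the full-sample estimate
    standing in for that replicate (zero deviation) and a warning issued.
    """
    rw = np.asarray(replicate_weights, dtype=float)
    if rw.ndim != 2 or rw.shape[1] < 2:
        raise ValueError("need an n x R matrix of replicate weights, R >= 2")
    R = rw.shape[1]
    theta_full = statistic(values, weights)
    theta_rep = np.empty(R)
    for g in range(R):
        if not rw[:, g].any():
            warnings.warn(
                f"replicate weight column {g} is all zero over this group; "
                "substituting the full-sample estimate", stacklevel=2,
            )
            theta_rep[g] = theta_full
        else:
            theta_rep[g] = statistic(values, rw[:, g])
    return float(np.sqrt((R - 1) / R * np.sum((theta_rep - theta_full) ** 2)))


def confidence_interval(mean: float, se: float,
                        multiplier: float = CI_MULTIPLIER) -> tuple:
    """(mean - multiplier*se, mean + multiplier*se)."""
    return (mean - multiplier * se, mean + multiplier * se)


def weighted_quartiles(values, weights) -> tuple:
    """Five ascending bounds (min, Q1, median, Q3, max) of a weighted
    distribution.

    Each bound is the lowest value whose cumulative normalised weight
    reaches the target fraction (0, .25, .5, .75, 1), giving contiguous
    quartile intervals. Scaling all weights by a constant leaves the bounds
    unchanged. Ties are resolved by value order (stable sort).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / np.sum(w)
    bounds = []
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        idx = int(np.searchsorted(cum, frac, side="left"))
        idx = min(idx, v.size - 1)
        bounds.append(float(v[idx]))
    return tuple(bounds)


def ai_attainment(
    usual: pd.DataFrame,
    respondents: Sequence[Respondent],
    ai_table: Sequence[AIReference],
    member_ids: Optional[Sequence[str]] = None,
) -> dict:
    """Share of a group whose usual intake reaches the Adequate Intake.

    The percentage is an unweighted count ratio (rounded to 2 decimals);
    the population equivalent of attainers is the weighted companion
    figure. Members without an applicable AI band are excluded and logged.
    """
    by_id = {r.resp_id: r for r in respondents}
    ids = list(member_ids) if member_ids is not None else list(by_id)
    intake = dict(zip(usual["resp_id"], usual["usual_mg"]))
    n = n_at = 0
    pop_at = 0.0
    excluded = []
    for rid in ids:
        r = by_id.get(rid)
        if r is None or rid not in intake:
            continue
        ai = lookup_ai(r, ai_table)
        if ai is None:
            excluded.append(rid)
            continue
        n += 1
        if intake[rid] >= ai:
            n_at += 1
            pop_at += r.weight
    if excluded:
        logger.info("%d respondents excluded from AI attainment (no AI band)",
                    len(excluded))
    pct = round(100.0 * n_at / n, 2) if n else 0.0
    return {
        "n": n,
        "n_at_or_above_ai": n_at,
        "pct_at_or_above_ai": pct,
        "pop_equivalent_at_or_above_ai": pop_at,
        "n_excluded": len(excluded),
    }


# ---------------------------------------------------------------------------
# Grouping


@dataclass(frozen=True)
class GroupDef:
    """One reporting group: sex/age band or life-stage band.

    ``exclusive`` groups partition the sample (pregnancy and lactation take
    precedence over plain female age bands); non-exclusive overlay groups
    (total, childbearing-age) are reported in addition.
    """

    label: str
    sex: Optional[str] = None  # None = any
    age_min: int = 0
    age_max: int = 200
    life_stage: str = "none"
    exclusive: bool = True
    exclude_life_stages: tuple = ()

    def contains(self, r: Respondent) -> bool:
        if not (self.age_min <= r.age <= self.age_max):
            return False
        if self.sex is not None and r.sex != self.sex:
            return False
        stage = r.life_stage or "none"
        if self.life_stage != "any" and stage != self.life_stage:
            return False
        if stage in self.exclude_life_stages:
            return False
        return True


def default_groups() -> list[GroupDef]:
    """The national-survey reporting bands: children 2-3 and 4-8 (both
    sexes), sex-specific 9-13, 14-18, 19-64 and 65-85 bands, pregnancy and
    lactation bands, plus overlay rows for the total population and females
    of childbearing age (16-44, excluding pregnant and breastfeeding)."""
    g: list[GroupDef] = [
        GroupDef("Total", sex=None, age_min=0, age_max=200,
                 life_stage="any", exclusive=False),
        GroupDef("Children 2-3 years", None, 2, 3),
        GroupDef("Children 4-8 years", None, 4, 8),
    ]
    for sex in ("male", "female"):
        cap = sex.capitalize()
        g += [
            GroupDef(f"{cap} 9-13 years", sex, 9, 13),
            GroupDef(f"{cap} 14-18 years", sex, 14, 18),
            GroupDef(f"{cap} 19-64 years", sex, 19, 64),
            GroupDef(f"{cap} 65-85 years", sex, 65, 85),
        ]
    g += [
        GroupDef("Pregnant 14-18 years", "female", 14, 18, "pregnant"),
        GroupDef("Pregnant 19-50 years", "female", 19, 50, "pregnant"),
        GroupDef("Lactating 14-18 years", "female", 14, 18, "lactating"),
        GroupDef("Lactating 19-50 years", "female", 19, 50, "lactating"),
        GroupDef("Childbearing age (16-44 years)", "female", 16, 44,
                 life_stage="none", exclusive=False,
                 exclude_life_stages=("pregnant", "lactating")),
    ]
    return g


def assign_exclusive_group(r: Respondent, groups: Sequence[GroupDef]
                           ) -> Optional[str]:
    """The unique exclusive group a respondent belongs to, if any.

    Life-stage bands are listed after plain bands but take precedence;
    since plain bands require life_stage == none, a pregnant or lactating
    respondent can only match a life-stage band, so exclusivity holds by
    construction. Multiple matches raise.
    """
    matches = [g.label for g in groups if g.exclusive and g.contains(r)]
    if len(matches) > 1:
        raise ValueError(
            f"{r.resp_id} matches multiple exclusive groups: {matches}"
        )
    return matches[0] if matches else None


def _replicate_matrix(members: Sequence[Respondent]) -> Optional[np.ndarray]:
    if not members or not members[0].replicate_weights:
        return None
    R = len(members[0].replicate_weights)
    if any(len(m.replicate_weights) != R for m in members):
        raise ValueError("replicate weight count differs across respondents")
    return np.array([m.replicate_weights for m in members], dtype=float)


def summarise_group(
    label: str,
    members: Sequence[Respondent],
    usual: pd.DataFrame,
    ai_table: Optional[Sequence[AIReference]] = None,
    multiplier: float = CI_MULTIPLIER,
) -> Optional[GroupSummary]:
    """Summary row for one group; None (with a log notice) when empty."""
    intake = dict(zip(usual["resp_id"], usual["usual_mg"]))
    members = [m for m in members if m.resp_id in intake]
    if not members:
        logger.info("group %r is empty; row omitted", label)
        return None
    values = np.array([intake[m.resp_id] for m in members])
    weights = np.array([m.weight for m in members])
    mean = weighted_mean(values, weights)
    rw = _replicate_matrix(members)
    if rw is not None and rw.shape[1] >= 2:
        se = jackknife_se(weighted_mean, values, weights, rw)
    else:
        # No replicate weights: fall back to the unweighted sd/sqrt(n).
        se = float(np.std(values, ddof=1) / np.sqrt(len(values))) \
            if len(values) > 1 else 0.0
    lo, hi = confidence_interval(mean, se, multiplier)
    summary = GroupSummary(
        group_label=label,
        n=len(members),
        pop_equivalent=float(weights.sum()),
        mean=mean, se=se, ci_low=lo, ci_high=hi,
        quartile_bounds=weighted_quartiles(values, weights),
    )
    if ai_table:
        ais = {lookup_ai(m, ai_table) for m in members}
        att = ai_attainment(usual, members, ai_table,
                            [m.resp_id for m in members])
        summary.ai = ais.pop() if len(ais) == 1 else None
        summary.pct_at_or_above_ai = att["pct_at_or_above_ai"]
        summary.n_at_or_above_ai = att["n_at_or_above_ai"]
        summary.pop_equivalent_at_or_above_ai = att[
            "pop_equivalent_at_or_above_ai"]
    return summary


def build_group_summaries(
    usual: pd.DataFrame,
    respondents: Sequence[Respondent],
    ai_table: Optional[Sequence[AIReference]] = None,
    groups: Optional[Sequence[GroupDef]] = None,
    multiplier: float = CI_MULTIPLIER,
) -> list[GroupSummary]:
    """One summary row per configured group, in configuration order.

    Exclusive groups partition the respondents (each person counted once,
    with pregnancy/lactation taking precedence over female age bands);
    overlay rows such as the total population are additional. Empty groups
    are omitted with a log notice.
    """
    groups = list(groups) if groups is not None else default_groups()
    # Validate exclusivity up front so precedence errors surface early.
    for r in respondents:
        assign_exclusive_group(r, groups)
    out = []
    for g in groups:
        members = [r for r in respondents if g.contains(r)]
        row = summarise_group(g.label, members, usual, ai_table, multiplier)
        if row is not None:
            out.append(row)
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary],
                       decimals: int = 2) -> pd.DataFrame:
    """Report table: means/SE/CI and percentages rounded, weights unrounded."""
    rows = []
    for s in summaries:
        q = s.quartile_bounds
        rows.append({
            "group": s.group_label,
            "n": s.n,
            "pop_equivalent": s.pop_equivalent,
            "mean_mg": round(s.mean, decimals),
            "se_mg": round(s.se, decimals),
            "ci_low_mg": round(s.ci_low, decimals),
            "ci_high_mg": round(s.ci_high, decimals),
            "q_min": round(q[0], decimals),
            "q1_mg": round(q[1], decimals),
            "median_mg": round(q[2], decimals),
            "q3_mg": round(q[3], decimals),
            "q_max": round(q[4], decimals),
            "ai_mg_day": s.ai,
            "pct_at_or_above_ai": s.pct_at_or_above_ai,
            "n_at_or_above_ai": s.n_at_or_above_ai,
            "pop_equivalent_at_or_above_ai": s.pop_equivalent_at_or_above_ai,
        })
    return pd.DataFrame(rows)
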
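"""Food-source analysis: which food groups supply the nutrient.

Contributions are computed from day-1 recall events (reported consumption,
not usual intakes): each event's nutrient mass is attributed to the food
group given by its code prefix, weighted by the respondent's population
weight. Per-consumer means are weighted means over the respondents who
reported any food of the group. Rankings are by percent of total population
intake, ties broken by group code ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import CompilationError
from .intake_pipeline import Respondent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContributionRecord:
    """One food group's contribution to total population nutrient intake."""

    group_code: str  # 2-, 3- or 5-digit prefix depending on level
    label: str
    n_consumers: int  # unweighted respondents consuming the group
    per_consumer_mean: float  # mg/day among consumers
    pct_of_total: float  # % of total population nutrient intake
    rank: int  # 1-based


def group_contributions(
    events: pd.DataFrame,
    db: Mapping[str, float],
    respondents: Sequence[Respondent],
    member_ids: Optional[Sequence[str]] = None,
    level: int = 3,
    day: Optional[int] = 1,
    labels: Optional[Mapping[str, str]] = None,
) -> list[ContributionRecord]:
    """Per-food-group nutrient contributions for a respondent subset.

    ``member_ids`` filters the population (all respondents by default);
    ``level`` selects the 2-, 3- or 5-digit grouping; ``day`` restricts the
    events (day 1 by default, None for all days). Percentages over all
    groups sum to 100 whenever total intake is positive, because every
    event belongs to exactly one group.
    """
    if level not in (2, 3, 5):
        raise ValueError("grouping level must be 2, 3 or 5")
    by_id = {r.resp_id: r for r in respondents}
    ids = set(member_ids) if member_ids is not None else set(by_id)
    df = events[events["resp_id"].isin(ids)]
    if day is not None:
        df = df[df["day"] == day]
    if df.empty:
        logger.info("no intake events after filtering; empty contribution set")
        return []
    unresolved = sorted(set(df["food_id"]) - set(db))
    if unresolved:
        raise CompilationError(
            f"unresolvable food ids: {unresolved}", ids=unresolved
        )
    df = df.assign(
        mg=df["grams"] * df["food_id"].map(db) / 100.0,
        group=df["food_id"].str[:level],
        w=df["resp_id"].map({i: by_id[i].weight for i in ids}),
    )
    total_mg = float((df["mg"] * df["w"]).sum())

    records = []
    for code, sub in df.groupby("group"):
        weighted_mg = float((sub["mg"] * sub["w"]).sum())
        per_person = sub.groupby("resp_id").agg(
            mg=("mg", "sum"), w=("w", "first")
        )
        consumers = per_person[per_person["mg"] > 0]
        per_consumer_mean = (
            float((consumers["mg"] * consumers["w"]).sum() /
                  consumers["w"].sum())
            if len(consumers) else 0.0
        )
        records.append({
            "group_code": str(code),
            "label": (labels or {}).get(str(code), f"group {code}"),
            "n_consumers": int(len(consumers)),
            "per_consumer_mean": per_consumer_mean,
            "pct_of_total": (100.0 * weighted_mg / total_mg
                             if total_mg > 0 else 0.0),
        })
    records.sort(key=lambda r: (-r["pct_of_total"], r["group_code"]))
    return [
        ContributionRecord(rank=i + 1, **r) for i, r in enumerate(records)
    ]


def top_n(records: Sequence[ContributionRecord], n: int = 20
          ) -> tuple[list[ContributionRecord], float]:
    """First n records by rank and their cumulative percent of total intake."""
    head = list(records[:n])
    return head, float(sum(r.pct_of_total for r in head))


def contributions_to_frame(records: Sequence[ContributionRecord]
                           ) -> pd.DataFrame:
    return pd.DataFrame([{
        "rank": r.rank,
        "group_code": r.group_code,
        "label": r.label,
        "n_consumers": r.n_consumers,
        "per_consumer_mean_mg": r.per_consumer_mean,
        "pct_of_total": r.pct_of_total,
    } for r in records])
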
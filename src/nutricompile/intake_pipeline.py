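"""From intake events to usual (habitual) daily intakes.

A two-day 24-hour-recall survey observes each person's intake on one or two
days. Observed person means are noisy estimates of habitual intake because
day-to-day (within-person) variation is large. The estimator here follows
the classic measurement-error decomposition: regress person-day intakes on
covariates, split the residual variance into between-person and
within-person components by method of moments, and shrink each person's
observed mean toward their covariate prediction by

    lambda_d = sigma2_between / (sigma2_between + sigma2_within / d)

where d is that person's number of recall days. The resulting usual-intake
distribution retains the population mean structure while removing the
excess spread that single-day data carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CompilationError, EstimationError

DEFAULT_COVARIATES = ("age", "sex")


@dataclass(frozen=True)
class Respondent:
    """One survey person: demographics, design weights, replicate weights."""

    resp_id: str
    age: int
    sex: str  # male / female
    life_stage: str = "none"  # none / pregnant / lactating
    weight: float = 1.0  # sampling/population weight
    replicate_weights: tuple = ()
    education_level: int = 3  # 1 (highest) .. 5
    activity_level: int = 3  # 1 (high) .. 5 (sedentary)
    energy: float = 0.0  # kJ/day

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError(f"{self.resp_id}: weight must be > 0")
        if any(w < 0 for w in self.replicate_weights):
            raise ValueError(f"{self.resp_id}: negative replicate weight")
        for lvl in (self.education_level, self.activity_level):
            if not 1 <= lvl <= 5:
                raise ValueError(f"{self.resp_id}: level {lvl} outside 1-5")


@dataclass(frozen=True)
class IntakeEvent:
    """One reported food on one recall day."""

    resp_id: str
    day: int  # 1 or 2
    food_id: str
    grams: float

    def __post_init__(self):
        if self.day not in (1, 2):
            raise ValueError(f"day must be 1 or 2, got {self.day}")
        if self.grams <= 0:
            raise ValueError(f"grams must be > 0, got {self.grams}")


@dataclass(frozen=True)
class VarianceComponents:
    """Between/within person variance split and the implied shrinkage."""

    sigma2_between: float  # (mg/day)^2
    sigma2_within: float  # (mg/day)^2

    def __post_init__(self):
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be >= 0")

    def shrinkage(self, n_days: int) -> float:
        """lambda_d in [0, 1]; 1 when there is no within-person noise."""
        denom = self.sigma2_between + self.sigma2_within / n_days
        if denom == 0:
            return 1.0
        return self.sigma2_between / denom


def events_to_frame(events: Sequence[IntakeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.resp_id, e.day, e.food_id, e.grams) for e in events],
        columns=["resp_id", "day", "food_id", "grams"],
    )


def daily_intake(
    events,
    db: Mapping[str, float],
    person_days: Optional[Sequence[tuple]] = None,
) -> pd.DataFrame:
    """Per (resp_id, day) nutrient intake in mg/day.

    ``db`` maps food_id to nutrient density (mg/100 g); an intake event of
    g grams contributes g * density / 100 mg. ``person_days`` lists the
    (resp_id, day) pairs present in the survey design; pairs with no events
    score 0 mg. When omitted, the person-days observed in the events are
    used. Unresolvable food ids raise, listing every offending id.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if len(df):
        unresolved = sorted(set(df["food_id"]) - set(db))
        if unresolved:
            raise CompilationError(
                f"unresolvable food ids in intake events: {unresolved}",
                ids=unresolved,
            )
        df = df.assign(mg=df["grams"] * df["food_id"].map(db) / 100.0)
        totals = df.groupby(["resp_id", "day"], as_index=False)["mg"].sum()
    else:
        totals = pd.DataFrame(columns=["resp_id", "day", "mg"])
    if person_days is not None:
        design = pd.DataFrame(person_days, columns=["resp_id", "day"])
        totals = design.merge(totals, on=["resp_id", "day"], how="left")
        totals["mg"] = totals["mg"].fillna(0.0)
    return totals.rename(columns={"mg": "intake_mg"})


def _design_matrix(respondents: Sequence[Respondent],
                   covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + requested covariates, numeric-coded (sex: male=0, female=1)."""
    cols, names = [np.ones(len(respondents))], ["const"]
    for cov in covariates:
        if cov == "sex":
            cols.append(np.array(
                [1.0 if r.sex == "female" else 0.0 for r in respondents]
            ))
        else:
            cols.append(np.array(
                [float(getattr(r, cov)) for r in respondents]
            ))
        names.append(cov)
    return np.column_stack(cols), names


def fit_variance_components(
    intakes: pd.DataFrame,
    respondents: Sequence[Respondent],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[VarianceComponents, np.ndarray, list[str]]:
    """Fit intake_ij = b.z_i + u_i + e_ij and split the residual variance.

    Step 1: ordinary least squares of person-day intakes on the person-level
    covariates. Step 2: one-way method-of-moments decomposition of the
    residuals with unbalanced day counts d_i:

        sigma2_within  = SSW / (N - n)
        sigma2_between = (MSB - sigma2_within) / c,
        c = (N - sum d_i^2 / N) / (n - 1)

    Negative moment estimates are truncated at 0. Requires at least two
    persons with both recall days; otherwise the within-person variance is
    unidentifiable and an error is raised.

    Returns (components, coefficient vector, coefficient names).
    """
    by_id = {r.resp_id: r for r in respondents}
    df = intakes[intakes["resp_id"].isin(by_id)].copy()
    if df.empty:
        raise EstimationError("no intakes for the given respondents")
    day_counts = df.groupby("resp_id")["day"].nunique()
    n_multi = int((day_counts >= 2).sum())
    if n_multi < 2:
        raise EstimationError(
            "within-person variance unidentifiable: fewer than 2 persons "
            "with both recall days"
        )

    persons = [by_id[i] for i in df["resp_id"]]
    X, names = _design_matrix(persons, covariates)
    y = df["intake_mg"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta

    rdf = pd.DataFrame({"resp_id": df["resp_id"].to_numpy(), "r": resid})
    g = rdf.groupby("resp_id")["r"]
    d = g.size().to_numpy(dtype=float)
    means = g.mean().to_numpy()
    N, n = d.sum(), len(d)
    grand = resid.sum() / N

    ssw = float(((rdf["r"] - rdf.groupby("resp_id")["r"].transform("mean")) ** 2).sum())
    sigma2_within = ssw / (N - n)
    msb = float((d * (means - grand) ** 2).sum()) / (n - 1)
    c = (N - (d ** 2).sum() / N) / (n - 1)
    sigma2_between = max((msb - sigma2_within) / c, 0.0)
    comps = VarianceComponents(
        sigma2_between=sigma2_between, sigma2_within=max(sigma2_within, 0.0)
    )
    return comps, beta, names


def usual_intake(
    intakes: pd.DataFrame,
    components: VarianceComponents,
    beta: np.ndarray,
    respondents: Sequence[Respondent],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-person usual intake: prediction + lambda_d * (mean - prediction).

    Persons observed on a single day get lambda_1; no second day is imputed.
    Every usual intake lies between the covariate prediction and the
    observed person mean, so the usual-intake distribution is never wider
    than the person-mean distribution.
    """
    by_id = {r.resp_id: r for r in respondents}
    per_person = intakes.groupby("resp_id").agg(
        mean_mg=("intake_mg", "mean"), n_days=("day", "nunique")
    ).reset_index()
    per_person = per_person[per_person["resp_id"].isin(by_id)]
    persons = [by_id[i] for i in per_person["resp_id"]]
    X, _ = _design_matrix(persons, covariates)
    pred = X @ beta
    lam = np.array([components.shrinkage(int(d)) for d in per_person["n_days"]])
    usual = pred + lam * (per_person["mean_mg"].to_numpy() - pred)
    return pd.DataFrame({
        "resp_id": per_person["resp_id"].to_numpy(),
        "usual_mg": usual,
        "mean_mg": per_person["mean_mg"].to_numpy(),
        "pred_mg": pred,
        "n_days": per_person["n_days"].to_numpy(),
        "lambda": lam,
    })


def estimate_usual_intakes(
    events,
    db: Mapping[str, float],
    respondents: Sequence[Respondent],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    person_days: Optional[Sequence[tuple]] = None,
    shrink: bool = True,
) -> tuple[pd.DataFrame, Optional[VarianceComponents]]:
    """Events -> per-person usual intake table, end to end.

    With ``shrink=False`` (day-1-only mode used by the food-source
    analyses) the day-1 observed intake is returned unshrunken.
    """
    intakes = daily_intake(events, db, person_days=person_days)
    if not shrink:
        day1 = intakes[intakes["day"] == 1]
        out = day1.rename(columns={"intake_mg": "usual_mg"})[
            ["resp_id", "usual_mg"]
        ].copy()
        out["n_days"] = 1
        return out.reset_index(drop=True), None
    comps, beta, names = fit_variance_components(
        intakes, respondents, covariates
    )
    return usual_intake(intakes, comps, beta, respondents, covariates), comps
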
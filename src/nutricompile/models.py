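"""Per-food-group regression of total nutrient intake on food-group
consumption.

One weighted least-squares model per food group: total daily intake
(mg/day) regressed on the group's consumption in 100 g units plus
person-level covariates (energy intake, physical-activity level, sex, age,
education level). Standard errors come from the delete-a-group jackknife
(the model is refitted under every replicate-weight column); p-values use a
t reference distribution with replicate-based degrees of freedom. Models
are ranked by the percent of intake variance they explain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError

DEFAULT_COVARIATES = ("energy", "activity_level", "sex", "age",
                      "education_level")
SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class CoefficientRow:
    """One fitted term: estimate, jackknife SE, t, p, significance flag."""

    name: str
    coefficient: float
    jackknife_se: float
    t: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL


@dataclass(frozen=True)
class ModelResult:
    """A fitted per-food-group model.

    ``rows[0]`` is the food-group term (mg choline per 100 g of the group);
    the remaining rows are covariates. ``r2_pct`` is 100 x the weighted R²
    of the full model.
    """

    group_code: str
    label: str
    rows: tuple
    r2_pct: float
    n: int
    df_resid: int

    @property
    def group_row(self) -> CoefficientRow:
        return self.rows[0]


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def _check_aliasing(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the first column linearly dependent on its predecessors."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    for k in range(1, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :k]) < k:
            raise EstimationError(
                f"collinear design: column {names[k - 1]!r} is aliased"
            )


def fit_group_model(
    data: pd.DataFrame,
    group_code: str,
    weights: np.ndarray,
    replicate_weights: np.ndarray,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    label: Optional[str] = None,
    grams_column: str = "group_g",
    intake_column: str = "total_mg",
) -> ModelResult:
    """Fit one food-group model with jackknife standard errors.

    ``data`` holds one row per respondent with the total intake, the
    group's grams/day and the covariate columns (sex coded female=1).
    Group grams are rescaled to 100 g units before fitting, so the group
    coefficient reads as mg of intake per 100 g increment of consumption.
    """
    n = len(data)
    names = ["const", "group_per_100g", *covariates]
    if n < len(names) + 2:
        raise EstimationError(
            f"group {group_code}: {n} observations for {len(names)} parameters"
        )
    cols = [np.ones(n), data[grams_column].to_numpy(dtype=float) / 100.0]
    for cov in covariates:
        if cov == "sex":
            cols.append(
                (data["sex"].to_numpy() == "female").astype(float)
                if data["sex"].dtype == object
                else data["sex"].to_numpy(dtype=float)
            )
        else:
            cols.append(data[cov].to_numpy(dtype=float))
    X = np.column_stack(cols)
    y = data[intake_column].to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    _check_aliasing(X, names)

    beta = _wls(X, y, w)

    rw = np.asarray(replicate_weights, dtype=float)
    if rw.ndim != 2 or rw.shape[0] != n or rw.shape[1] < 2:
        raise ValueError("replicate_weights must be n x R with R >= 2")
    R = rw.shape[1]
    reps = np.empty((R, len(beta)))
    for g in range(R):
        wg = rw[:, g]
        keep = wg > 0
        reps[g] = _wls(X[keep], y[keep], wg[keep])
    se = np.sqrt((R - 1) / R * np.sum((reps - beta) ** 2, axis=0))

    df_resid = max(R - len(beta), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df=df_resid)
    p = np.where(np.isfinite(t), p, 0.0)

    resid = y - X @ beta
    ybar = np.sum(w * y) / np.sum(w)
    sst = float(np.sum(w * (y - ybar) ** 2))
    ssr = float(np.sum(w * resid ** 2))
    r2_pct = 100.0 * (1.0 - ssr / sst) if sst > 0 else 0.0
    r2_pct = min(max(r2_pct, 0.0), 100.0)

    rows = tuple(
        CoefficientRow(name=nm, coefficient=float(b), jackknife_se=float(s),
                       t=float(tt), p=float(pp))
        for nm, b, s, tt, pp in zip(names[1:], beta[1:], se[1:], t[1:], p[1:])
    )
    return ModelResult(
        group_code=str(group_code),
        label=label or f"group {group_code}",
        rows=rows, r2_pct=r2_pct, n=n, df_resid=df_resid,
    )


def rank_models(results: Sequence[ModelResult],
                exclude: Sequence[str] = ()) -> list[ModelResult]:
    """Order models by descending variance explained.

    Ties break by group code ascending; groups listed in ``exclude`` (e.g.
    infant formula and infant foods, irrelevant to the surveyed age range)
    are dropped.
    """
    excluded = set(exclude)
    kept = [m for m in results if m.group_code not in excluded]
    return sorted(kept, key=lambda m: (-m.r2_pct, m.group_code))


def models_to_frame(results: Sequence[ModelResult]) -> pd.DataFrame:
    rows = []
    for m in results:
        for row in m.rows:
            rows.append({
                "group_code": m.group_code,
                "label": m.label,
                "term": row.name,
                "coefficient": row.coefficient,
                "jackknife_se": row.jackknife_se,
                "t": row.t,
                "p": row.p,
                "significant": row.significant,
                "r2_pct": m.r2_pct,
                "n": m.n,
            })
    return pd.DataFrame(rows)
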
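"""Two-step anomaly detection on next-day prediction errors.

Step 1 models the per-day prediction errors (MAE between predicted and
actual dedication vectors) with a normal distribution and flags days whose
z-score exceeds the quantile Z = Phi^-1(p_value).  Step 2 explains and
gates a flagged day: it is reported as an anomaly only if at least one
activity's dedication falls outside its population boxplot whiskers
(Q1 - 1.5 IQR, Q3 + 1.5 IQR).  Both comparisons are strict, so ties are
non-anomalous.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models.evaluation import per_day_errors
from .table import DedicationTable
from .windowing import WindowedDataset

DEFAULT_P_VALUE = 0.925


@dataclass
class ErrorVector:
    """Per-(user, day) next-day prediction errors (MAE, percent units)."""

    errors: np.ndarray
    index: list[tuple[str, dt.date]]

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        if len(self.errors) != len(self.index):
            raise ValueError("errors and index length mismatch")
        if (self.errors < 0).any():
            raise ValueError("errors must be non-negative")

    def __len__(self) -> int:
        return len(self.errors)


def compute_error_vector(predictor, data: WindowedDataset) -> ErrorVector:
    """One MAE entry per labelled day, with its (user, day) index retained."""
    if data.n_samples == 0:
        raise ValueError("empty dataset")
    pred = predictor.predict(data.inputs)
    mae_days, _ = per_day_errors(data.labels, pred)
    return ErrorVector(mae_days, list(zip(data.users, data.label_days)))


@dataclass(frozen=True)
class NormalErrorModel:
    """Gaussian fit of the error vector: mu, sigma (population form) and
    the flagging threshold Z at the configured tail probability."""

    mu: float
    sigma: float
    p_value: float
    Z: float

    def z_scores(self, errors: np.ndarray) -> np.ndarray:
        return (np.asarray(errors, dtype=float) - self.mu) / self.sigma


def fit_error_model(errors: ErrorVector | np.ndarray, p_value: float = DEFAULT_P_VALUE) -> NormalErrorModel:
    eps = errors.errors if isinstance(errors, ErrorVector) else np.asarray(errors, dtype=float)
    if len(eps) < 2:
        raise ValueError("need at least two errors to fit the model")
    if not 0.0 < p_value < 1.0:
        raise ValueError("p_value must be in (0, 1)")
    mu = float(eps.mean())
    sigma = float(eps.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("degenerate error distribution (all errors equal)")
    return NormalErrorModel(mu, sigma, p_value, float(stats.norm.ppf(p_value)))


def step1_flag(errors: ErrorVector, model: NormalErrorModel) -> set[tuple[str, dt.date]]:
    """Days whose error z-score strictly exceeds Z (one-sided: only large
    errors are anomalous)."""
    z = model.z_scores(errors.errors)
    return {errors.index[i] for i in np.nonzero(z > model.Z)[0]}


@dataclass
class ActivityLimits:
    """Per-activity boxplot whiskers over a reference population.

    Quartiles use linear interpolation between closest order statistics;
    upper = Q3 + 1.5 IQR, lower = Q1 - 1.5 IQR.
    """

    lower: pd.Series
    upper: pd.Series
    q1: pd.Series
    q3: pd.Series

    @property
    def activity_names(self) -> list[str]:
        return list(self.lower.index)


def compute_activity_limits(reference: DedicationTable) -> ActivityLimits:
    if len(reference) == 0:
        raise ValueError("empty reference table")
    vals = reference.data.to_numpy()
    q1 = np.percentile(vals, 25, axis=0, method="linear")
    q3 = np.percentile(vals, 75, axis=0, method="linear")
    iqr = q3 - q1
    cols = reference.activity_names
    return ActivityLimits(
        lower=pd.Series(q1 - 1.5 * iqr, index=cols),
        upper=pd.Series(q3 + 1.5 * iqr, index=cols),
        q1=pd.Series(q1, index=cols),
        q3=pd.Series(q3, index=cols),
    )


@dataclass(frozen=True)
class Deviation:
    activity: str
    dedication: float
    direction: str  # "over" | "under"
    limit: float


def explain_day(day: pd.Series, limits: ActivityLimits) -> list[Deviation]:
    """Activities of one day strictly outside their whiskers."""
    if list(day.index) != limits.activity_names:
        raise ValueError("activity vocabulary mismatch between day and limits")
    out: list[Deviation] = []
    for act in day.index:
        v = float(day[act])
        if v > limits.upper[act]:
            out.append(Deviation(act, v, "over", float(limits.upper[act])))
        elif v < limits.lower[act]:
            out.append(Deviation(act, v, "under", float(limits.lower[act])))
    return out


@dataclass
class AnomalyReport:
    user: str
    day: dt.date
    day_ordinal: int  # per-user ordinal of the labelled day (1-based)
    z_score: float
    deviated: list[Deviation] = field(default_factory=list)


def detect_anomalies(
    predictor,
    data: WindowedDataset,
    reference: DedicationTable,
    p_value: float = DEFAULT_P_VALUE,
    error_model: NormalErrorModel | None = None,
) -> tuple[list[AnomalyReport], dict]:
    """Full two-step detector.

    A day is reported iff its error z-score strictly exceeds Z (step 1) and
    at least one activity lies outside the reference whiskers (step 2).  By
    default the error model is fitted on ``data`` itself; pass a
    pre-fitted ``error_model`` (e.g. fitted on the training subset) to
    score held-out data without re-estimating mu/sigma.
    """
    if list(reference.activity_names) != list(data.activity_names):
        raise ValueError("reference table and dataset use different activity vocabularies")
    errors = compute_error_vector(predictor, data)
    model = error_model if error_model is not None else fit_error_model(errors, p_value)
    flagged = step1_flag(errors, model)
    limits = compute_activity_limits(reference)
    z = model.z_scores(errors.errors)

    ordinals: dict[str, dict[dt.date, int]] = {}
    for user in set(data.users):
        days = sorted(d for u, d in errors.index if u == user)
        ordinals[user] = {d: i + 1 for i, d in enumerate(days)}

    reports: list[AnomalyReport] = []
    day_rows = pd.DataFrame(data.labels, columns=data.activity_names)
    for i, (user, day) in enumerate(errors.index):
        if (user, day) not in flagged:
            continue
        deviated = explain_day(day_rows.iloc[i], limits)
        if deviated:
            reports.append(AnomalyReport(user, day, ordinals[user][day], float(z[i]), deviated))
    reports.sort(key=lambda r: (r.user, r.day))

    n_dev = [len(r.deviated) for r in reports]
    summary = {
        "n_days": len(errors),
        "n_step1": len(flagged),
        "n_anomalies": len(reports),
        "mean_deviated_activities": float(np.mean(n_dev)) if n_dev else 0.0,
        "frac_with_3plus_deviated": float(np.mean([n >= 3 for n in n_dev])) if n_dev else 0.0,
        "p_value": model.p_value,
        "Z": model.Z,
    }
    return reports, summary


# ---- report rendering ----------------------------------------------------

def reports_to_frame(reports: list[AnomalyReport]) -> pd.DataFrame:
    """Flat listing: one row per deviated activity of each anomalous day."""
    rows = []
    for r in reports:
        for dev in r.deviated:
            rows.append({
                "user": r.user,
                "day": str(r.day),
                "day_id": r.day_ordinal,
                "activity": dev.activity,
                "dedication": f"{dev.dedication:.2f}%",
                "description": f"Dedication {dev.direction} the {dev.limit:.2f}%",
            })
    return pd.DataFrame(rows, columns=["user", "day", "day_id", "activity",
                                       "dedication", "description"])


def reports_to_json(reports: list[AnomalyReport], summary: dict) -> str:
    payload = {
        "summary": summary,
        "anomalies": [
            {
                "user": r.user,
                "day": str(r.day),
                "day_id": r.day_ordinal,
                "z_score": r.z_score,
                "deviated": [
                    {"activity": d.activity, "dedication": d.dedication,
                     "direction": d.direction, "limit": d.limit}
                    for d in r.deviated
                ],
            }
            for r in reports
        ],
    }
    return json.dumps(payload, indent=2)
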
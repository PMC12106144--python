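"""Window-1 models: the mean baseline and per-label classical regressors.

These models cannot exploit the temporal component, so they consume a
single previous day (window size 1 input).  Multi-output prediction is
assembled from one independent single-output regressor per activity, and
negative predictions are clipped to zero (dedication is non-negative).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import BayesianRidge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from ..windowing import WindowedDataset


def _flatten_inputs(data: WindowedDataset) -> np.ndarray:
    if data.inputs.shape[1] != 1:
        raise ValueError(
            "window-1 models take exactly one input day; build windows with w=2"
        )
    return data.inputs[:, 0, :]


@dataclass
class MeanBaseline:
    """Predicts the per-activity mean of the training labels for any input."""

    mean_: np.ndarray | None = None

    def fit(self, train: WindowedDataset) -> "MeanBaseline":
        if train.n_samples == 0:
            raise ValueError("empty training set")
        self.mean_ = train.labels.mean(axis=0)
        return self

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("baseline not fitted")
        n = len(inputs)
        return np.tile(self.mean_, (n, 1))


def fit_mean_baseline(train: WindowedDataset) -> MeanBaseline:
    return MeanBaseline().fit(train)


def _make_estimator(kind: str, seed: int | None):
    if kind == "knn":
        return KNeighborsRegressor()
    if kind == "svm":
        return SVR()
    if kind == "naive_bayes_style":
        # Gaussian-assumption Bayesian linear predictor per label
        return BayesianRidge()
    if kind == "adaboost":
        return AdaBoostRegressor(random_state=seed)
    if kind == "random_forest":
        return RandomForestRegressor(random_state=seed)
    if kind == "feedforward_net":
        return MLPRegressor(random_state=seed, max_iter=500)
    raise ValueError(f"unknown window-1 regressor kind {kind!r}")


WINDOW1_KINDS = (
    "knn",
    "svm",
    "naive_bayes_style",
    "adaboost",
    "random_forest",
    "feedforward_net",
)


@dataclass
class PerLabelRegressor:
    """One single-output regressor per activity; outputs clipped to >= 0.

    ``fit_seconds`` accumulates the per-label fit+predict wall-clock cost,
    summed over labels as the total cost of a full next-day prediction.
    """

    kind: str
    seed: int | None = None
    estimators_: list = field(default_factory=list, repr=False)
    fit_seconds: float = 0.0

    def fit(self, train: WindowedDataset) -> "PerLabelRegressor":
        X = _flatten_inputs(train)
        self.estimators_ = []
        t0 = time.perf_counter()
        for k in range(train.n_activities):
            est = _make_estimator(self.kind, self.seed)
            est.fit(X, train.labels[:, k])
            self.estimators_.append(est)
        self.fit_seconds = time.perf_counter() - t0
        return self

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        if not self.estimators_:
            raise RuntimeError("regressor not fitted")
        X = inputs[:, 0, :] if inputs.ndim == 3 else inputs
        preds = np.column_stack([est.predict(X) for est in self.estimators_])
        return np.clip(preds, 0.0, None)


def fit_window1_regressors(
    train: WindowedDataset, kind: str, seed: int | None = None
) -> PerLabelRegressor:
    if kind not in WINDOW1_KINDS:
        raise ValueError(f"unknown window-1 regressor kind {kind!r}")
    return PerLabelRegressor(kind, seed).fit(train)
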
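"""Evaluation protocol: per-day MSE/MAE, chronological k-fold
cross-validation, and the paired t-test used for model comparison.

Conventions: the per-day error averages over the t activities first
(MAE = mean |a - a_hat|, MSE = mean (a - a_hat)^2), and the dataset score
is the mean over days.  Fold dispersion uses the population standard
deviation (denominator k).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..windowing import WindowedDataset


def per_day_errors(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-day (MAE, MSE) vectors on the percentage scale."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch {truth.shape} vs {pred.shape}")
    diff = truth - pred
    return np.abs(diff).mean(axis=1), (diff ** 2).mean(axis=1)


def evaluate(predictor, data: WindowedDataset) -> dict:
    """Score a fitted predictor: dataset-level MSE/MAE plus per-day vectors."""
    if data.n_samples == 0:
        raise ValueError("empty evaluation set")
    pred = predictor.predict(data.inputs)
    mae_days, mse_days = per_day_errors(data.labels, pred)
    return {
        "mse": float(mse_days.mean()),
        "mae": float(mae_days.mean()),
        "per_day_mae": mae_days,
        "per_day_mse": mse_days,
    }


@dataclass
class EvalResult:
    mse_mean: float
    mse_std: float
    mae_mean: float
    mae_std: float
    seconds_mean: float
    seconds_std: float
    fold_mse: list[float] = field(default_factory=list)
    fold_mae: list[float] = field(default_factory=list)
    fold_seconds: list[float] = field(default_factory=list)

    @classmethod
    def from_folds(cls, mse, mae, seconds) -> "EvalResult":
        mse, mae, seconds = map(np.asarray, (mse, mae, seconds))
        return cls(
            float(mse.mean()), float(mse.std(ddof=0)),
            float(mae.mean()), float(mae.std(ddof=0)),
            float(seconds.mean()), float(seconds.std(ddof=0)),
            list(map(float, mse)), list(map(float, mae)), list(map(float, seconds)),
        )


def chronological_folds(
    data: WindowedDataset, k: int, mode: str = "chrono", seed: int | None = None
) -> list[np.ndarray]:
    """Index arrays for k folds.

    ``chrono`` (default): per user, samples ordered by label day are cut
    into k contiguous-in-time blocks, so each fold preserves chronology and
    no fold interleaves with another within a user.  ``shuffled`` permutes
    samples globally first; it is provided for comparison only and is
    leakage-prone for temporal data.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if data.n_samples < k:
        raise ValueError("not enough samples for the requested folds")
    folds: list[list[int]] = [[] for _ in range(k)]
    if mode == "shuffled":
        rng = np.random.default_rng(seed)
        for j, block in enumerate(np.array_split(rng.permutation(data.n_samples), k)):
            folds[j].extend(block.tolist())
    elif mode == "chrono":
        order = np.lexsort((np.array([d.toordinal() for d in data.label_days]),
                            np.array(data.users)))
        by_user: dict[str, list[int]] = {}
        for i in order:
            by_user.setdefault(data.users[i], []).append(int(i))
        for idxs in by_user.values():
            for j, block in enumerate(np.array_split(np.array(idxs), k)):
                folds[j].extend(block.tolist())
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate(
    model_factory,
    data: WindowedDataset,
    k: int = 3,
    mode: str = "chrono",
    seed: int | None = None,
) -> EvalResult:
    """k rounds of fit-on-(k-1)-folds / score-on-held-out-fold.

    ``model_factory(train_subset)`` must return a fitted predictor with a
    ``predict`` method.  Wall-clock fit+predict seconds are recorded per
    fold (hardware-dependent; reported, never asserted on).
    """
    folds = chronological_folds(data, k, mode=mode, seed=seed)
    all_idx = np.arange(data.n_samples)
    fold_mse, fold_mae, fold_seconds = [], [], []
    for j in range(k):
        test_idx = folds[j]
        train_idx = np.setdiff1d(all_idx, test_idx)
        if len(test_idx) == 0 or len(train_idx) == 0:
            raise ValueError("degenerate fold (empty train or test)")
        t0 = time.perf_counter()
        model = model_factory(data.subset(train_idx))
        scores = evaluate(model, data.subset(test_idx))
        fold_seconds.append(time.perf_counter() - t0)
        fold_mse.append(scores["mse"])
        fold_mae.append(scores["mae"])
    return EvalResult.from_folds(fold_mse, fold_mae, fold_seconds)


def paired_t_test(scores_a, scores_b) -> float:
    """Two-sided paired t-test p-value on per-fold score differences.

    Conventions for the degenerate zero-variance cases: identical scores
    give p = 1 (no evidence of difference); a constant nonzero difference
    gives p = 0 (difference certain under the paired design).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two paired scores")
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    if np.isclose(d.std(ddof=1), 0.0):
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)
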
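"""Seeded random hyperparameter search over the recurrent architectures.

Each trial samples an architecture from the declared ranges (layer counts
1-4, conv filters/kernel 2-64, recurrent/feed-forward units 8-256, dropout
0-0.4), trains it with the shared recipe and scores test-set MSE; the
argmin spec is returned with the full trial log.  The sampler is a seeded
uniform random sampler (trials are independent draws).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..windowing import WindowedDataset
from .evaluation import evaluate
from .recurrent import ModelSpec, TrainConfig, build_recurrent_predictor, train_predictor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    n_layers_range: tuple[int, int] = (1, 4)
    conv_range: tuple[int, int] = (2, 64)      # filters and kernel size
    units_range: tuple[int, int] = (8, 256)    # recurrent and feed-forward units
    dropout_range: tuple[float, float] = (0.0, 0.4)
    n_trials: int = 25

    def __post_init__(self) -> None:
        for lo, hi in (self.n_layers_range, self.conv_range, self.units_range,
                       self.dropout_range):
            if hi < lo:
                raise ValueError("empty search range")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class Trial:
    spec: ModelSpec
    mse: float
    mae: float


@dataclass
class SearchResult:
    best_spec: ModelSpec
    best_mse: float
    trials: list[Trial] = field(default_factory=list)


def _sample_spec(family: str, space: SearchSpace, w: int, rng: np.random.Generator) -> ModelSpec:
    lo, hi = space.n_layers_range
    ulo, uhi = space.units_range
    clo, chi = space.conv_range
    dlo, dhi = space.dropout_range
    return ModelSpec(
        family=family,
        w=w,
        n_recurrent_layers=int(rng.integers(lo, hi + 1)),
        units=int(rng.integers(ulo, uhi + 1)),
        dropout=float(rng.uniform(dlo, dhi)),
        conv_filters=int(rng.integers(clo, chi + 1)),
        kernel_size=int(min(rng.integers(clo, chi + 1), w - 1)),
        n_ff_layers=int(rng.integers(lo, hi + 1)),
        ff_units=int(rng.integers(ulo, uhi + 1)),
        attention_units=int(rng.integers(ulo, uhi + 1)),
    )


def hyperparameter_search(
    family: str,
    space: SearchSpace,
    train: WindowedDataset,
    val: WindowedDataset,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> SearchResult:
    """Run ``space.n_trials`` seeded trials and return the MSE-minimising spec."""
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    best: Trial | None = None
    for trial_no in range(space.n_trials):
        spec = _sample_spec(family, space, train.w, rng)
        model_seed = int(rng.integers(2**31))
        try:
            model = build_recurrent_predictor(spec, train.n_activities, seed=model_seed)
            train_predictor(model, train, config)
            scores = evaluate(model, val)
        except (RuntimeError, FloatingPointError) as exc:
            logger.warning("trial %d failed: %s", trial_no, exc)
            trials.append(Trial(spec, float("inf"), float("inf")))
            continue
        trial = Trial(spec, scores["mse"], scores["mae"])
        trials.append(trial)
        if best is None or trial.mse < best.mse:
            best = trial
    if best is None:
        raise RuntimeError("all hyperparameter trials failed")
    return SearchResult(best.spec, best.mse, trials)
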
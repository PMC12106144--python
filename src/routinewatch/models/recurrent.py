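"""Recurrent next-day predictors: LSTM, bidirectional LSTM, Conv+LSTM and
LSTM-with-attention architectures.

Each model maps the previous ``w - 1`` days, a (w-1) x t block of dedication
percentages, to the predicted t-vector for the next day.  The final layer
uses a rectifier so predictions are non-negative, matching the dedication
domain.  Training follows the standard recipe: Adam (lr 0.1, beta1 0.9,
beta2 0.999), mean-squared-error loss, batch size 128, 80 epochs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..nn import Adam, AdditiveAttention, Conv1D, Dense, LSTM, Tensor, concat
from ..windowing import WindowedDataset

RECURRENT_FAMILIES = ("rnn", "conv_lstm", "attention_rnn", "bi_rnn")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 128
    epochs: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive, epochs >= 1")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    w: int = 15
    n_recurrent_layers: int = 1
    units: int = 32
    dropout: float = 0.0
    conv_filters: int = 16
    kernel_size: int = 3
    n_ff_layers: int = 1
    ff_units: int = 64
    attention_units: int = 32
    # inputs are divided by this before the first layer: percentages land in
    # [0, 1], keeping LSTM pre-activations out of tanh saturation.  Outputs
    # stay on the percent scale (the final rectified layer is unscaled).
    input_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.family not in RECURRENT_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.w < 2:
            raise ValueError("recurrent families require w >= 2 (>= 1 input day)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_recurrent_layers < 1 or self.n_ff_layers < 1:
            raise ValueError("layer counts must be >= 1")


class RecurrentPredictor:
    """A built (possibly untrained) recurrent next-day model."""

    def __init__(self, spec: ModelSpec, t: int, seed: int = 0):
        self.spec = spec
        self.t = t
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.conv: Conv1D | None = None
        self.attention: AdditiveAttention | None = None
        self.recurrent: list = []
        u = spec.units

        n_in = t
        if spec.family == "conv_lstm":
            k = min(spec.kernel_size, spec.w - 1)
            self.conv = Conv1D(t, spec.conv_filters, k, rng=rng)
            n_in = spec.conv_filters

        if spec.family == "bi_rnn":
            for i in range(spec.n_recurrent_layers):
                last = i == spec.n_recurrent_layers - 1
                fwd = LSTM(n_in, u, return_sequences=True, rng=rng)
                bwd = LSTM(n_in, u, return_sequences=True, go_backwards=True, rng=rng)
                self.recurrent.append(("bi", fwd, bwd, last))
                n_in = 2 * u
            ff_in = 2 * u
        elif spec.family == "attention_rnn":
            self.recurrent.append(("uni", LSTM(n_in, u, return_sequences=True, rng=rng), None, False))
            self.attention = AdditiveAttention(u, spec.attention_units, rng=rng)
            self.recurrent.append(("uni", LSTM(u, u, return_sequences=False, rng=rng), None, True))
            ff_in = u
        else:  # rnn, conv_lstm
            for i in range(spec.n_recurrent_layers):
                last = i == spec.n_recurrent_layers - 1
                self.recurrent.append(
                    ("uni", LSTM(n_in, u, return_sequences=not last, rng=rng), None, last)
                )
                n_in = u
            ff_in = u

        self.ff: list[Dense] = []
        for _ in range(spec.n_ff_layers - 1):
            self.ff.append(Dense(ff_in, spec.ff_units, activation="relu", rng=rng))
            ff_in = spec.ff_units
        self.ff.append(Dense(ff_in, t, activation="relu", rng=rng))
        self.loss_history: list[float] = []

    # ------------------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        if self.conv is not None:
            params += self.conv.parameters()
        for kind, a, b, _ in self.recurrent:
            params += a.parameters()
            if kind == "bi":
                params += b.parameters()
        if self.attention is not None:
            params += self.attention.parameters()
        for d in self.ff:
            params += d.parameters()
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        p = self.spec.dropout
        if not training or p == 0.0:
            return x
        mask = (self._dropout_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def forward(self, X: np.ndarray, training: bool = False) -> Tensor:
        if X.ndim != 3 or X.shape[1] != self.spec.w - 1 or X.shape[2] != self.t:
            raise ValueError(
                f"expected input of shape (n, {self.spec.w - 1}, {self.t}), got {X.shape}"
            )
        X = X / self.spec.input_scale
        steps: list[Tensor] = [Tensor(X[:, i, :]) for i in range(X.shape[1])]
        if self.conv is not None:
            steps = self.conv(steps)
        att_done = False
        for kind, a, b, last in self.recurrent:
            if kind == "bi":
                fwd, bwd = a(steps), b(steps)
                steps = [concat([f, r], axis=1) for f, r in zip(fwd, bwd)]
                out = steps[-1] if last else None
                if not last:
                    steps = [self._dropout(s, training) for s in steps]
            else:
                res = a(steps)
                if a.return_sequences:
                    steps = [self._dropout(s, training) for s in res]
                    if self.attention is not None and not att_done:
                        steps = self.attention(steps)
                        att_done = True
                    out = None
                else:
                    out = self._dropout(res, training)
        h = out
        for d in self.ff:
            h = d(h)
        return h

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(inputs, dtype=float), training=False).data

    @property
    def last_attention_weights(self) -> np.ndarray | None:
        """Per-sample softmax weights over time steps from the last forward pass."""
        return None if self.attention is None else self.attention.last_alphas

    # ---- checkpointing ------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {"spec": asdict(self.spec), "t": self.t, "seed": self.seed}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savez(d / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(self.parameters())})

    @classmethod
    def load(cls, directory) -> "RecurrentPredictor":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        model = cls(ModelSpec(**manifest["spec"]), manifest["t"], manifest["seed"])
        with np.load(d / "weights.npz") as weights:
            for i, p in enumerate(model.parameters()):
                p.data[...] = weights[f"p{i}"]
        return model


def build_recurrent_predictor(spec: ModelSpec, t: int, seed: int = 0) -> RecurrentPredictor:
    return RecurrentPredictor(spec, t, seed)


def train_predictor(
    model: RecurrentPredictor, train: WindowedDataset, config: TrainConfig = TrainConfig()
) -> RecurrentPredictor:
    """Minimise MSE with Adam for exactly ``config.epochs`` epochs.

    Deterministic given identical seeds and backend; raises on non-finite
    loss (divergence).
    """
    if train.n_samples == 0:
        raise ValueError("empty training set")
    X, y = train.inputs, train.labels
    # start the rectified output layer at the per-activity label means:
    # a zero-initialised bias can leave output units dead (gradient-free)
    # under the final relu, and this also centres the initial loss.
    if not model.loss_history:
        model.ff[-1].b.data[...] = y.mean(axis=0, keepdims=True)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng(config.seed)
    n = len(y)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model.forward(X[idx], training=True)
            loss = (pred - Tensor(y[idx])).square().mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged to non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        model.loss_history.append(epoch_loss / n)
    return model
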
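"""Chronological train/test splitting and sliding-window dataset construction.

Next-day prediction samples are built per user by sliding a window of ``w``
consecutive days one day forward at a time: the first ``w - 1`` days form
the input block and day ``w`` is the label.  Splitting is chronological
within each user (first 70% of days train, rest test) so both subsets
contain every user and no test label precedes a training day.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import DedicationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def chronological_split(
    table: DedicationTable, spec: SplitSpec = SplitSpec()
) -> tuple[DedicationTable, DedicationTable]:
    """Per user: first floor(train_fraction * m) days to train, rest to test.

    Users with fewer than 2 days are excluded (with a warning) since they
    cannot contribute to both subsets.
    """
    train_parts, test_parts = [], []
    for user in table.users:
        block = table.user_matrix(user)
        m = len(block)
        if m < 2:
            logger.warning("user %s has %d day(s); excluded from split", user, m)
            continue
        cut = int(np.floor(spec.train_fraction * m))
        cut = max(1, min(cut, m - 1))  # both subsets non-empty for m >= 2
        idx = pd.MultiIndex.from_product([[user], block.index], names=["user", "day"])
        part = block.set_axis(idx)
        train_parts.append(part.iloc[:cut])
        test_parts.append(part.iloc[cut:])
    if not train_parts:
        raise ValueError("no user has enough days to split")
    return (
        DedicationTable(pd.concat(train_parts)),
        DedicationTable(pd.concat(test_parts)),
    )


@dataclass
class WindowedDataset:
    """Supervised next-day samples: inputs (n, w-1, t), labels (n, t)."""

    inputs: np.ndarray
    labels: np.ndarray
    users: list[str]
    label_days: list[dt.date]
    w: int
    activity_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.inputs) == len(self.users) == len(self.label_days) == n):
            raise ValueError("inconsistent sample arrays")
        if n and self.inputs.shape[1] != self.w - 1:
            raise ValueError("input block must have w - 1 days")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def n_activities(self) -> int:
        return self.labels.shape[1]

    def subset(self, idx) -> "WindowedDataset":
        idx = np.asarray(idx)
        return WindowedDataset(
            self.inputs[idx],
            self.labels[idx],
            [self.users[i] for i in idx],
            [self.label_days[i] for i in idx],
            self.w,
            self.activity_names,
        )

    # flat persisted layout: one row per sample, input days flattened oldest-first
    def to_csv(self, path) -> None:
        t = self.n_activities
        cols = [f"in_d{d}_{a}" for d in range(self.w - 1) for a in self.activity_names]
        cols += [f"label_{a}" for a in self.activity_names]
        flat = np.hstack([self.inputs.reshape(self.n_samples, -1), self.labels])
        df = pd.DataFrame(flat, columns=cols)
        df.insert(0, "label_day", [str(d) for d in self.label_days])
        df.insert(0, "user", self.users)
        with open(path, "w") as fh:
            fh.write(f"# routinewatch windows v1 w={self.w} t={t}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "WindowedDataset":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# routinewatch windows v1"):
                raise ValueError("not a routinewatch windows file")
            meta = dict(tok.split("=") for tok in header.split() if "=" in tok)
            df = pd.read_csv(fh)
        w, t = int(meta["w"]), int(meta["t"])
        acts = [c[len("label_"):] for c in df.columns
                if c.startswith("label_") and c != "label_day"]
        inputs = df[[c for c in df.columns if c.startswith("in_")]].to_numpy()
        return cls(
            inputs.reshape(len(df), w - 1, t),
            df[[f"label_{a}" for a in acts]].to_numpy(),
            df["user"].astype(str).tolist(),
            [dt.date.fromisoformat(s) for s in df["label_day"]],
            w,
            acts,
        )


def _consecutive_segments(days: list[dt.date], allow_gaps: bool) -> list[list[int]]:
    segments: list[list[int]] = [[0]] if days else []
    for i in range(1, len(days)):
        if allow_gaps or (days[i] - days[i - 1]) == dt.timedelta(days=1):
            segments[-1].append(i)
        else:
            segments.append([i])
    return segments


def make_windows(
    table: DedicationTable, w: int, allow_gaps: bool = False
) -> WindowedDataset:
    """Slide a window of ``w`` days one day forward per step, per user.

    A user block of m consecutive days yields max(0, m - w + 1) samples.
    By default windows never span a gap of missing calendar days (the
    window restarts after a gap); ``allow_gaps=True`` treats rows as
    consecutive regardless.
    """
    if w < 2:
        raise ValueError("window size w must be >= 2")
    inputs, labels, users, label_days = [], [], [], []
    for user in table.users:
        block = table.user_matrix(user)
        days = list(block.index)
        vals = block.to_numpy()
        for seg in _consecutive_segments(days, allow_gaps):
            for s in range(len(seg) - w + 1):
                rows = seg[s : s + w]
                inputs.append(vals[rows[:-1]])
                labels.append(vals[rows[-1]])
                users.append(user)
                label_days.append(days[rows[-1]])
    t = table.n_activities
    return WindowedDataset(
        np.asarray(inputs, dtype=float).reshape(len(labels), w - 1, t),
        np.asarray(labels, dtype=float).reshape(len(labels), t),
        users,
        label_days,
        w,
        table.activity_names,
    )
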
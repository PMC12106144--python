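"""Parse labelled smart-home event logs into day x activity dedication tables.

The input is the standard single-resident smart-home log layout: one sensor
event per line with a timestamp, the sensor identifier, the value read and
the activity label recognised for that moment.  Consecutive events sharing
an activity label are merged into episodes, episodes are framed within
calendar days, and per-day dedication percentages are accumulated.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .table import DedicationTable

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400.0
OTHER_ACTIVITY = "Other_Activity"


class SensorEvent(NamedTuple):
    timestamp: dt.datetime
    sensor_id: str
    value: str
    activity: str


@dataclass(frozen=True)
class ActivityInterval:
    """A maximal episode of one activity, with explicit start/end instants."""

    user: str
    activity: str
    start: dt.datetime
    end: dt.datetime

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval end before start: {self}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


def read_casas_events(path, user: str) -> list[SensorEvent]:
    """Read a whitespace-separated event log: date time sensor value activity.

    Malformed lines are skipped with a logged warning count; an unreadable
    file raises.
    """
    path = Path(path)
    events: list[SensorEvent] = []
    n_bad = 0
    with path.open("r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 5:
                n_bad += 1
                logger.debug("%s:%d malformed line (%d fields)", path, lineno, len(parts))
                continue
            date_s, time_s, sensor, value = parts[0], parts[1], parts[2], parts[3]
            activity = parts[4]
            try:
                ts = dt.datetime.fromisoformat(f"{date_s} {time_s}")
            except ValueError:
                n_bad += 1
                logger.debug("%s:%d unparseable timestamp", path, lineno)
                continue
            events.append(SensorEvent(ts, sensor, value, activity))
    if n_bad:
        logger.warning("%s: skipped %d malformed line(s) for user %s", path, n_bad, user)
    return events


def merge_consecutive_runs(
    events: Sequence[SensorEvent],
    user: str,
    end_convention: str = "next_start",
) -> list[ActivityInterval]:
    """Merge maximal runs of identical consecutive activity labels.

    Each run becomes one interval starting at its first event.  By default a
    run ends where the next run starts (the recognised activity persists
    until the next recognised activity), which yields full-day coverage;
    ``end_convention="last_event"`` instead ends a run at its own last event.
    The final run always ends at its own last event.
    """
    if end_convention not in ("next_start", "last_event"):
        raise ValueError(f"unknown end convention {end_convention!r}")
    if not events:
        return []
    events = sorted(events, key=lambda e: e.timestamp)  # stable, defensive

    runs: list[tuple[str, dt.datetime, dt.datetime]] = []  # (activity, first_ts, last_ts)
    cur_act = events[0].activity
    first_ts = last_ts = events[0].timestamp
    for ev in events[1:]:
        if ev.activity == cur_act:
            last_ts = ev.timestamp
        else:
            runs.append((cur_act, first_ts, last_ts))
            cur_act = ev.activity
            first_ts = last_ts = ev.timestamp
    runs.append((cur_act, first_ts, last_ts))

    intervals: list[ActivityInterval] = []
    for i, (act, start, last) in enumerate(runs):
        if end_convention == "next_start" and i + 1 < len(runs):
            end = runs[i + 1][1]
        else:
            end = last
        intervals.append(ActivityInterval(user, act, start, end))
    return intervals


def split_intervals_at_midnight(
    intervals: Iterable[ActivityInterval],
) -> list[ActivityInterval]:
    """Frame intervals within single calendar days, conserving total duration."""
    out: list[ActivityInterval] = []
    for iv in intervals:
        start = iv.start
        while start.date() != iv.end.date():
            midnight = dt.datetime.combine(start.date() + dt.timedelta(days=1), dt.time())
            out.append(ActivityInterval(iv.user, iv.activity, start, midnight))
            start = midnight
        out.append(ActivityInterval(iv.user, iv.activity, start, iv.end))
    return out


def compute_daily_dedication(
    intervals: Iterable[ActivityInterval],
    activity_names: Sequence[str] | None = None,
    drop_boundary_days: bool = True,
) -> DedicationTable:
    """Accumulate per-(user, day, activity) durations into dedication percent.

    dedication = 100 * total_seconds / 86400, against a fixed full-day
    denominator.  Days inside a user's observation range with no intervals
    become all-zero rows.  The first and last observed calendar day of each
    user are dropped by default (they are typically truncated).
    """
    intervals = list(intervals)
    rows: dict[tuple[str, dt.date], dict[str, float]] = {}
    user_days: dict[str, list[dt.date]] = {}
    for iv in intervals:
        if iv.duration_s < 0:
            raise ValueError(f"negative duration: {iv}")
        if iv.start.date() != iv.end.date() and not (
            iv.end.time() == dt.time() and iv.end.date() == iv.start.date() + dt.timedelta(days=1)
        ):
            raise ValueError("interval crosses a day boundary; split at midnight first")
        key = (iv.user, iv.start.date())
        rows.setdefault(key, {})
        rows[key][iv.activity] = rows[key].get(iv.activity, 0.0) + iv.duration_s
        user_days.setdefault(iv.user, []).append(iv.start.date())

    if activity_names is None:
        seen = {iv.activity for iv in intervals}
        activity_names = sorted(seen)
    activity_names = list(activity_names)

    index: list[tuple[str, dt.date]] = []
    for user, days in user_days.items():
        lo, hi = min(days), max(days)
        if drop_boundary_days:
            lo = lo + dt.timedelta(days=1)
            hi = hi - dt.timedelta(days=1)
        d = lo
        while d <= hi:
            index.append((user, d))
            d += dt.timedelta(days=1)

    data = np.zeros((len(index), len(activity_names)))
    col = {a: k for k, a in enumerate(activity_names)}
    for r, key in enumerate(index):
        for act, secs in rows.get(key, {}).items():
            if act in col:
                data[r, col[act]] = 100.0 * secs / SECONDS_PER_DAY
    df = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(index, names=["user", "day"]),
        columns=activity_names,
    )
    return DedicationTable(df)


def drop_activity(table: DedicationTable, label: str) -> DedicationTable:
    """Remove one activity column (no renormalisation of the others)."""
    if label not in table.activity_names:
        raise KeyError(f"activity {label!r} not in table")
    return DedicationTable(table.data.drop(columns=[label]))


def summarize_activities(table: DedicationTable) -> pd.DataFrame:
    """Per-activity mean and population standard deviation, in percent."""
    if len(table) == 0:
        raise ValueError("empty dedication table")
    mean = table.data.mean(axis=0)
    std = table.data.std(axis=0, ddof=0)
    return pd.DataFrame({"mean": mean, "std": std})


def ingest_event_logs(
    log_dir,
    pattern: str = "*.txt",
    drop_other_activity: bool = True,
    drop_boundary_days: bool = True,
    end_convention: str = "next_start",
) -> DedicationTable:
    """Full pipeline over a directory of per-user event logs (user = file stem)."""
    log_dir = Path(log_dir)
    files = sorted(log_dir.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no event logs matching {pattern!r} in {log_dir}")
    all_intervals: list[ActivityInterval] = []
    vocab: set[str] = set()
    for f in files:
        user = f.stem
        events = read_casas_events(f, user)
        ivs = split_intervals_at_midnight(
            merge_consecutive_runs(events, user, end_convention=end_convention)
        )
        vocab.update(iv.activity for iv in ivs)
        all_intervals.extend(ivs)
    table = compute_daily_dedication(
        all_intervals, sorted(vocab), drop_boundary_days=drop_boundary_days
    )
    if drop_other_activity and OTHER_ACTIVITY in table.activity_names:
        table = drop_activity(table, OTHER_ACTIVITY)
    return table
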
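"""Day x activity dedication tables.

The central container of the package: for each monitored user and calendar
day, the percentage of the day (0-100) dedicated to each recognised
activity.  Backed by a pandas DataFrame with a (user, day) MultiIndex and
one float column per activity.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUM_TOLERANCE = 1e-6


@dataclass
class DedicationTable:
    """Per (user, day) dedication percentages over a fixed activity vocabulary.

    Parameters
    ----------
    data
        DataFrame indexed by a (user, day) MultiIndex (``day`` holds
        ``datetime.date`` values), one column per activity, values in
        percent of the day.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.nlevels != 2:
            raise ValueError("DedicationTable requires a (user, day) MultiIndex")
        self.data.index = self.data.index.set_names(["user", "day"])
        if self.data.index.duplicated().any():
            raise ValueError("duplicate (user, day) pairs")
        self.data = self.data.sort_index()

    @property
    def activity_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_activities(self) -> int:
        return self.data.shape[1]

    @property
    def users(self) -> list[str]:
        return list(self.data.index.get_level_values("user").unique())

    def days_for(self, user: str) -> list[dt.date]:
        return list(self.data.loc[user].index)

    def user_matrix(self, user: str) -> pd.DataFrame:
        """The day-by-activity block of one user, days ascending."""
        return self.data.loc[user]

    def validate(self, include_total: bool = True) -> None:
        """Check the value-domain invariants (cells in [0,100], row sums <= 100)."""
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("non-finite dedication values")
        if (vals < -SUM_TOLERANCE).any() or (vals > 100 + SUM_TOLERANCE).any():
            raise ValueError("dedication values outside [0, 100]")
        if include_total:
            sums = vals.sum(axis=1)
            if (sums > 100 + SUM_TOLERANCE).any():
                raise ValueError("day totals exceed 100%")

    def copy(self) -> "DedicationTable":
        return DedicationTable(self.data.copy())

    def __len__(self) -> int:
        return len(self.data)

    # ---- I/O -------------------------------------------------------------

    def to_csv(self, path, decimals: int = 2) -> None:
        """Write ``user,day,<activity...>`` CSV; values rounded at output only."""
        out = self.data.round(decimals).reset_index()
        out["day"] = out["day"].astype(str)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DedicationTable":
        df = pd.read_csv(path)
        if "user" not in df.columns or "day" not in df.columns:
            raise ValueError("dedication CSV must have 'user' and 'day' columns")
        df["day"] = pd.to_datetime(df["day"]).dt.date
        df = df.set_index(["user", "day"])
        return cls(df.astype(float))
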
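import datetime as dt

import numpy as np
import pandas as pd
import pytest

from routinewatch.simulate import simulate_population
from routinewatch.table import DedicationTable


def make_table(values, users=None, start=dt.date(2012, 7, 20), columns=None):
    """Small dedication table from a 2-D array (one user unless given)."""
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    columns = columns or [f"A{k}" for k in range(t)]
    users = users or ["u1"] * n
    days = []
    counter = {}
    for u in users:
        counter[u] = counter.get(u, -1) + 1
        days.append(start + dt.timedelta(days=counter[u]))
    idx = pd.MultiIndex.from_arrays([users, days], names=["user", "day"])
    return DedicationTable(pd.DataFrame(values, index=idx, columns=columns))


@pytest.fixture(scope="session")
def small_population():
    """A compact simulated corpus shared by the cheaper tests."""
    table, manifest = simulate_population(n_users=6, n_days=40, seed=11)
    return table, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
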
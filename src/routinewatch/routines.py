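"""Daily-routine pattern discovery: k-means over dedication vectors with
silhouette scoring."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .table import DedicationTable

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    k: int
    labels: pd.Series          # (user, day) -> cluster id
    centroids: np.ndarray      # k x t, on the input (raw or standardised) scale
    silhouette: float
    standardized: bool = False


def cluster_routines(
    table: DedicationTable, k: int, seed: int = 0, standardize: bool = False
) -> ClusteringResult:
    """Seeded k-means on day vectors; silhouette uses Euclidean distance.

    ``standardize=True`` z-scores each activity column first (the
    clustering then weights rare and dominant activities equally).
    """
    n = len(table)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available days")
    X = table.data.to_numpy()
    if standardize:
        X = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    if k == n:
        logger.warning("k equals the number of days: every day is its own cluster")
        sil = 1.0  # degenerate; silhouette undefined for singleton-only clustering
    else:
        sil = float(silhouette_score(X, labels, metric="euclidean"))
    return ClusteringResult(
        k=k,
        labels=pd.Series(labels, index=table.data.index, name="cluster"),
        centroids=km.cluster_centers_,
        silhouette=sil,
        standardized=standardize,
    )


def select_k(
    table: DedicationTable,
    ks=range(2, 11),
    seed: int = 0,
    standardize: bool = False,
) -> tuple[ClusteringResult, pd.DataFrame]:
    """Grid over k, returning the silhouette-maximising clustering plus the
    full k/silhouette table."""
    results = [cluster_routines(table, k, seed=seed, standardize=standardize)
               for k in ks if k <= len(table)]
    if not results:
        raise ValueError("no feasible k in the grid")
    grid = pd.DataFrame({"k": [r.k for r in results],
                         "silhouette": [r.silhouette for r in results]})
    best = max(results, key=lambda r: r.silhouette)
    return best, grid
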
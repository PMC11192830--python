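"""Aggregate per-rater similarity ratings into a normalized dissimilarity matrix.

Raters judge unordered stimulus pairs on an integer similarity scale
(1 = not similar ... L = very similar).  Ratings are averaged per pair across
raters, min-max normalized to [0, 1] over the observed pairs, and subtracted
from one to yield dissimilarities.  Unobserved pairs receive weight 0 and are
ignored by the MDS fit downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from rulexj.mds import DissimilarityMatrix

__all__ = [
    "aggregate_ratings",
    "normalize_to_dissimilarity",
    "dissimilarity_from_ratings",
    "read_ratings",
    "write_dissimilarity",
    "read_dissimilarity",
]

log = logging.getLogger(__name__)

RATING_COLUMNS = ["rater_id", "stim_a", "stim_b", "rating"]


def read_ratings(path: str) -> pd.DataFrame:
    """Read a long-format rating table (rater_id, stim_a, stim_b, rating)."""
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rating table missing columns {missing}")
    return df


def aggregate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Mean similarity and rating count per unordered stimulus pair.

    Returns a DataFrame with columns (stim_a, stim_b, mean_rating, n_ratings)
    where (stim_a, stim_b) is the canonical (sorted) order of the pair.
    """
    if len(table) == 0:
        raise ValueError("rating table is empty")
    if (table["stim_a"].astype(str) == table["stim_b"].astype(str)).any():
        raise ValueError("self-pairs (stim_a == stim_b) are not allowed")
    a = table["stim_a"].astype(str).to_numpy()
    b = table["stim_b"].astype(str).to_numpy()
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    agg = (
        pd.DataFrame({"stim_a": lo, "stim_b": hi, "rating": table["rating"].to_numpy()})
        .groupby(["stim_a", "stim_b"], as_index=False)
        .agg(mean_rating=("rating", "mean"), n_ratings=("rating", "size"))
    )
    return agg


def normalize_to_dissimilarity(
    mean_sims: pd.DataFrame, labels: list[str] | None = None
) -> DissimilarityMatrix:
    """Min-max normalize mean similarities over observed pairs and flip them
    into dissimilarities ``1 - s_norm``; assemble the symmetric matrix.

    Pairs absent from ``mean_sims`` (possible under an incomplete design)
    get value 0 and weight 0.  Stimulus order is lexicographic over ids.
    """
    if labels is None:
        labels = sorted(set(mean_sims["stim_a"]) | set(mean_sims["stim_b"]))
    labels = [str(x) for x in labels]
    index = {s: i for i, s in enumerate(labels)}
    n = len(labels)

    m = mean_sims["mean_rating"].to_numpy(float)
    lo, hi = float(m.min()), float(m.max())
    if hi - lo <= 0:
        raise ValueError("mean similarities are constant; zero normalization range")
    dis = 1.0 - (m - lo) / (hi - lo)

    values = np.zeros((n, n))
    weights = np.zeros((n, n))
    ia = mean_sims["stim_a"].map(index).to_numpy()
    ib = mean_sims["stim_b"].map(index).to_numpy()
    values[ia, ib] = dis
    values[ib, ia] = dis
    weights[ia, ib] = 1.0
    weights[ib, ia] = 1.0

    n_missing = n * (n - 1) // 2 - len(mean_sims)
    if n_missing > 0:
        log.warning("%d stimulus pairs have no ratings (weight 0)", n_missing)
    return DissimilarityMatrix(values=values, weights=weights, labels=labels)


def dissimilarity_from_ratings(
    table: pd.DataFrame, labels: list[str] | None = None
) -> DissimilarityMatrix:
    """Convenience composition: aggregate then normalize."""
    return normalize_to_dissimilarity(aggregate_ratings(table), labels=labels)


def write_dissimilarity(D: DissimilarityMatrix, values_path: str, weights_path: str) -> None:
    """Write the dissimilarity matrix and its weights as square delimited
    text with a leading label column."""
    for arr, path in ((D.values, values_path), (D.weights, weights_path)):
        df = pd.DataFrame(arr, columns=D.labels)
        df.insert(0, "stim_id", D.labels)
        df.to_csv(path, index=False)


def read_dissimilarity(values_path: str, weights_path: str) -> DissimilarityMatrix:
    vdf = pd.read_csv(values_path)
    wdf = pd.read_csv(weights_path)
    labels = [str(x) for x in vdf["stim_id"]]
    values = vdf[labels].to_numpy(float)
    weights = wdf[labels].to_numpy(float)
    return DissimilarityMatrix(values=values, weights=weights, labels=labels)
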
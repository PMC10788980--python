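"""Biological read-outs of a trained model.

Thresholded condition assignment from the probability matrix, gene ranking
from the first-layer weights, k-means clustering of the latent embedding,
and cluster-by-category composition tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

UNASSIGNED = "unassigned"


def assign_condition(
    P: np.ndarray,
    threshold: float = 0.5,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Assign each cell the class whose probability reaches ``threshold``.

    A cell whose maximum probability falls below the threshold is
    "unassigned".  An exact tie at the threshold (possible only at 0.5 with
    two classes) is broken toward the lower class index and flagged.

    Returns a DataFrame with columns ``assigned`` and ``tie``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1]; got {threshold}")
    P = np.asarray(P, dtype=np.float64)
    n, c = P.shape
    if class_names is None:
        class_names = [str(j) for j in range(c)]
    hits = P >= threshold - 1e-12
    n_hits = hits.sum(axis=1)
    first_hit = np.where(n_hits > 0, hits.argmax(axis=1), -1)
    assigned = [class_names[j] if j >= 0 else UNASSIGNED for j in first_hit]
    tie = n_hits > 1
    return pd.DataFrame({"assigned": assigned, "tie": tie})


def rank_genes(
    W0: np.ndarray,
    gene_names: list[str],
    top_n: int = 25,
    mode: str = "signed",
) -> pd.DataFrame:
    """Rank genes by aggregated first-layer weight.

    Score per gene is the row-sum of W0 (``mode='signed'``, the default) or
    the row-sum of absolute weights (``mode='absolute'``, immune to
    cancellation across latent dimensions).  Sorted descending, ties broken
    lexicographically by gene name.
    """
    W0 = np.asarray(W0)
    if len(gene_names) != W0.shape[0]:
        raise ValueError("gene_names length must match W0 rows")
    if mode == "signed":
        scores = W0.sum(axis=1)
    elif mode == "absolute":
        scores = np.abs(W0).sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'signed' or 'absolute'")
    if top_n > len(gene_names):
        warnings.warn(
            f"top_n={top_n} exceeds {len(gene_names)} genes; truncating",
            stacklevel=2,
        )
        top_n = len(gene_names)
    df = pd.DataFrame({"gene": gene_names, "score": scores})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return df.head(top_n).reset_index(drop=True)


def cluster_latent(
    latent: np.ndarray, k: int, seed: int = 0, restarts: int = 10
) -> np.ndarray:
    """k-means on the latent embedding; best inertia over seeded restarts."""
    latent = np.asarray(latent, dtype=np.float64)
    if not 1 <= k <= latent.shape[0]:
        raise ValueError(f"k must be in [1, n_cells={latent.shape[0]}]; got {k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(latent)


def composition_table(categories, clusters) -> pd.DataFrame:
    """Fraction of each category within each cluster; rows sum to 1.

    Empty clusters (possible when cluster ids are not contiguous) yield a
    zero row and a warning.
    """
    categories = np.asarray(categories)
    clusters = np.asarray(clusters)
    if categories.shape != clusters.shape:
        raise ValueError("categories and clusters must have equal length")
    tab = pd.crosstab(pd.Series(clusters, name="cluster"), pd.Series(categories, name="category"))
    totals = tab.sum(axis=1)
    if (totals == 0).any():
        warnings.warn("empty cluster produced a zero row", stacklevel=2)
    frac = tab.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return frac
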
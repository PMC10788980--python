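"""Evaluation statistics: multiclass Brier score and normalized mutual information."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import normalized_mutual_info_score


def brier_score(true_labels: np.ndarray, P: np.ndarray) -> float:
    """Multiclass Brier score, lower is better, range [0, 2].

    (1/N) sum_i sum_j (p_ij - delta_ij)^2 with delta_ij = 1 iff y_i = j:
    the mean squared distance between each predicted probability vector and
    the one-hot truth.
    """
    P = np.asarray(P, dtype=np.float64)
    y = np.asarray(true_labels)
    if P.ndim != 2 or y.shape[0] != P.shape[0]:
        raise ValueError(f"shape mismatch: labels {y.shape}, P {P.shape}")
    if y.min() < 0 or y.max() >= P.shape[1]:
        raise ValueError("labels out of range for the probability matrix")
    delta = np.zeros_like(P)
    delta[np.arange(len(y)), y] = 1.0
    return float(((P - delta) ** 2).sum(axis=1).mean())


def nmi(partition_a: np.ndarray, partition_b: np.ndarray) -> float:
    """NMI normalized by the arithmetic mean of the two partition entropies.

    Returns 0 when either partition is constant (zero-entropy convention),
    1 for identical partitions up to relabeling.
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))
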
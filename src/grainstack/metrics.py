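"""Detection-quality metrics against generator ground truth."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["match_centroids", "precision_recall"]


def match_centroids(
    detected_um: np.ndarray, true_um: np.ndarray, max_dist_um: float = 0.5
) -> list[tuple[int, int]]:
    """One-to-one matching of detected to true centroids.

    Minimum-cost (Hungarian) assignment on Euclidean distance; pairs farther
    apart than ``max_dist_um`` are not matched.
    """
    detected_um = np.atleast_2d(detected_um)
    true_um = np.atleast_2d(true_um)
    if detected_um.shape[0] == 0 or true_um.shape[0] == 0:
        return []
    d = np.linalg.norm(detected_um[:, None, :] - true_um[None, :, :], axis=-1)
    cost = np.where(d <= max_dist_um, d, 1e6)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= max_dist_um]


def precision_recall(
    detected_um: np.ndarray, true_um: np.ndarray, max_dist_um: float = 0.5
) -> tuple[float, float]:
    """Detection precision and recall under one-to-one centroid matching."""
    n_det = np.atleast_2d(detected_um).shape[0] if np.size(detected_um) else 0
    n_true = np.atleast_2d(true_um).shape[0] if np.size(true_um) else 0
    matches = match_centroids(detected_um, true_um, max_dist_um)
    tp = len(matches)
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_true if n_true else 1.0
    return precision, recall
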
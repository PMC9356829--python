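"""Plug-in entropy and mutual-information estimators on discrete label vectors.

All quantities are in bits (log base 2) with empirical plug-in
probabilities, no smoothing, and the convention ``0 * log 0 = 0``.
Mutual information is computed through the identity
``MI(X1, X2) = H(X1) + H(X2) - H(X1, X2)`` and clamped at zero against
negative floating-point residue.

Applied to ensembles: ``tree_mi_matrix`` measures redundancy between the
trees' predicted-label vectors on a validation set, and ``tree_truth_mi``
measures how informative each tree's predictions are about the true labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TreeOutputs",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "tree_mi_matrix",
    "tree_truth_mi",
]


@dataclass
class TreeOutputs:
    """Per-tree predicted labels on a validation set, plus the true labels.

    ``predictions`` has shape (n_trees, L); ``truth`` has length L.
    """

    predictions: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=np.int64)
        self.truth = np.asarray(self.truth, dtype=np.int64)
        if self.predictions.ndim != 2:
            raise ValueError("predictions must be a (n_trees, L) matrix")
        if self.predictions.shape[1] != self.truth.size:
            raise ValueError("prediction vectors and truth must share length L")

    @property
    def n_trees(self) -> int:
        return self.predictions.shape[0]


def _entropy_of_codes(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    return float(-np.sum(p * np.log2(p)))


def entropy(labels: Sequence[int]) -> float:
    """Shannon entropy, in bits, of the empirical label distribution."""
    y = np.asarray(labels, dtype=np.int64)
    if y.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    return _entropy_of_codes(y)


def joint_entropy(x1: Sequence[int], x2: Sequence[int]) -> float:
    """Entropy of the paired symbol sequence ``(x1[t], x2[t])``, in bits."""
    a = np.asarray(x1, dtype=np.int64)
    b = np.asarray(x2, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("joint entropy requires equal-length vectors")
    if a.size == 0:
        raise ValueError("joint entropy of empty vectors is undefined")
    # collapse each pair to a single code
    pairs = a.astype(np.int64) * (b.max() + 1 if b.size else 1) + b
    return _entropy_of_codes(pairs)


def mutual_information(x1: Sequence[int], x2: Sequence[int]) -> float:
    """MI(X1, X2) = H(X1) + H(X2) - H(X1, X2), in bits, clamped at 0."""
    a = np.asarray(x1, dtype=np.int64)
    b = np.asarray(x2, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("mutual information requires equal-length vectors")
    mi = entropy(a) + entropy(b) - joint_entropy(a, b)
    return max(0.0, float(mi))


def tree_mi_matrix(outputs: TreeOutputs) -> np.ndarray:
    """Symmetric tree-tree MI matrix; entry (i, c) = MI(z_i, z_c).

    The diagonal holds each tree's output entropy (MI of a vector with
    itself).  Requires at least two trees.
    """
    z = outputs.predictions
    T = outputs.n_trees
    if T < 2:
        raise ValueError("a redundancy matrix needs at least two trees")
    h = np.array([entropy(z[i]) for i in range(T)])
    M = np.zeros((T, T))
    for i in range(T):
        M[i, i] = h[i]
        for c in range(i + 1, T):
            mi = max(0.0, h[i] + h[c] - joint_entropy(z[i], z[c]))
            M[i, c] = M[c, i] = mi
    return M


def tree_truth_mi(outputs: TreeOutputs) -> np.ndarray:
    """Per-tree MI between predictions and the true labels (higher = better)."""
    z = outputs.predictions
    return np.array([mutual_information(z[i], outputs.truth) for i in range(outputs.n_trees)])
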
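"""Traditional bootstrap random forest with majority voting.

Each tree is trained on a bootstrap draw of ``n`` rows (default n = N, the
mainstream RF convention) with its own rng stream derived from
``(seed, tree_index)``, so training is reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cart_tree import DecisionTree, grow_tree
from .panel import LabeledPanel

__all__ = ["Forest", "bootstrap_sample", "train_forest", "majority_vote"]


@dataclass
class Forest:
    """Ordered collection of CART trees sharing one feature space."""

    trees: list[DecisionTree]
    bootstrap_n: int
    d: int
    seed: int
    class_names: list[str]
    feature_names: list[str]

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Per-tree predictions, shape (n_trees, n_probes)."""
        X = np.asarray(X, dtype=float)
        return np.stack([t.predict(X) for t in self.trees])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote predictions for a probe matrix."""
        votes = self.predict_matrix(X)
        out = np.empty(votes.shape[1], dtype=np.int64)
        for j in range(votes.shape[1]):
            counts = np.bincount(votes[:, j], minlength=self.n_classes)
            out[j] = np.argmax(counts)  # first max -> smallest class code on ties
        return out


def bootstrap_sample(panel: LabeledPanel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` row indices uniformly with replacement."""
    if n < 1:
        raise ValueError("bootstrap draw size must be at least 1")
    return rng.integers(0, panel.n_samples, size=n)


def train_forest(
    panel: LabeledPanel,
    n_trees: int = 100,
    n: Optional[int] = None,
    d: Optional[int] = None,
    seed: int = 0,
    *,
    min_samples_split: int = 2,
    max_depth: Optional[int] = None,
) -> Forest:
    """Train ``n_trees`` CART trees, each on its own bootstrap draw.

    Tree i uses the rng stream ``default_rng([seed, i])`` for both its
    bootstrap draw and its per-node feature subsets, so the forest is fully
    reproducible from ``seed`` and each tree is independent of construction
    order.
    """
    if n_trees < 1:
        raise ValueError("a forest needs at least one tree")
    if n is None:
        n = panel.n_samples
    if d is None:
        d = int(np.ceil(np.sqrt(panel.n_features)))
    trees = []
    for i in range(n_trees):
        rng = np.random.default_rng([seed, i])
        rows = bootstrap_sample(panel, n, rng)
        trees.append(
            grow_tree(
                panel,
                rows,
                d,
                min_samples_split=min_samples_split,
                max_depth=max_depth,
                rng=rng,
                seed=i,
            )
        )
    return Forest(trees, n, d, seed, list(panel.class_names), list(panel.feature_names))


def majority_vote(forest: Forest, x: Sequence[float]) -> int:
    """Unweighted plurality over tree votes; ties go to the smallest class code."""
    if forest.n_trees < 1:
        raise ValueError("forest is empty")
    votes = np.array([t.predict_one(np.asarray(x, dtype=float)) for t in forest.trees])
    counts = np.bincount(votes, minlength=forest.n_classes)
    return int(np.argmax(counts))
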
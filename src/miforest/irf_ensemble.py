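"""Improved random forest (IRF): MI-redundancy pruning + accuracy-weighted voting.

The procedure, applied to a trained bootstrap forest and a held-out
validation set:

1. Predict the validation set with every tree.
2. Estimate the pairwise mutual information between tree output vectors
   (redundancy) and between each tree and the true labels (informativeness).
3. Greedily group trees whose MI with a group seed exceeds a threshold
   epsilon: scanning in tree-index order, the first ungrouped tree seeds a
   group and absorbs every still-ungrouped tree whose MI with it is
   strictly greater than epsilon; trees exceeding epsilon with no seed end
   up as singletons.
4. Keep, per group, the tree with the highest tree-truth MI (ties go to
   the smallest tree index) — the pruned forest R'.
5. Score each kept tree's per-class validation recall into an accuracy
   matrix A (rows = classes, columns = kept trees) and use it directly as
   the voting weight matrix Q = A.
6. Classify a probe by weighted voting: each tree's vote for class g is
   worth q_gc; the class with the highest total wins.

Epsilon is not fixed by the procedure itself; the default here is the 75th
percentile of the off-diagonal pairwise MI, adaptive to the ensemble's
entropy scale, with an absolute override.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .forest import Forest, train_forest
from .info_theory import TreeOutputs, tree_mi_matrix, tree_truth_mi
from .panel import LabeledPanel

__all__ = [
    "TreeGrouping",
    "IRFModel",
    "group_trees",
    "select_representatives",
    "accuracy_matrix",
    "weight_matrix",
    "weighted_vote",
    "fit_irf",
]

logger = logging.getLogger(__name__)


@dataclass
class TreeGrouping:
    """Partition of tree indices into redundancy groups."""

    groups: list[list[int]]
    epsilon: float

    def __post_init__(self) -> None:
        flat = [i for g in self.groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("groups must be disjoint")
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("groups must be nonempty")

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class IRFModel:
    """Pruned forest + per-class weight matrix; the deployable classifier."""

    pruned_forest: Forest
    weight_matrix: np.ndarray  # Q, shape (G, C')
    accuracy_matrix: np.ndarray  # A, shape (G, C')
    class_names: list[str]
    epsilon: float
    fit_report: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-vote predictions for a probe matrix."""
        X = np.asarray(X, dtype=float)
        votes = self.pruned_forest.predict_matrix(X)  # (C', n)
        G = self.n_classes
        out = np.empty(votes.shape[1], dtype=np.int64)
        fell_back = False
        for j in range(votes.shape[1]):
            v = votes[:, j]
            scores = np.array([self.weight_matrix[g, v == g].sum() for g in range(G)])
            if np.all(scores == 0.0):
                fell_back = True
                counts = np.bincount(v, minlength=G)
                out[j] = np.argmax(counts)
            else:
                out[j] = np.argmax(scores)  # first max -> smallest class code
        if fell_back:
            warnings.warn(
                "all weighted-vote scores were zero for some probes; "
                "fell back to unweighted majority",
                stacklevel=2,
            )
        return out

    def predict_one(self, x: Sequence[float]) -> int:
        return int(self.predict(np.asarray(x, dtype=float)[None, :])[0])

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "miforest-irf-model",
            "version": 1,
            "class_names": list(self.class_names),
            "feature_names": list(self.pruned_forest.feature_names),
            "epsilon": float(self.epsilon),
            "seed": int(self.pruned_forest.seed),
            "bootstrap_n": int(self.pruned_forest.bootstrap_n),
            "d": int(self.pruned_forest.d),
            "weight_matrix": [[float(v) for v in row] for row in self.weight_matrix],
            "accuracy_matrix": [[float(v) for v in row] for row in self.accuracy_matrix],
            "fit_report": self.fit_report,
            "trees": [t.to_dict() for t in self.pruned_forest.trees],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "IRFModel":
        from .cart_tree import DecisionTree

        trees = [DecisionTree.from_dict(t) for t in data["trees"]]
        forest = Forest(
            trees=trees,
            bootstrap_n=int(data["bootstrap_n"]),
            d=int(data["d"]),
            seed=int(data["seed"]),
            class_names=list(data["class_names"]),
            feature_names=list(data["feature_names"]),
        )
        return cls(
            pruned_forest=forest,
            weight_matrix=np.asarray(data["weight_matrix"], dtype=float),
            accuracy_matrix=np.asarray(data["accuracy_matrix"], dtype=float),
            class_names=list(data["class_names"]),
            epsilon=float(data["epsilon"]),
            fit_report=dict(data.get("fit_report", {})),
        )

    @classmethod
    def from_json(cls, path) -> "IRFModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# the pruning pipeline
# ---------------------------------------------------------------------------

def group_trees(mi_matrix: np.ndarray, epsilon: float) -> TreeGrouping:
    """Greedy sequential redundancy grouping.

    Scanning trees in index order, the first ungrouped tree seeds a group
    and absorbs every still-ungrouped tree whose MI with the seed is
    strictly greater than ``epsilon``.  Absorption is tested against the
    seed only.  A tree exceeding epsilon with no seed becomes a singleton.
    """
    M = np.asarray(mi_matrix, dtype=float)
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("MI matrix must be square")
    T = M.shape[0]
    grouped = np.zeros(T, dtype=bool)
    groups: list[list[int]] = []
    for i in range(T):
        if grouped[i]:
            continue
        members = [i]
        grouped[i] = True
        for c in range(T):
            if not grouped[c] and M[i, c] > epsilon:
                members.append(c)
                grouped[c] = True
        groups.append(sorted(members))
    return TreeGrouping(groups, float(epsilon))


def select_representatives(grouping: TreeGrouping, truth_mi: np.ndarray) -> list[int]:
    """Keep, per group, the tree with maximal tree-truth MI.

    Within-group ties keep the smallest tree index; the kept list is
    sorted ascending.
    """
    truth_mi = np.asarray(truth_mi, dtype=float)
    n_trees = sum(len(g) for g in grouping.groups)
    if truth_mi.size < n_trees:
        raise ValueError("truth_mi must cover every tree")
    kept = []
    for g in grouping.groups:
        idx = np.asarray(g)
        kept.append(int(idx[np.argmax(truth_mi[idx])]))  # first max -> smallest index
    return sorted(kept)


def accuracy_matrix(pruned: Forest, validation: LabeledPanel) -> np.ndarray:
    """Per-class validation recall of every kept tree.

    ``A[g, c]`` = fraction of validation samples of true class g that tree
    c predicts as g.  A class absent from the validation set yields a zero
    row and a logged warning.
    """
    if validation.n_samples == 0:
        raise ValueError("validation panel is empty")
    votes = pruned.predict_matrix(validation.features)  # (C', L)
    G = pruned.n_classes
    A = np.zeros((G, pruned.n_trees))
    for g in range(G):
        in_class = validation.labels == g
        n_g = int(in_class.sum())
        if n_g == 0:
            logger.warning(
                "validation set has no samples of class %r; its accuracy row is 0",
                pruned.class_names[g],
            )
            continue
        A[g] = (votes[:, in_class] == g).sum(axis=1) / n_g
    return A


def weight_matrix(A: np.ndarray) -> np.ndarray:
    """Voting weights from the accuracy matrix: Q = A entrywise.

    Kept as a separate step so alternative accuracy-to-weight mappings
    remain pluggable.
    """
    A = np.asarray(A, dtype=float)
    if A.size and (A.min() < 0 or A.max() > 1):
        raise ValueError("accuracy entries must lie in [0, 1]")
    return A.copy()


def weighted_vote(model: IRFModel, x: Sequence[float]) -> int:
    """Single-probe weighted vote; see :meth:`IRFModel.predict`."""
    return model.predict_one(x)


def fit_irf(
    train: LabeledPanel,
    validation: LabeledPanel,
    n_trees: int = 100,
    n: Optional[int] = None,
    d: Optional[int] = None,
    epsilon: Optional[float] = None,
    seed: int = 0,
    *,
    epsilon_quantile: float = 0.75,
    forest: Optional[Forest] = None,
    min_samples_split: int = 2,
    max_depth: Optional[int] = None,
) -> IRFModel:
    """Full IRF pipeline: forest -> MI pruning -> accuracy-weighted voting.

    Parameters
    ----------
    train, validation : LabeledPanel
        Must share feature space and class vocabulary.  The validation set
        drives both the redundancy estimates and the voting weights.
    epsilon : float, optional
        Absolute MI threshold in bits.  When None, the
        ``epsilon_quantile`` quantile (default 0.75) of the off-diagonal
        pairwise MI is used.
    forest : Forest, optional
        A pre-trained forest to prune (for experiments injecting
        duplicated trees); when given, ``n_trees``/``n``/``d``/``seed``
        are ignored for training.
    """
    if validation.n_samples == 0:
        raise ValueError("validation panel is empty")
    if train.feature_names != validation.feature_names:
        raise ValueError("train and validation panels must share the feature space")
    if train.class_names != validation.class_names:
        raise ValueError("train and validation panels must share the class vocabulary")
    if np.unique(train.labels).size < 2:
        raise ValueError("training panel must contain at least two classes")

    if forest is None:
        forest = train_forest(
            train,
            n_trees=n_trees,
            n=n,
            d=d,
            seed=seed,
            min_samples_split=min_samples_split,
            max_depth=max_depth,
        )
    outputs = TreeOutputs(forest.predict_matrix(validation.features), validation.labels)
    M = tree_mi_matrix(outputs)
    if epsilon is None:
        off_diag = M[~np.eye(M.shape[0], dtype=bool)]
        epsilon = float(np.quantile(off_diag, epsilon_quantile))
    grouping = group_trees(M, epsilon)
    truth = tree_truth_mi(outputs)
    kept = select_representatives(grouping, truth)
    logger.info(
        "IRF pruning: epsilon=%.4f bits, %d trees -> %d groups, kept %s",
        epsilon,
        forest.n_trees,
        grouping.n_groups,
        kept,
    )
    pruned = Forest(
        trees=[forest.trees[i] for i in kept],
        bootstrap_n=forest.bootstrap_n,
        d=forest.d,
        seed=forest.seed,
        class_names=list(forest.class_names),
        feature_names=list(forest.feature_names),
    )
    A = accuracy_matrix(pruned, validation)
    Q = weight_matrix(A)
    report = {
        "n_trees": forest.n_trees,
        "epsilon": float(epsilon),
        "group_sizes": [len(g) for g in grouping.groups],
        "groups": [list(map(int, g)) for g in grouping.groups],
        "kept_indices": [int(i) for i in kept],
        "validation_size": int(validation.n_samples),
    }
    return IRFModel(pruned, Q, A, list(forest.class_names), float(epsilon), report)
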
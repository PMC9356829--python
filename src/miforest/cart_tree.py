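"""Single CART classification trees with Gini-index split selection.

Trees are grown greedily: at every internal node a random subset of ``d``
features is drawn, every (feature, threshold) pair over that subset is
scored by the size-weighted Gini impurity of the induced binary partition,
and the argmin is taken.  Thresholds are midpoints between consecutive
distinct sorted values; a sample goes left when ``value <= threshold``.

Tie-breaking is fully deterministic: among equal-Gini splits the smallest
feature index wins, then the smallest threshold; leaf majority ties go to
the smallest class code.  Same seed + same data therefore reproduces a
bit-identical tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .panel import LabeledPanel

__all__ = [
    "SplitRule",
    "Leaf",
    "InternalNode",
    "DecisionTree",
    "gini_value",
    "gini_index",
    "best_split",
    "grow_tree",
    "predict_tree",
]


@dataclass(frozen=True)
class SplitRule:
    """Axis-aligned binary test: left = (value <= threshold)."""

    feature_index: int
    threshold: float


@dataclass
class Leaf:
    label: int
    histogram: np.ndarray  # training-class counts at this leaf


@dataclass
class InternalNode:
    rule: SplitRule
    left: "Node"
    right: "Node"


Node = Union[Leaf, InternalNode]


@dataclass
class DecisionTree:
    """Binary CART tree over a fixed feature space."""

    root: Node
    n_features: int
    n_classes: int
    d_used: int
    seed: Optional[int] = None

    def predict_one(self, x: np.ndarray) -> int:
        return predict_tree(self, x)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError("probe matrix width must match the training feature count")
        out = np.empty(X.shape[0], dtype=np.int64)
        for i in range(X.shape[0]):
            node = self.root
            row = X[i]
            while isinstance(node, InternalNode):
                r = node.rule
                node = node.left if row[r.feature_index] <= r.threshold else node.right
            out[i] = node.label
        return out

    def n_leaves(self) -> int:
        def count(node: Node) -> int:
            if isinstance(node, Leaf):
                return 1
            return count(node.left) + count(node.right)

        return count(self.root)

    def to_dict(self) -> dict:
        def encode(node: Node) -> dict:
            if isinstance(node, Leaf):
                return {"label": int(node.label), "histogram": [int(c) for c in node.histogram]}
            return {
                "feature": int(node.rule.feature_index),
                "threshold": float(node.rule.threshold),
                "left": encode(node.left),
                "right": encode(node.right),
            }

        return {
            "root": encode(self.root),
            "n_features": self.n_features,
            "n_classes": self.n_classes,
            "d_used": self.d_used,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DecisionTree":
        def decode(obj: dict) -> Node:
            if "label" in obj:
                return Leaf(int(obj["label"]), np.asarray(obj["histogram"], dtype=np.int64))
            return InternalNode(
                SplitRule(int(obj["feature"]), float(obj["threshold"])),
                decode(obj["left"]),
                decode(obj["right"]),
            )

        return cls(
            root=decode(data["root"]),
            n_features=int(data["n_features"]),
            n_classes=int(data["n_classes"]),
            d_used=int(data["d_used"]),
            seed=data.get("seed"),
        )


# ---------------------------------------------------------------------------
# impurity
# ---------------------------------------------------------------------------

def gini_value(labels: Sequence[int]) -> float:
    """Gini impurity ``1 - sum_i s_i**2`` of a label multiset.

    ``s_i`` is the empirical proportion of class i.  0 for a pure node;
    at most ``1 - 1/k`` for k observed classes.
    """
    y = np.asarray(labels, dtype=np.int64)
    if y.size == 0:
        raise ValueError("gini_value of an empty label vector is undefined")
    counts = np.bincount(y)
    s = counts / y.size
    return float(1.0 - np.sum(s * s))


def gini_index(labels: Sequence[int], partition_mask: Sequence[bool]) -> float:
    """Size-weighted Gini impurity of a binary partition.

    ``(|V1|/|V|) Gini(V1) + (|V2|/|V|) Gini(V2)`` where V1 is the masked-in
    side.  Both sides must be nonempty.
    """
    y = np.asarray(labels, dtype=np.int64)
    mask = np.asarray(partition_mask, dtype=bool)
    if mask.shape != y.shape:
        raise ValueError("partition mask length must equal labels length")
    n1 = int(mask.sum())
    if n1 == 0 or n1 == y.size:
        raise ValueError("partition must be two-sided")
    w1 = n1 / y.size
    return float(w1 * gini_value(y[mask]) + (1.0 - w1) * gini_value(y[~mask]))


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def best_split(
    panel: LabeledPanel,
    row_subset: Optional[np.ndarray] = None,
    candidate_features: Optional[Sequence[int]] = None,
) -> Optional[SplitRule]:
    """Exhaustive argmin-Gini split over the candidate features.

    Scores every (feature, threshold) pair, thresholds being midpoints of
    consecutive sorted distinct values.  Returns ``None`` when the node is
    pure or no feature admits a non-degenerate split.
    """
    rows = np.arange(panel.n_samples) if row_subset is None else np.asarray(row_subset)
    if rows.size == 0:
        raise ValueError("row subset is empty")
    feats = (
        range(panel.n_features)
        if candidate_features is None
        else sorted(int(f) for f in candidate_features)
    )
    y = panel.labels[rows]
    m = y.size
    k = panel.n_classes
    if np.all(y == y[0]):
        return None  # pure node: caller stops here

    best_rule: Optional[SplitRule] = None
    best_score = np.inf
    onehot = np.zeros((m, k), dtype=np.int64)
    for f in feats:
        if not 0 <= f < panel.n_features:
            raise ValueError(f"candidate feature {f} outside [0, {panel.n_features})")
        x = panel.features[rows, f]
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        cut = np.flatnonzero(xs[:-1] < xs[1:])  # left block = [0..c]
        if cut.size == 0:
            continue
        onehot[:] = 0
        onehot[np.arange(m), y[order]] = 1
        csum = np.cumsum(onehot, axis=0)
        total = csum[-1]
        c_left = csum[cut]
        c_right = total[None, :] - c_left
        m_left = cut + 1
        m_right = m - m_left
        ss_left = np.einsum("ij,ij->i", c_left, c_left)
        ss_right = np.einsum("ij,ij->i", c_right, c_right)
        # weighted Gini: [ (m_L - ssL/m_L) + (m_R - ssR/m_R) ] / m
        score = (m_left - ss_left / m_left + m_right - ss_right / m_right) / m
        j = int(np.argmin(score))  # first minimum -> smallest threshold
        if score[j] < best_score:  # strict: earlier feature wins ties
            best_score = float(score[j])
            best_rule = SplitRule(f, float((xs[cut[j]] + xs[cut[j] + 1]) / 2.0))
    return best_rule


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _majority(y: np.ndarray, k: int) -> tuple[int, np.ndarray]:
    hist = np.bincount(y, minlength=k)
    return int(np.argmax(hist)), hist  # argmax takes the smallest code on ties


def grow_tree(
    panel: LabeledPanel,
    row_subset: Optional[np.ndarray] = None,
    d: Optional[int] = None,
    *,
    min_samples_split: int = 2,
    max_depth: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> DecisionTree:
    """Grow a CART tree on ``row_subset`` of the panel.

    At each internal node ``d`` features are drawn without replacement
    (default ``ceil(sqrt(D))``).  Growth stops at purity, ``min_samples_split``,
    ``max_depth``, or when no candidate feature admits a split; leaves
    predict the majority class of their rows.
    """
    rows = np.arange(panel.n_samples) if row_subset is None else np.asarray(row_subset)
    if rows.size == 0:
        raise ValueError("cannot grow a tree on an empty row subset")
    D = panel.n_features
    if d is None:
        d = int(np.ceil(np.sqrt(D)))
    if not 1 <= d <= D:
        raise ValueError(f"d must lie in [1, {D}]")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = panel.n_classes

    def build(node_rows: np.ndarray, depth: int) -> Node:
        y = panel.labels[node_rows]
        label, hist = _majority(y, k)
        if (
            np.all(y == y[0])
            or node_rows.size < min_samples_split
            or (max_depth is not None and depth >= max_depth)
        ):
            return Leaf(label, hist)
        feats = np.sort(rng.choice(D, size=d, replace=False))
        rule = best_split(panel, node_rows, feats)
        if rule is None:
            return Leaf(label, hist)
        go_left = panel.features[node_rows, rule.feature_index] <= rule.threshold
        return InternalNode(
            rule, build(node_rows[go_left], depth + 1), build(node_rows[~go_left], depth + 1)
        )

    return DecisionTree(build(rows, 0), D, k, d, seed)


def predict_tree(tree: DecisionTree, x: Sequence[float]) -> int:
    """Deterministic root-to-leaf descent for a single probe vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.n_features,):
        raise ValueError("probe length must match the training feature count")
    node = tree.root
    while isinstance(node, InternalNode):
        r = node.rule
        node = node.left if x[r.feature_index] <= r.threshold else node.right
    return int(node.label)
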
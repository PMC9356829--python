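"""Labeled sensor-panel container.

A :class:`LabeledPanel` is the universal dataset object of the package: a
numeric feature matrix (rows = samples, columns = sensor or physicochemical
indices) with one integer class label per row, plus the class and feature
vocabularies.  Panels move between modules in memory and are serialized as
plain CSV with a ``label`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledPanel"]


@dataclass
class LabeledPanel:
    """Numeric feature matrix with integer class labels.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Unitless sensor readings; no missing values allowed.
    labels : ndarray of shape (n_samples,)
        Integer class codes in ``{0 .. n_classes-1}``.
    class_names : list of str
        Ordered class vocabulary; ``labels`` index into it.
    feature_names : list of str
        Ordered column names, one per feature.
    """

    features: np.ndarray
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        n, d = self.features.shape
        if n < 1:
            raise ValueError("panel must contain at least one sample")
        if len(self.labels) != n:
            raise ValueError("labels length must equal the number of rows")
        if np.any(~np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative class codes")
        if not self.class_names:
            self.class_names = [f"class_{g}" for g in range(int(self.labels.max()) + 1)]
        if self.labels.max() >= len(self.class_names):
            raise ValueError("every label must index into class_names")
        if not self.feature_names:
            self.feature_names = [f"sensor_{j}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal the number of columns")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    # -- subsetting ------------------------------------------------------
    def subset(self, rows: np.ndarray) -> "LabeledPanel":
        """Panel restricted to ``rows`` (keeps the full class vocabulary)."""
        rows = np.asarray(rows)
        return LabeledPanel(
            self.features[rows],
            self.labels[rows],
            list(self.class_names),
            list(self.feature_names),
        )

    def stratified_split(
        self, frac: float, rng: np.random.Generator
    ) -> tuple["LabeledPanel", "LabeledPanel"]:
        """Split into two panels with per-class proportions ``frac`` / ``1-frac``.

        The first returned panel receives ``round(frac * n_g)`` samples of
        each class g (at least one where the class has >= 2 samples, so both
        sides stay usable).
        """
        if not 0.0 < frac < 1.0:
            raise ValueError("frac must lie strictly between 0 and 1")
        first: list[np.ndarray] = []
        second: list[np.ndarray] = []
        for g in range(self.n_classes):
            idx = np.flatnonzero(self.labels == g)
            if idx.size == 0:
                continue
            idx = idx[rng.permutation(idx.size)]
            n_first = int(round(frac * idx.size))
            if idx.size >= 2:
                n_first = min(max(n_first, 1), idx.size - 1)
            first.append(idx[:n_first])
            second.append(idx[n_first:])
        a = np.sort(np.concatenate(first))
        b = np.sort(np.concatenate(second))
        return self.subset(a), self.subset(b)

    # -- I/O --------------------------------------------------------------
    def to_dataframe(self, label_col: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_col] = [self.class_names[g] for g in self.labels]
        return df

    def to_csv(self, path, label_col: str = "label") -> None:
        self.to_dataframe(label_col).to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        class_names: list[str] | None = None,
    ) -> "LabeledPanel":
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not found in table")
        if len(df) == 0:
            raise ValueError("table contains no rows")
        raw = df[label_col]
        feature_names = [c for c in df.columns if c != label_col]
        features = df[feature_names].to_numpy(dtype=float)
        if class_names is None:
            # preserve a stable, human-meaningful order: sorted unique names
            class_names = sorted(str(v) for v in pd.unique(raw))
        index = {name: g for g, name in enumerate(class_names)}
        try:
            labels = np.array([index[str(v)] for v in raw], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"label {exc} not in class vocabulary") from exc
        return cls(features, labels, list(class_names), feature_names)

    @classmethod
    def read_csv(
        cls, path, label_col: str = "label", class_names: list[str] | None = None
    ) -> "LabeledPanel":
        return cls.from_dataframe(pd.read_csv(path), label_col, class_names)
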
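"""High-level modelling interface: ``ImprovedRandomForest`` -> ``IRFResults``.

The model object is built from data (a :class:`~miforest.panel.LabeledPanel`
or a DataFrame via :meth:`ImprovedRandomForest.from_dataframe`) together
with the hyperparameters; ``fit()`` runs the full pipeline — bootstrap
forest, MI-redundancy pruning, accuracy-weighted voting — and returns a
results object carrying the fitted classifier, the pruning diagnostics and
a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .irf_ensemble import IRFModel, fit_irf
from .panel import LabeledPanel

__all__ = ["ImprovedRandomForest", "IRFResults"]


class ImprovedRandomForest:
    """Mutual-information-pruned, accuracy-weighted random forest.

    Parameters
    ----------
    panel : LabeledPanel
        Training data.  When ``validation`` is not supplied, a stratified
        ``1 - val_frac`` / ``val_frac`` split of this panel provides the
        internal validation set that drives pruning and voting weights.
    n_trees : int
        Size of the initial bootstrap forest.
    bootstrap_frac : float
        Bootstrap draw size as a fraction of the training size (1.0 = the
        mainstream convention n = N).
    d : int, optional
        Features drawn per node; default ``ceil(sqrt(D))``.
    epsilon : float, optional
        Absolute MI redundancy threshold in bits; default adapts to the
        ensemble via ``epsilon_quantile``.
    epsilon_quantile : float
        Quantile of off-diagonal pairwise MI used when ``epsilon`` is None.
    val_frac : float
        Fraction of the panel held out for validation when no explicit
        validation panel is given.
    seed : int
        Drives every random draw (split, bootstraps, feature subsets).
    """

    def __init__(
        self,
        panel: LabeledPanel,
        validation: Optional[LabeledPanel] = None,
        *,
        n_trees: int = 100,
        bootstrap_frac: float = 1.0,
        d: Optional[int] = None,
        epsilon: Optional[float] = None,
        epsilon_quantile: float = 0.75,
        val_frac: float = 0.25,
        seed: int = 0,
    ) -> None:
        if not 0.0 < bootstrap_frac <= 1.0:
            raise ValueError("bootstrap_frac must lie in (0, 1]")
        self.panel = panel
        self.validation = validation
        self.n_trees = n_trees
        self.bootstrap_frac = bootstrap_frac
        self.d = d
        self.epsilon = epsilon
        self.epsilon_quantile = epsilon_quantile
        self.val_frac = val_frac
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        validation: Optional[pd.DataFrame] = None,
        **kwargs,
    ) -> "ImprovedRandomForest":
        panel = LabeledPanel.from_dataframe(df, label_col)
        val = None
        if validation is not None:
            val = LabeledPanel.from_dataframe(validation, label_col, panel.class_names)
        return cls(panel, val, **kwargs)

    def fit(self) -> "IRFResults":
        if self.validation is not None:
            train, val = self.panel, self.validation
        else:
            rng = np.random.default_rng([self.seed, 0x5EED])
            train, val = self.panel.stratified_split(1.0 - self.val_frac, rng)
        n = max(1, int(round(self.bootstrap_frac * train.n_samples)))
        irf = fit_irf(
            train,
            val,
            n_trees=self.n_trees,
            n=n,
            d=self.d,
            epsilon=self.epsilon,
            seed=self.seed,
            epsilon_quantile=self.epsilon_quantile,
        )
        return IRFResults(self, irf, train, val)


class IRFResults:
    """Fitted IRF: pruned forest, weight matrix, and pruning diagnostics."""

    def __init__(
        self,
        model: ImprovedRandomForest,
        irf: IRFModel,
        train: LabeledPanel,
        validation: LabeledPanel,
    ) -> None:
        self.model = model
        self.irf = irf
        self.train_panel = train
        self.validation_panel = validation

    # convenient views ---------------------------------------------------
    @property
    def weight_matrix(self) -> np.ndarray:
        return self.irf.weight_matrix

    @property
    def accuracy_matrix(self) -> np.ndarray:
        return self.irf.accuracy_matrix

    @property
    def epsilon(self) -> float:
        return self.irf.epsilon

    @property
    def kept_indices(self) -> list[int]:
        return list(self.irf.fit_report["kept_indices"])

    @property
    def group_sizes(self) -> list[int]:
        return list(self.irf.fit_report["group_sizes"])

    def predict(self, X) -> np.ndarray:
        """Weighted-vote class codes for a probe matrix or DataFrame."""
        if isinstance(X, pd.DataFrame):
            X = X[self.irf.pruned_forest.feature_names].to_numpy(dtype=float)
        return self.irf.predict(np.asarray(X, dtype=float))

    def predict_names(self, X) -> list[str]:
        return [self.irf.class_names[g] for g in self.predict(X)]

    def save(self, path) -> None:
        self.irf.to_json(path)

    def summary(self) -> str:
        """Human-readable fit summary: ensemble census and voting weights."""
        rep = self.irf.fit_report
        G, Ck = self.irf.weight_matrix.shape
        lines = [
            "Improved Random Forest results",
            "=" * 46,
            f"training samples       {self.train_panel.n_samples}",
            f"validation samples     {rep['validation_size']}",
            f"features               {self.train_panel.n_features}",
            f"classes                {G}",
            f"initial trees          {rep['n_trees']}",
            f"epsilon (bits)         {rep['epsilon']:.4f}",
            f"redundancy groups      {len(rep['group_sizes'])}",
            f"trees kept             {Ck}",
            f"group sizes            {rep['group_sizes']}",
            f"kept tree indices      {rep['kept_indices']}",
            "",
            "per-class voting weights Q (rows = classes, cols = kept trees)",
        ]
        names = self.irf.class_names
        width = max(len(n) for n in names) + 2
        for g in range(G):
            row = " ".join(f"{v:5.2f}" for v in self.irf.weight_matrix[g])
            lines.append(f"{names[g]:<{width}}{row}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<IRFResults: {self.irf.pruned_forest.n_trees} trees kept of "
            f"{self.irf.fit_report['n_trees']}, epsilon={self.epsilon:.3f} bits>"
        )
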
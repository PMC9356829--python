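"""Synthetic taste-sensor panels emulating a five-class table-vinegar study.

The built-in :func:`vinegar_spec` reproduces the published per-class
mean +/- SD of five physicochemical indices measured on five kinds of
Chinese table vinegar (white, rice, aged, balsamic, sugar): total soluble
sugar (%), total acid (%), salt (%), sugar-acid ratio (dimensionless;
the quotient of the mean sugar and mean acid), and pH.  The study's sensor
array had eight channels but only these five indices are quantified, so
three extra synthetic sensors with configurable class separation pad the
panel to eight features.

Within a class, features are drawn independently from truncated normals
(concentrations and pH cannot go negative); the published table gives only
marginal mean +/- SD, so no within-class covariance is modelled.  Classes
"aged" and "balsamic" overlap strongly on every printed index — mirroring
the real study, where those two vinegars confuse any classifier — so the
paper-like preset is deliberately not linearly separable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .panel import LabeledPanel

__all__ = [
    "PanelSpec",
    "GeneratedPanel",
    "vinegar_spec",
    "sugar_acid_ratio",
    "generate_panel",
    "separability_preset",
    "VINEGAR_CLASSES",
    "VINEGAR_FEATURES",
]

VINEGAR_CLASSES = [
    "white_vinegar",
    "rice_vinegar",
    "aged_vinegar",
    "balsamic_vinegar",
    "sugar_vinegar",
]
VINEGAR_FEATURES = ["total_sugar", "total_acid", "salt", "sugar_acid_ratio", "pH"]

# Published quantitative indicators (rows = class, columns = index).
# The "1.17 +/- 091" rice-vinegar sugar-acid-ratio cell is read as SD 0.91
# (an obvious misprint of 0.91).
_VINEGAR_MEANS = np.array(
    [
        #  sugar   acid   salt  ratio    pH
        [3.86, 4.82, 0.94, 0.80, 2.53],  # white
        [7.55, 6.46, 1.28, 1.17, 2.49],  # rice
        [14.51, 5.45, 1.82, 2.66, 3.32],  # aged
        [14.64, 5.35, 1.79, 2.74, 3.54],  # balsamic
        [7.17, 4.65, 1.42, 1.54, 3.38],  # sugar
    ]
)
_VINEGAR_SDS = np.array(
    [
        [0.57, 0.62, 0.38, 0.92, 0.86],
        [0.73, 1.03, 0.84, 0.91, 0.40],
        [0.28, 0.53, 0.44, 0.38, 0.64],
        [0.63, 0.55, 0.84, 0.97, 0.63],
        [0.81, 1.02, 0.87, 0.53, 0.62],
    ]
)


@dataclass
class PanelSpec:
    """Class-conditional Gaussian recipe for a synthetic sensor panel.

    ``means`` and ``sds`` are (n_classes, n_base_features); extra sensors
    are appended with class-g mean ``g * extra_scale * extra_sd`` and SD
    ``extra_sd``, so ``extra_scale`` is the between-class separation in SD
    units.  ``lower_bounds`` holds per-base-feature truncation floors
    (None = unbounded).
    """

    class_names: list[str]
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    n_extra_sensors: int = 0
    extra_scale: float = 1.0
    extra_sd: float = 1.0
    lower_bounds: list[Optional[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        G = len(self.class_names)
        if self.means.shape != (G, len(self.feature_names)):
            raise ValueError("means must be (n_classes, n_base_features)")
        if self.sds.shape != self.means.shape:
            raise ValueError("sds must match the shape of means")
        if not np.all(np.isfinite(self.means)):
            raise ValueError("means must be finite")
        if np.any(self.sds <= 0):
            raise ValueError("every SD must be strictly positive")
        if self.n_extra_sensors < 0:
            raise ValueError("n_extra_sensors must be nonnegative")
        if not self.lower_bounds:
            self.lower_bounds = [None] * len(self.feature_names)
        if len(self.lower_bounds) != len(self.feature_names):
            raise ValueError("one lower bound (or None) per base feature")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_features(self) -> int:
        return len(self.feature_names) + self.n_extra_sensors

    def all_feature_names(self) -> list[str]:
        return list(self.feature_names) + [
            f"extra_sensor_{j}" for j in range(self.n_extra_sensors)
        ]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "feature_names": list(self.feature_names),
            "means": [[float(v) for v in row] for row in self.means],
            "sds": [[float(v) for v in row] for row in self.sds],
            "n_extra_sensors": int(self.n_extra_sensors),
            "extra_scale": float(self.extra_scale),
            "extra_sd": float(self.extra_sd),
            "lower_bounds": [None if b is None else float(b) for b in self.lower_bounds],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PanelSpec":
        return cls(
            class_names=list(data["class_names"]),
            feature_names=list(data["feature_names"]),
            means=np.asarray(data["means"], dtype=float),
            sds=np.asarray(data["sds"], dtype=float),
            n_extra_sensors=int(data.get("n_extra_sensors", 0)),
            extra_scale=float(data.get("extra_scale", 1.0)),
            extra_sd=float(data.get("extra_sd", 1.0)),
            lower_bounds=list(data.get("lower_bounds", [])),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PanelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def spec_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GeneratedPanel(LabeledPanel):
    """LabeledPanel plus generation provenance."""

    spec_hash: str = ""
    seed: int = 0
    per_class_counts: list[int] = field(default_factory=list)

    def provenance(self) -> dict:
        return {
            "spec_hash": self.spec_hash,
            "seed": int(self.seed),
            "per_class_counts": [int(c) for c in self.per_class_counts],
        }


def vinegar_spec(n_extra_sensors: int = 3, extra_scale: float = 1.0) -> PanelSpec:
    """Built-in spec reproducing the published five-vinegar panel.

    Five classes x five printed physicochemical indices, padded with
    ``n_extra_sensors`` (default 3, reaching the study's 8 sensors) mildly
    informative synthetic channels.  Concentrations, the ratio and pH are
    truncated at zero.
    """
    return PanelSpec(
        class_names=list(VINEGAR_CLASSES),
        feature_names=list(VINEGAR_FEATURES),
        means=_VINEGAR_MEANS.copy(),
        sds=_VINEGAR_SDS.copy(),
        n_extra_sensors=n_extra_sensors,
        extra_scale=extra_scale,
        extra_sd=1.0,
        lower_bounds=[0.0, 0.0, 0.0, 0.0, 0.0],
    )


def sugar_acid_ratio(mean_sugar: float, mean_acid: float) -> float:
    """Quotient of mean total soluble sugar to mean total acid.

    The published per-class ratio cells equal the quotient of the printed
    sugar and acid means (to 2 decimals), which fixes this reading.
    """
    if mean_acid <= 0:
        raise ValueError("mean total acid must be positive")
    return mean_sugar / mean_acid


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: Optional[float],
    size: int,
    max_tries: int = 1000,
) -> np.ndarray:
    vals = rng.normal(mean, sd, size)
    if lower is None:
        return vals
    bad = vals < lower
    tries = 0
    while bad.any() and tries < max_tries:
        vals[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = vals < lower
        tries += 1
    if bad.any():
        warnings.warn(
            f"truncated-normal rejection exhausted {max_tries} rounds; clamping",
            stacklevel=2,
        )
        vals[bad] = lower
    return vals


def generate_panel(spec: PanelSpec, n_per_class: int, seed: int = 0) -> GeneratedPanel:
    """Draw a balanced labeled panel from a :class:`PanelSpec`.

    Per class g, ``n_per_class`` samples are drawn feature-wise from
    truncated ``Normal(mean_gd, sd_gd)``; extra sensors from
    ``Normal(g * extra_scale * extra_sd, extra_sd)``.  Row order is
    shuffled (seeded).  Deterministic for a fixed (spec, n, seed).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    rng = np.random.default_rng(seed)
    G, D0 = spec.means.shape
    blocks = []
    labels = []
    for g in range(G):
        cols = [
            _truncated_normal(
                rng, spec.means[g, d], spec.sds[g, d], spec.lower_bounds[d], n_per_class
            )
            for d in range(D0)
        ]
        for j in range(spec.n_extra_sensors):
            cols.append(
                rng.normal(g * spec.extra_scale * spec.extra_sd, spec.extra_sd, n_per_class)
            )
        blocks.append(np.column_stack(cols))
        labels.append(np.full(n_per_class, g, dtype=np.int64))
    features = np.vstack(blocks)
    y = np.concatenate(labels)
    perm = rng.permutation(features.shape[0])
    return GeneratedPanel(
        features=features[perm],
        labels=y[perm],
        class_names=list(spec.class_names),
        feature_names=spec.all_feature_names(),
        spec_hash=spec.spec_hash(),
        seed=int(seed),
        per_class_counts=[n_per_class] * G,
    )


def separability_preset(level: str) -> PanelSpec:
    """Canonical difficulty presets for accuracy-floor experiments.

    - ``easy``: 5 classes, 8 features, adjacent class means 6 SD apart on
      every feature — near-zero Bayes error by the Gaussian overlap
      integral, so any competent classifier should approach 100%.
    - ``paper-like``: the vinegar spec; the aged/balsamic pair overlaps
      heavily, so perfect test accuracy should not be expected.
    - ``hard``: 1 SD separation on every feature.
    """
    if level == "paper-like":
        return vinegar_spec()
    if level in ("easy", "hard"):
        sep = 6.0 if level == "easy" else 1.0
        G, D = 5, 8
        means = np.tile(np.arange(G, dtype=float)[:, None] * sep, (1, D))
        sds = np.ones((G, D))
        return PanelSpec(
            class_names=[f"class_{g}" for g in range(G)],
            feature_names=[f"sensor_{j}" for j in range(D)],
            means=means,
            sds=sds,
            n_extra_sensors=0,
            lower_bounds=[None] * D,
        )
    raise ValueError("preset must be one of: easy, paper-like, hard")
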
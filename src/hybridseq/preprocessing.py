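"""Min-max normalization and Fisher linear discriminant projection.

Min-max rescales each feature to [0, 1] using training-set statistics
only; test values outside the training range deliberately map outside
[0, 1] (no clipping), so the scaler never hides train/test covariate
shift.  A constant training feature maps to 0 everywhere.

The discriminant projection maximizes the Fisher criterion: separate the
class means as far as possible while keeping within-class scatter small.
With C classes at most C-1 informative directions exist.  k-mer frequency
tables are collinear (rows sum to one), so the within-class scatter is
ridge-regularized when singular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .kmer_features import FeatureTable

#: ridge added to a singular within-class scatter, as a fraction of trace/d
LDA_RIDGE = 1e-6


@dataclass
class MinMaxState:
    """Per-feature training min/max defining the [0,1] rescaling."""

    feature_names: list[str]
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.minimum > self.maximum):
            raise ValueError("per-feature minimum exceeds maximum")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "minimum": self.minimum.tolist(),
                    "maximum": self.maximum.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MinMaxState":
        d = json.loads(Path(path).read_text())
        return cls(d["feature_names"], np.array(d["minimum"]), np.array(d["maximum"]))


@dataclass
class LdaProjection:
    """Fitted discriminant directions (features × components) and class means."""

    feature_names: list[str]
    directions: np.ndarray
    class_means: np.ndarray
    class_names: list[str]
    n_components: int

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        if not np.all(np.isfinite(self.directions)):
            raise ValueError("projection directions are not finite")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "directions": self.directions.tolist(),
                    "class_means": self.class_means.tolist(),
                    "class_names": self.class_names,
                    "n_components": self.n_components,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LdaProjection":
        d = json.loads(Path(path).read_text())
        return cls(
            d["feature_names"],
            np.array(d["directions"]),
            np.array(d["class_means"]),
            d["class_names"],
            d["n_components"],
        )


def fit_minmax(table: FeatureTable) -> MinMaxState:
    if table.n_samples < 1:
        raise ValueError("cannot fit min-max on an empty table")
    return MinMaxState(
        feature_names=list(table.feature_names),
        minimum=table.values.min(axis=0),
        maximum=table.values.max(axis=0),
    )


def apply_minmax(state: MinMaxState, table: FeatureTable) -> FeatureTable:
    """(x - x_min) / (x_max - x_min), unclipped; constant features map to 0."""
    if list(table.feature_names) != state.feature_names:
        raise ValueError("feature names do not match the fitted min-max state")
    span = state.maximum - state.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = (table.values - state.minimum) / safe
    scaled[:, span == 0] = 0.0
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_names=list(table.feature_names),
        values=scaled,
        labels=None if table.labels is None else list(table.labels),
    )


def fit_lda(
    table: FeatureTable,
    labels: Sequence[str] | None = None,
    n_components: int | None = None,
) -> LdaProjection:
    """Fisher discriminant directions from labelled training rows.

    Solves the generalized eigenproblem S_b v = λ S_w v; for two classes
    the single direction is parallel to S_w^{-1}(μ₁ − μ₂).  Directions are
    made deterministic by forcing the first nonzero coefficient positive.
    """
    y = list(labels) if labels is not None else table.labels
    if y is None:
        raise ValueError("labels are required to fit the discriminant projection")
    if len(y) != table.n_samples:
        raise ValueError("label count does not match sample count")
    classes = sorted(set(map(str, y)))
    if len(classes) < 2:
        raise ValueError("at least two classes are required")
    max_comp = len(classes) - 1
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for {len(classes)} classes"
        )

    X = table.values
    y_arr = np.array(list(map(str, y)))
    d = X.shape[1]
    overall = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    means = []
    for c in classes:
        Xc = X[y_arr == c]
        mu = Xc.mean(axis=0)
        means.append(mu)
        centered = Xc - mu
        Sw += centered.T @ centered
        diff = (mu - overall)[:, None]
        Sb += len(Xc) * (diff @ diff.T)

    if np.linalg.matrix_rank(Sw) < d:
        Sw = Sw + (LDA_RIDGE * np.trace(Sw) / d + 1e-12) * np.eye(d)

    eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(eigvals)[::-1][:n_components]
    W = eigvecs[:, order]
    for j in range(W.shape[1]):
        nz = np.flatnonzero(np.abs(W[:, j]) > 1e-12)
        if nz.size and W[nz[0], j] < 0:
            W[:, j] = -W[:, j]

    return LdaProjection(
        feature_names=list(table.feature_names),
        directions=W,
        class_means=np.vstack(means),
        class_names=classes,
        n_components=n_components,
    )


def apply_lda(projection: LdaProjection, table: FeatureTable) -> FeatureTable:
    if list(table.feature_names) != projection.feature_names:
        raise ValueError("feature names do not match the fitted projection")
    projected = table.values @ projection.directions
    names = [f"ld{i + 1}" for i in range(projection.n_components)]
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_names=names,
        values=projected,
        labels=None if table.labels is None else list(table.labels),
    )
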
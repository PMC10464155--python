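"""Bayesian hyperparameter optimization of the base learners.

The objective is mean 5-fold cross-validated accuracy.  A Gaussian
process (Matérn 5/2) surrogate is fitted to the evaluations made so far,
and the next configuration is chosen by maximizing expected improvement
over a seeded random candidate pool — the standard
exploration/exploitation balance: candidates with high predicted mean
are exploited, candidates with high predictive uncertainty explored.
The first ``n_initial`` evaluations are space-filling random draws.
Every source of randomness derives from the single ``seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .hybrid_model import BaseLearnerSpec, _default_estimator


@dataclass(frozen=True)
class Dimension:
    """One hyperparameter domain: real/log-real/integer interval or categorical."""

    name: str
    kind: str  # "real" | "log-real" | "integer" | "categorical"
    low: float | None = None
    high: float | None = None
    categories: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind in ("real", "log-real", "integer"):
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"{self.name}: bounds must satisfy low < high")
            if self.kind == "log-real" and self.low <= 0:
                raise ValueError(f"{self.name}: log domain requires low > 0")
        elif self.kind == "categorical":
            if not self.categories:
                raise ValueError(f"{self.name}: categories must be non-empty")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def decode(self, unit: float):
        """Map a [0,1] coordinate to a parameter value."""
        if self.kind == "real":
            return self.low + unit * (self.high - self.low)
        if self.kind == "log-real":
            return float(
                np.exp(np.log(self.low) + unit * (np.log(self.high) - np.log(self.low)))
            )
        if self.kind == "integer":
            return int(round(self.low + unit * (self.high - self.low)))
        idx = min(int(unit * len(self.categories)), len(self.categories) - 1)
        return self.categories[idx]


@dataclass
class SearchSpace:
    dimensions: list[Dimension]

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("search space must contain at least one dimension")

    def decode(self, unit_point: np.ndarray) -> dict:
        return {
            d.name: d.decode(float(u)) for d, u in zip(self.dimensions, unit_point)
        }

    @property
    def n_dims(self) -> int:
        return len(self.dimensions)


def default_space(learner: str) -> SearchSpace:
    """Per-learner default domains (overridable)."""
    spaces = {
        "SVM": [
            Dimension("C", "log-real", 1e-2, 1e2),
            Dimension("kernel", "categorical", categories=("rbf", "linear")),
        ],
        "RF": [Dimension("n_estimators", "integer", 50, 300)],
        "KNN": [Dimension("n_neighbors", "integer", 1, 15)],
        "LR": [Dimension("C", "log-real", 1e-2, 1e2)],
        "MLP": [Dimension("hidden_layer_sizes", "integer", 8, 128)],
    }
    if learner not in spaces:
        raise ValueError(f"no default search space for learner {learner!r}")
    return SearchSpace(spaces[learner])


@dataclass
class TuningResult:
    best_params: dict
    best_value: float
    history: list[tuple[dict, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "best_params": _jsonable(self.best_params),
                    "best_value": self.best_value,
                    "history": [
                        {"params": _jsonable(p), "score": s} for p, s in self.history
                    ],
                },
                indent=2,
            )
        )


def _jsonable(params: Mapping) -> dict:
    return {
        k: (v if isinstance(v, (int, float, str, bool)) else str(v))
        for k, v in params.items()
    }


def _expected_improvement(
    gp: GaussianProcessRegressor, candidates: np.ndarray, best: float
) -> np.ndarray:
    mu, sigma = gp.predict(candidates, return_std=True)
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def _cv_accuracy(
    learner_name: str,
    params: Mapping[str, object],
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
) -> float:
    params = dict(params)
    if learner_name == "MLP" and isinstance(params.get("hidden_layer_sizes"), int):
        params["hidden_layer_sizes"] = (params["hidden_layer_sizes"],)
    if learner_name == "KNN":
        # k must fit inside the smallest training fold
        params["n_neighbors"] = max(
            1, min(int(params.get("n_neighbors", 5)), len(y) - len(y) // 5)
        )
    est = _default_estimator(learner_name, seed, params)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def bayes_optimize(
    learner: str | BaseLearnerSpec,
    features: np.ndarray,
    labels: Sequence,
    space: SearchSpace | None = None,
    budget: int = 25,
    seed: int = 0,
    n_initial: int = 5,
    objective: Callable[[dict], float] | None = None,
    n_candidates: int = 256,
) -> TuningResult:
    """Sequential surrogate-guided maximization of CV accuracy.

    ``objective`` may replace the CV-accuracy objective (it receives the
    decoded parameter dict), which is convenient for testing the
    optimizer against analytic functions.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    name = learner.name if isinstance(learner, BaseLearnerSpec) else learner
    if space is None:
        space = default_space(name)
    rng = np.random.default_rng(seed)
    X = np.asarray(features, dtype=float) if features is not None else None
    y = np.asarray(labels) if labels is not None else None

    def evaluate(point: np.ndarray) -> tuple[dict, float]:
        params = space.decode(point)
        if objective is not None:
            return params, float(objective(params))
        return params, _cv_accuracy(name, params, X, y, seed)

    unit_points: list[np.ndarray] = []
    history: list[tuple[dict, float]] = []
    values: list[float] = []
    n_initial = min(n_initial, budget)
    for _ in range(n_initial):
        unit_points.append(rng.random(space.n_dims))
        params, score = evaluate(unit_points[-1])
        history.append((params, score))
        values.append(score)

    kernel = Matern(nu=2.5, length_scale=np.ones(space.n_dims)) + WhiteKernel(1e-6)
    for _ in range(budget - n_initial):
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=seed, alpha=1e-10
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.vstack(unit_points), np.asarray(values))
        candidates = rng.random((n_candidates, space.n_dims))
        ei = _expected_improvement(gp, candidates, max(values))
        unit_points.append(candidates[int(np.argmax(ei))])
        params, score = evaluate(unit_points[-1])
        history.append((params, score))
        values.append(score)

    best_idx = int(np.argmax(values))
    return TuningResult(
        best_params=history[best_idx][0],
        best_value=values[best_idx],
        history=history,
    )
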
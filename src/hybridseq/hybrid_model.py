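"""Five-phase hybrid classifier with cluster-routed ensembles.

The model augments the training labels with latent structure discovered
in class-probability space, then trains a local ensemble per discovered
cluster:

1. features are k-mer frequencies, min-max scaled and optionally
   projected onto Fisher discriminant axes;
2. a logistic regression scores every training sample with a
   class-probability vector;
3. K-means clusters those probability vectors, choosing the cluster
   count by silhouette over a configurable range — the clusters capture
   latent subgroups within classes (e.g. disease subsets that co-occur
   with different conditions);
4. each training sample receives a composite label (original class,
   cluster id) and a support-vector machine is fitted on the composite
   labels; at test time this bridge simultaneously predicts a class and
   routes the sample to a cluster;
5. per cluster, the configured combination of base learners (SVM, RF,
   LR, KNN, MLP) is fitted on that cluster's rows; a routed test sample
   is classified by the soft vote (mean class-probability vector) of its
   cluster's ensemble.

With a single cluster the whole construction collapses exactly to a
plain soft-voting ensemble of the same combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .io_sequences import LabeledDataset
from .kmer_features import FeatureTable, featurize_dataset
from .preprocessing import (
    LdaProjection,
    MinMaxState,
    apply_lda,
    apply_minmax,
    fit_lda,
    fit_minmax,
)

LEARNER_NAMES = ("SVM", "RF", "LR", "KNN", "MLP")


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A named base learner with hyperparameter overrides and a seed."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise ValueError(
                f"unknown learner {self.name!r}; expected one of {LEARNER_NAMES}"
            )


@dataclass(frozen=True)
class KmerConfig:
    k: int = 3
    mode: str = "frequency"
    canonical: bool = False


@dataclass(frozen=True)
class PreprocessConfig:
    minmax: bool = True
    lda: bool = True
    n_components: int | None = None  # None -> classes - 1
    order: Literal["minmax_first", "lda_first"] = "minmax_first"


@dataclass(frozen=True)
class HybridConfig:
    """Structural knobs of phases 2–5."""

    cluster_range: tuple[int, int] = (2, 8)
    combination: tuple[str, ...] = ("RF", "LR", "KNN", "MLP")
    min_cluster_size: int = 5
    probability_source: Literal["in_sample", "out_of_fold"] = "in_sample"
    probability_regularization: float = 0.01
    voting: Literal["soft", "hard"] = "soft"
    seed: int = 0
    learner_overrides: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.cluster_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid cluster_range {self.cluster_range}")
        if not self.combination:
            raise ValueError("ensemble combination must be non-empty")
        for name in self.combination:
            if name not in LEARNER_NAMES:
                raise ValueError(f"unknown learner {name!r} in combination")


class ConstantClassifier(BaseEstimator, ClassifierMixin):
    """Predicts a single class with probability one (degenerate clusters)."""

    def __init__(self, constant: object = None):
        self.constant = constant

    def fit(self, X, y=None):
        if self.constant is None:
            values, counts = np.unique(np.asarray(y), return_counts=True)
            self.constant = values[np.argmax(counts)]
        self.classes_ = np.array([self.constant])
        return self

    def predict(self, X):
        return np.full(len(X), self.constant)

    def predict_proba(self, X):
        return np.ones((len(X), 1))


def _default_estimator(name: str, seed: int, params: Mapping[str, object]):
    params = dict(params)
    if name == "SVM":
        base = dict(C=1.0, kernel="rbf", gamma="scale", probability=True,
                    random_state=seed)
    elif name == "RF":
        base = dict(n_estimators=100, random_state=seed)
    elif name == "LR":
        base = dict(C=1.0, max_iter=2000, random_state=seed)
    elif name == "KNN":
        base = dict(n_neighbors=5)
    elif name == "MLP":
        base = dict(hidden_layer_sizes=(64,), max_iter=800, random_state=seed)
    else:
        raise ValueError(f"unknown learner {name!r}")
    base.update(params)
    cls = {
        "SVM": SVC,
        "RF": RandomForestClassifier,
        "LR": LogisticRegression,
        "KNN": KNeighborsClassifier,
        "MLP": MLPClassifier,
    }[name]
    return cls(**base)


def _learner_seed(seed: int, learner_index: int) -> int:
    return int((seed * 1_000_003 + 7919 * learner_index + 1) % (2**31 - 1))


def make_learners(
    combination: Sequence[str],
    seed: int,
    overrides: Mapping[str, Mapping[str, object]] | None = None,
) -> list[BaseLearnerSpec]:
    overrides = overrides or {}
    return [
        BaseLearnerSpec(
            name=name,
            hyperparameters=dict(overrides.get(name, {})),
            seed=_learner_seed(seed, i),
        )
        for i, name in enumerate(combination)
    ]


def _fit_one(spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray):
    """Fit one base learner, degrading to a constant on single-class data."""
    if len(np.unique(y)) < 2:
        return ConstantClassifier().fit(X, y)
    params = dict(spec.hyperparameters)
    if spec.name == "KNN":
        # k cannot exceed the number of fitted samples
        k = int(params.get("n_neighbors", 5))
        params["n_neighbors"] = max(1, min(k, len(y)))
    est = _default_estimator(spec.name, spec.seed, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est


def _proba_in(est, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Class probabilities aligned onto the global class order.

    Learners without probability outputs contribute a one-hot vote.
    """
    out = np.zeros((len(X), len(classes)))
    pos = {c: j for j, c in enumerate(classes)}
    if hasattr(est, "predict_proba"):
        local = est.predict_proba(X)
        for j, c in enumerate(est.classes_):
            out[:, pos[c]] = local[:, j]
    else:
        for i, c in enumerate(est.predict(X)):
            out[i, pos[c]] = 1.0
    return out


# --------------------------------------------------------------------------
# Phase 2: per-sample class probabilities


def compute_class_probabilities(
    features: FeatureTable | np.ndarray,
    labels: Sequence,
    source: str = "in_sample",
    seed: int = 0,
    C: float = 0.01,
) -> np.ndarray:
    """Logistic-regression class-probability matrix (samples × classes).

    ``in_sample`` fits on all rows and scores the same rows (the
    sequential construction); ``out_of_fold`` returns 5-fold
    cross-fitted probabilities to mitigate the leakage of scoring
    training points with their own model.

    ``C`` is the inverse L2 regularization strength of the probability
    model.  It is deliberately stronger (smaller C) than a typical
    classification default: on well-separated classes a
    maximum-likelihood fit drives probabilities to saturation near 0/1,
    which collapses the per-sample confidence structure that the
    subsequent clustering phase exists to exploit.  A smoother
    probability map keeps latent subgroups at distinct confidence
    levels.
    """
    X = features.values if isinstance(features, FeatureTable) else np.asarray(features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("class probabilities require at least two classes")
    lr = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    if source == "in_sample":
        lr.fit(X, y)
        return lr.predict_proba(X)
    if source == "out_of_fold":
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        return cross_val_predict(lr, X, y, cv=cv, method="predict_proba")
    raise ValueError(f"unknown probability source {source!r}")


# --------------------------------------------------------------------------
# Phase 3: clustering the probability matrix


@dataclass
class ClusterSelection:
    n_clusters: int
    assignments: np.ndarray
    centroids: np.ndarray
    silhouettes: dict[int, float]


def select_cluster_count(
    probabilities: np.ndarray,
    cluster_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_init: int = 10,
) -> ClusterSelection:
    """Dynamic cluster count: silhouette argmax over K-means fits.

    Runs K-means (k-means++ init, ``n_init`` restarts, fixed seed) for
    each k in the range and keeps the k with the highest mean silhouette;
    ties go to the smaller k.  A degenerate range [k, k] skips selection.
    """
    P = np.asarray(probabilities, dtype=float)
    n = len(P)
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    lo, hi = cluster_range
    if hi >= n:
        warnings.warn(f"cluster_range upper bound {hi} truncated to {n - 1}")
        hi = n - 1
        lo = min(lo, hi)

    def _fit(k: int) -> KMeans:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
        km.fit(P)
        return km

    if lo == hi:
        if lo == 1:
            return ClusterSelection(
                1, np.zeros(n, dtype=int), P.mean(axis=0, keepdims=True), {1: float("nan")}
            )
        km = _fit(lo)
        return ClusterSelection(lo, km.labels_, km.cluster_centers_, {lo: float("nan")})

    best: tuple[int, KMeans] | None = None
    scores: dict[int, float] = {}
    for k in range(max(2, lo), hi + 1):
        km = _fit(k)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = float(silhouette_score(P, km.labels_))
        scores[k] = score
        if best is None or score > scores[best[0]] + 1e-12:
            best = (k, km)
    if best is None:
        return ClusterSelection(
            1, np.zeros(n, dtype=int), P.mean(axis=0, keepdims=True), scores
        )
    k, km = best
    return ClusterSelection(k, km.labels_, km.cluster_centers_, scores)


def merge_small_clusters(
    assignments: np.ndarray,
    centroids: np.ndarray,
    min_cluster_size: int,
) -> np.ndarray:
    """Fold clusters below ``min_cluster_size`` into their nearest neighbour.

    Per-cluster learners need a fittable number of rows; a tiny cluster's
    points are relabelled to the cluster with the nearest centroid.
    Cluster ids are then re-encoded densely as 0..m-1.
    """
    labels = np.asarray(assignments).copy()
    centroids = np.asarray(centroids, dtype=float)
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if len(ids) <= 1:
            break
        small = ids[counts < min_cluster_size]
        if small.size == 0:
            break
        c = small[np.argmin(counts[np.isin(ids, small)])]
        others = [i for i in ids if i != c]
        dists = [np.linalg.norm(centroids[c] - centroids[o]) for o in others]
        target = others[int(np.argmin(dists))]
        labels[labels == c] = target
    dense = {old: new for new, old in enumerate(sorted(np.unique(labels)))}
    return np.array([dense[v] for v in labels], dtype=int)


# --------------------------------------------------------------------------
# Phase 3/4: composite labels and the SVM bridge


@dataclass(frozen=True)
class CompositeCodec:
    """Invertible dense encoding of (class index, cluster id) pairs."""

    pairs: tuple[tuple[int, int], ...]

    def encode(self, class_idx: int, cluster: int) -> int:
        return self.pairs.index((class_idx, cluster))

    def decode(self, code: int) -> tuple[int, int]:
        return self.pairs[code]

    def __len__(self) -> int:
        return len(self.pairs)


def augment_labels(
    labels: Sequence[int], assignments: Sequence[int]
) -> tuple[np.ndarray, CompositeCodec]:
    """Composite label per sample: dense code of the (class, cluster) pair."""
    y = np.asarray(labels, dtype=int)
    a = np.asarray(assignments, dtype=int)
    if len(y) != len(a):
        raise ValueError("labels and cluster assignments differ in length")
    pairs = tuple(sorted({(int(c), int(g)) for c, g in zip(y, a)}))
    codec = CompositeCodec(pairs=pairs)
    index = {p: i for i, p in enumerate(pairs)}
    codes = np.array([index[(int(c), int(g))] for c, g in zip(y, a)], dtype=int)
    return codes, codec


def fit_bridge(
    features: np.ndarray,
    composite_labels: np.ndarray,
    seed: int = 0,
    svm_params: Mapping[str, object] | None = None,
):
    """Multi-class SVM over composite codes; constant if only one code."""
    X = np.asarray(features, dtype=float)
    codes = np.asarray(composite_labels, dtype=int)
    if len(np.unique(codes)) < 2:
        return ConstantClassifier().fit(X, codes)
    params = dict(C=1.0, kernel="rbf", gamma="scale",
                  decision_function_shape="ovr", random_state=seed)
    params.update(svm_params or {})
    svm = SVC(**params)
    svm.fit(X, codes)
    return svm


# --------------------------------------------------------------------------
# Phase 5: per-cluster ensembles


def fit_cluster_ensembles(
    features: np.ndarray,
    labels: Sequence[int],
    assignments: Sequence[int],
    combination: Sequence[BaseLearnerSpec],
) -> dict[int, list]:
    """Fit each learner of the combination independently on each cluster."""
    if not combination:
        raise ValueError("ensemble combination must be non-empty")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    a = np.asarray(assignments, dtype=int)
    ensembles: dict[int, list] = {}
    for cluster in sorted(np.unique(a)):
        rows = a == cluster
        Xc, yc = X[rows], y[rows]
        if len(np.unique(yc)) < 2:
            ensembles[int(cluster)] = [ConstantClassifier().fit(Xc, yc)]
        else:
            ensembles[int(cluster)] = [_fit_one(s, Xc, yc) for s in combination]
    return ensembles


@dataclass
class PredictionResult:
    predicted: np.ndarray
    clusters: np.ndarray
    probabilities: np.ndarray


@dataclass
class FittedHybridModel:
    """All fitted state of phases 2–5 on preprocessed features."""

    probability_model: LogisticRegression
    n_clusters: int
    centroids: np.ndarray
    assignments: np.ndarray
    codec: CompositeCodec
    bridge: object
    cluster_ensembles: dict[int, list]
    class_names: list[str]
    config: HybridConfig


def fit_phases(
    X: np.ndarray, y_idx: np.ndarray, class_names: Sequence[str], config: HybridConfig
) -> FittedHybridModel:
    """Phases 2–5 on already-preprocessed features."""
    X = np.asarray(X, dtype=float)
    y_idx = np.asarray(y_idx, dtype=int)
    probs = compute_class_probabilities(
        X, y_idx, source=config.probability_source, seed=config.seed,
        C=config.probability_regularization,
    )
    lr = LogisticRegression(
        C=config.probability_regularization, max_iter=2000, random_state=config.seed
    ).fit(X, y_idx)
    sel = select_cluster_count(probs, config.cluster_range, seed=config.seed)
    merged = merge_small_clusters(sel.assignments, sel.centroids, config.min_cluster_size)
    codes, codec = augment_labels(y_idx, merged)
    bridge = fit_bridge(X, codes, seed=config.seed)
    specs = make_learners(config.combination, config.seed, config.learner_overrides)
    ensembles = fit_cluster_ensembles(X, y_idx, merged, specs)
    return FittedHybridModel(
        probability_model=lr,
        n_clusters=sel.n_clusters,
        centroids=sel.centroids,
        assignments=merged,
        codec=codec,
        bridge=bridge,
        cluster_ensembles=ensembles,
        class_names=list(class_names),
        config=config,
    )


def predict(model: FittedHybridModel, features: FeatureTable | np.ndarray) -> PredictionResult:
    """Route each sample via the bridge, then soft-vote its cluster ensemble.

    The bridge predicts a composite code whose cluster component selects
    the local ensemble; the ensemble's unweighted mean probability vector
    is the sample's class distribution (argmax, lowest index on ties).
    Hard voting instead averages one-hot member votes.
    """
    X = features.values if isinstance(features, FeatureTable) else np.asarray(features)
    codes = np.asarray(model.bridge.predict(X), dtype=int)
    clusters = np.array([model.codec.decode(c)[1] for c in codes], dtype=int)
    classes = np.arange(len(model.class_names))
    prob = np.zeros((len(X), len(classes)))
    for cluster in np.unique(clusters):
        rows = np.flatnonzero(clusters == cluster)
        ensemble = model.cluster_ensembles.get(int(cluster))
        if ensemble is None:
            # bridge routed to a cluster never seen in training: fall back
            # to the probability model
            prob[rows] = _proba_in(model.probability_model, X[rows], classes)
            continue
        votes = np.zeros((len(rows), len(classes)))
        for est in ensemble:
            if model.config.voting == "soft":
                votes += _proba_in(est, X[rows], classes)
            else:
                for i, c in enumerate(np.asarray(est.predict(X[rows]), dtype=int)):
                    votes[i, c] += 1.0
        prob[rows] = votes / len(ensemble)
    row_sums = prob.sum(axis=1, keepdims=True)
    prob = np.divide(prob, row_sums, out=np.full_like(prob, 1.0 / len(classes)),
                     where=row_sums > 0)
    pred = prob.argmax(axis=1)
    return PredictionResult(predicted=pred, clusters=clusters, probabilities=prob)


# --------------------------------------------------------------------------
# Plain soft-voting reference ensemble (the non-hybrid benchmark rows)


@dataclass
class PlainEnsemble:
    estimators: list
    class_names: list[str]
    voting: str = "soft"

    def predict_result(self, X: np.ndarray) -> PredictionResult:
        X = X.values if isinstance(X, FeatureTable) else np.asarray(X)
        classes = np.arange(len(self.class_names))
        votes = np.zeros((len(X), len(classes)))
        for est in self.estimators:
            if self.voting == "soft":
                votes += _proba_in(est, X, classes)
            else:
                for i, c in enumerate(np.asarray(est.predict(X), dtype=int)):
                    votes[i, c] += 1.0
        prob = votes / len(self.estimators)
        return PredictionResult(
            predicted=prob.argmax(axis=1),
            clusters=np.zeros(len(X), dtype=int),
            probabilities=prob,
        )


def fit_plain_ensemble(
    X: np.ndarray,
    y_idx: np.ndarray,
    class_names: Sequence[str],
    config: HybridConfig,
) -> PlainEnsemble:
    """The same combination fitted once on all rows (no clustering/routing).

    Uses the identical learner construction and seed derivation as the
    hybrid's per-cluster ensembles, so a one-cluster hybrid reproduces it
    exactly.
    """
    specs = make_learners(config.combination, config.seed, config.learner_overrides)
    ests = [_fit_one(s, np.asarray(X, dtype=float), np.asarray(y_idx, dtype=int))
            for s in specs]
    return PlainEnsemble(estimators=ests, class_names=list(class_names),
                         voting=config.voting)


# --------------------------------------------------------------------------
# End-to-end pipeline over raw sequence datasets


@dataclass
class HybridPipeline:
    """Featurization + preprocessing states + the fitted hybrid core."""

    kmer: KmerConfig
    preprocess: PreprocessConfig
    minmax_state: MinMaxState | None
    lda_projection: LdaProjection | None
    model: FittedHybridModel
    class_names: list[str]

    def transform(self, dataset: LabeledDataset | Sequence) -> np.ndarray:
        table = featurize_dataset(
            dataset, k=self.kmer.k, mode=self.kmer.mode, canonical=self.kmer.canonical
        )
        return self.transform_table(table)

    def transform_table(self, table: FeatureTable) -> np.ndarray:
        if self.minmax_state is not None:
            table = apply_minmax(self.minmax_state, table)
        if self.lda_projection is not None:
            table = apply_lda(self.lda_projection, table)
        return table.values

    def predict(self, dataset: LabeledDataset | Sequence) -> PredictionResult:
        return predict(self.model, self.transform(dataset))

    def predict_labels(self, dataset: LabeledDataset | Sequence) -> list[str]:
        result = self.predict(dataset)
        return [self.class_names[i] for i in result.predicted]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "HybridPipeline":
        return joblib.load(path)


def fit_hybrid(
    dataset: LabeledDataset,
    kmer: KmerConfig = KmerConfig(),
    preprocess: PreprocessConfig = PreprocessConfig(),
    config: HybridConfig = HybridConfig(),
) -> HybridPipeline:
    """Fit the full pipeline: featurize → min-max → LDA → phases 2–5."""
    if len(dataset.class_names) < 2:
        raise ValueError("fit_hybrid requires a dataset with at least two classes")
    table = featurize_dataset(
        dataset, k=kmer.k, mode=kmer.mode, canonical=kmer.canonical
    )
    y_idx = np.asarray(dataset.label_indices(), dtype=int)

    minmax_state = None
    lda_projection = None
    work = table
    try:
        steps = (
            ["minmax", "lda"]
            if preprocess.order == "minmax_first"
            else ["lda", "minmax"]
        )
        for step in steps:
            if step == "minmax" and preprocess.minmax:
                minmax_state = fit_minmax(work)
                work = apply_minmax(minmax_state, work)
            if step == "lda" and preprocess.lda:
                lda_projection = fit_lda(
                    work, dataset.label_list(), n_components=preprocess.n_components
                )
                work = apply_lda(lda_projection, work)
    except Exception as exc:
        raise RuntimeError(f"preprocessing stage failed: {exc}") from exc

    model = fit_phases(work.values, y_idx, dataset.class_names, config)
    return HybridPipeline(
        kmer=kmer,
        preprocess=preprocess,
        minmax_state=minmax_state,
        lda_projection=lda_projection,
        model=model,
        class_names=list(dataset.class_names),
    )


# --------------------------------------------------------------------------
# Benchmark combinatorics


def enumerate_combinations(
    learners: Sequence[str] = LEARNER_NAMES, arity: int = 2
) -> list[tuple[str, ...]]:
    """All unordered subsets of the given size, in deterministic order."""
    from itertools import combinations

    if not 1 <= arity <= len(learners):
        raise ValueError(
            f"arity must be in [1, {len(learners)}], got {arity}"
        )
    return [tuple(c) for c in combinations(learners, arity)]


def combination_name(combination: Sequence[str], hybrid: bool = False) -> str:
    """Benchmark row label, e.g. ``SVM-RF-LR`` or ``Hybrid-RF-LR-KNN-MLP``."""
    body = "-".join(combination)
    return f"Hybrid-{body}" if hybrid else body
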
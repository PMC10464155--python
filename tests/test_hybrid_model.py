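import numpy as np
import pytest

from hybridseq.evaluation import holdout_split
from hybridseq.hybrid_model import (
    BaseLearnerSpec,
    HybridConfig,
    KmerConfig,
    PreprocessConfig,
    augment_labels,
    combination_name,
    compute_class_probabilities,
    enumerate_combinations,
    fit_bridge,
    fit_cluster_ensembles,
    fit_hybrid,
    fit_phases,
    fit_plain_ensemble,
    make_learners,
    merge_small_clusters,
    predict,
    select_cluster_count,
)


class TestClassProbabilities:
    def test_rows_sum_to_one_and_shape(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 3, size=30)
        y[:3] = [0, 1, 2]  # ensure all classes present
        P = compute_class_probabilities(X, y)
        assert P.shape == (30, 3)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_separated_binary_data_confident(self, rng):
        X = np.concatenate([rng.normal(-5, 0.1, 40), rng.normal(5, 0.1, 40)])[:, None]
        y = np.array([0] * 40 + [1] * 40)
        P = compute_class_probabilities(X, y, C=1000.0)
        assert np.all(P.max(axis=1) > 0.99)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            compute_class_probabilities(rng.normal(size=(10, 2)), np.zeros(10))

    def test_out_of_fold_shape(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.array([0, 1] * 20)
        P = compute_class_probabilities(X, y, source="out_of_fold")
        assert P.shape == (40, 2)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)


class TestClusterSelection:
    def test_planted_blobs_recovered(self, rng):
        P = np.vstack([
            rng.normal([0.9, 0.1], 0.02, size=(30, 2)),
            rng.normal([0.1, 0.9], 0.02, size=(30, 2)),
        ])
        sel = select_cluster_count(P, (2, 6), seed=0)
        assert sel.n_clusters == 2

    def test_degenerate_range_skips_selection(self, rng):
        sel = select_cluster_count(rng.random((10, 2)), (1, 1), seed=0)
        assert sel.n_clusters == 1
        assert np.all(sel.assignments == 0)

    def test_tie_prefers_smaller_k(self):
        # perfectly symmetric two points: every k gives the same structure
        P = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        sel = select_cluster_count(P, (2, 3), seed=0)
        assert sel.n_clusters == 2

    def test_range_truncated_with_warning(self, rng):
        P = rng.random((5, 2))
        with pytest.warns(UserWarning, match="truncated"):
            select_cluster_count(P, (2, 10), seed=0)


class TestMergeSmallClusters:
    def test_small_cluster_folded_into_nearest(self):
        assignments = np.array([0] * 10 + [1] * 10 + [2] * 2)
        centroids = np.array([[0.0], [1.0], [0.9]])
        merged = merge_small_clusters(assignments, centroids, min_cluster_size=5)
        assert set(merged) == {0, 1}
        # the two stragglers joined the nearest centroid (old cluster 1)
        assert np.all(merged[20:] == merged[10])

    def test_no_merge_when_all_large(self):
        assignments = np.array([0] * 6 + [1] * 6)
        merged = merge_small_clusters(assignments, np.array([[0.0], [1.0]]), 5)
        np.testing.assert_array_equal(merged, assignments)


class TestAugmentLabels:
    def test_distinct_pairs_counted(self):
        codes, codec = augment_labels([0, 0, 1, 1], [0, 1, 0, 0])
        assert len(codec) == 3
        assert len(set(codes.tolist())) == 3

    def test_single_cluster_bijective_with_classes(self):
        codes, codec = augment_labels([0, 1, 0, 1], [0, 0, 0, 0])
        assert len(codec) == 2
        assert codec.decode(codes[0]) == (0, 0)
        assert codec.decode(codes[1]) == (1, 0)

    def test_pair_bound(self, rng):
        y = rng.integers(0, 3, 50)
        a = rng.integers(0, 4, 50)
        codes, codec = augment_labels(y, a)
        assert len(codec) <= 3 * 4

    def test_codec_invertible(self, rng):
        y = rng.integers(0, 2, 30)
        a = rng.integers(0, 3, 30)
        codes, codec = augment_labels(y, a)
        for code, cls, cluster in zip(codes, y, a):
            assert codec.decode(code) == (cls, cluster)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment_labels([0, 1], [0])


class TestBridge:
    def test_training_fit_reaches_majority_rate(self, rng):
        X = rng.normal(size=(40, 2))
        codes = np.array([0] * 30 + [1] * 10)
        bridge = fit_bridge(X, codes, seed=0)
        acc = np.mean(bridge.predict(X) == codes)
        assert acc >= 0.75

    def test_single_code_constant_predictor(self, rng):
        X = rng.normal(size=(10, 2))
        bridge = fit_bridge(X, np.zeros(10, dtype=int), seed=0)
        assert np.all(bridge.predict(X) == 0)

    def test_refit_deterministic(self, rng):
        X = rng.normal(size=(30, 2))
        codes = np.array([0, 1, 2] * 10)
        p1 = fit_bridge(X, codes, seed=1).predict(X)
        p2 = fit_bridge(X, codes, seed=1).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestClusterEnsembles:
    def test_learner_count(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.array([0, 1] * 20)
        a = np.array([0] * 20 + [1] * 20)
        specs = make_learners(("KNN", "MLP"), seed=0)
        ensembles = fit_cluster_ensembles(X, y, a, specs)
        assert sorted(ensembles) == [0, 1]
        assert all(len(v) == 2 for v in ensembles.values())

    def test_single_class_cluster_constant(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 10 + [1] * 10)
        a = np.array([0] * 10 + [1] * 10)
        specs = make_learners(("KNN",), seed=0)
        ensembles = fit_cluster_ensembles(X, y, a, specs)
        assert np.all(ensembles[0][0].predict(X) == 0)
        assert np.all(ensembles[1][0].predict(X) == 1)

    def test_empty_combination_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_cluster_ensembles(rng.normal(size=(4, 2)), [0, 1, 0, 1],
                                  [0, 0, 0, 0], [])


class TestPredict:
    def test_probability_rows_sum_to_one(self, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        model = fit_phases(X, y, ["a", "b"], HybridConfig(seed=0,
                                                          combination=("LR", "KNN")))
        result = predict(model, rng.normal(size=(20, 2)))
        np.testing.assert_allclose(result.probabilities.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(
            result.predicted, result.probabilities.argmax(axis=1)
        )

    def test_single_class_cluster_gives_certain_prediction(self, rng):
        # two far blobs, one per class: every cluster is single-class
        X = np.vstack([rng.normal(-10, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = fit_phases(X, y, ["a", "b"],
                           HybridConfig(seed=0, cluster_range=(2, 2),
                                        combination=("KNN",)))
        result = predict(model, X)
        routed_single = [
            i for i, c in enumerate(result.clusters)
            if len(model.cluster_ensembles.get(int(c), [1, 2])) == 1
        ]
        assert routed_single  # the construction creates single-class clusters
        for i in routed_single:
            assert result.probabilities[i].max() == pytest.approx(1.0)


class TestDegenerateEquivalence:
    def test_one_cluster_hybrid_equals_plain_ensemble(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=50) > 0).astype(int)
        X_test = rng.normal(size=(30, 3))
        config = HybridConfig(seed=3, cluster_range=(1, 1),
                              combination=("SVM", "LR", "KNN"))
        model = fit_phases(X, y, ["a", "b"], config)
        plain = fit_plain_ensemble(X, y, ["a", "b"], config)
        np.testing.assert_array_equal(
            predict(model, X_test).predicted,
            plain.predict_result(X_test).predicted,
        )


class TestFitHybridEndToEnd:
    def test_same_seed_reproducible(self, separable_dataset):
        dataset, _ = separable_dataset
        cfg = HybridConfig(seed=5, combination=("LR", "KNN"), cluster_range=(2, 4))
        p1 = fit_hybrid(dataset, config=cfg)
        p2 = fit_hybrid(dataset, config=cfg)
        np.testing.assert_array_equal(
            p1.model.assignments, p2.model.assignments
        )
        np.testing.assert_array_equal(
            p1.predict(dataset).predicted, p2.predict(dataset).predicted
        )
        assert p1.model.n_clusters == p2.model.n_clusters

    def test_holdout_accuracy_on_separated_data(self, separable_dataset):
        dataset, _ = separable_dataset
        from hybridseq.io_sequences import LabeledDataset

        plan = holdout_split(len(dataset), 0.6, seed=1)
        recs = dataset.records
        train = LabeledDataset([recs[i] for i in plan.train],
                               {recs[i].id: dataset.labels[recs[i].id]
                                for i in plan.train},
                               class_names=dataset.class_names)
        test_recs = [recs[i] for i in plan.test]
        y_true = [dataset.labels[r.id] for r in test_recs]
        pipeline = fit_hybrid(
            train,
            preprocess=PreprocessConfig(lda=False),
            config=HybridConfig(seed=1, combination=("LR", "KNN")),
        )
        predicted = pipeline.predict_labels(test_recs)
        acc = np.mean([p == t for p, t in zip(predicted, y_true)])
        assert acc >= 0.95

    def test_single_class_dataset_rejected(self, tiny_dataset):
        from hybridseq.io_sequences import LabeledDataset

        mono = LabeledDataset(tiny_dataset.records,
                              {r.id: "x" for r in tiny_dataset.records})
        with pytest.raises(ValueError, match="two classes"):
            fit_hybrid(mono)

    def test_save_load_round_trip(self, separable_dataset, tmp_path):
        dataset, _ = separable_dataset
        pipeline = fit_hybrid(
            dataset, config=HybridConfig(seed=2, combination=("LR",),
                                         cluster_range=(2, 3))
        )
        pipeline.save(tmp_path / "model.joblib")
        from hybridseq.hybrid_model import HybridPipeline

        loaded = HybridPipeline.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(
            loaded.predict(dataset).predicted, pipeline.predict(dataset).predicted
        )


class TestCombinations:
    @pytest.mark.parametrize("arity,count", [(1, 5), (2, 10), (3, 10), (4, 5), (5, 1)])
    def test_subset_counts(self, arity, count):
        assert len(enumerate_combinations(arity=arity)) == count

    def test_arity_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_combinations(arity=0)
        with pytest.raises(ValueError):
            enumerate_combinations(arity=6)

    def test_quinary_row_label(self):
        combos = enumerate_combinations(arity=5)
        assert combination_name(combos[0]) == "SVM-RF-LR-KNN-MLP"
        assert combination_name(("RF", "LR", "KNN", "MLP"), hybrid=True) == \
            "Hybrid-RF-LR-KNN-MLP"

    def test_deterministic_order(self):
        assert enumerate_combinations(arity=2) == enumerate_combinations(arity=2)


class TestSpecsValidation:
    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            BaseLearnerSpec(name="XGB")

    def test_bad_cluster_range_rejected(self):
        with pytest.raises(ValueError):
            HybridConfig(cluster_range=(3, 2))

    def test_empty_combination_rejected(self):
        with pytest.raises(ValueError):
            HybridConfig(combination=())
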
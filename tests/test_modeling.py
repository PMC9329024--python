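"""Splits, folds, classifier training, pooling and suite structure."""

import numpy as np
import pytest

from mtqsar import ModelSpec, build_suite, make_folds, stratified_split, train_classifier
from mtqsar.errors import DomainError, UnknownTargetError
from mtqsar.modeling import (
    ALL_MODEL_NAMES,
    PCM_MODEL_NAMES,
    PER_TARGET_MODEL_NAMES,
    ModelSuite,
    child_seed,
    pool_pcm_dataset,
)
from conftest import fast_suite_config


def labels(n_active, n_inactive):
    return np.array([1] * n_active + [0] * n_inactive)


class TestStratifiedSplit:
    def test_stratification_arithmetic(self):
        split = stratified_split(labels(40, 60), 0.2, seed=0)
        y = split.labels
        assert (y[split.test_idx] == 1).sum() == 8
        assert (y[split.test_idx] == 0).sum() == 12

    def test_seed_determinism(self):
        a = stratified_split(labels(30, 30), 0.2, seed=9)
        b = stratified_split(labels(30, 30), 0.2, seed=9)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_zero_fraction_boundary(self):
        split = stratified_split(labels(5, 5), 0.0, seed=0)
        assert len(split.test_idx) == 0 and len(split.train_idx) == 10

    def test_small_class_rejected(self):
        with pytest.raises(DomainError) as err:
            stratified_split(labels(1, 10), 0.2, seed=0)
        assert "class 1" in str(err.value)

    def test_partition_property(self):
        split = stratified_split(labels(17, 23), 0.25, seed=3)
        split.validate()
        assert len(np.intersect1d(split.train_idx, split.test_idx)) == 0


class TestMakeFolds:
    def test_even_folds(self):
        split = stratified_split(labels(15, 10), 0.0, seed=0)
        plan = make_folds(split, k=5, seed=1)
        assert sorted(len(f) for f in plan.folds) == [5] * 5

    def test_remainder_rule(self):
        split = stratified_split(labels(13, 13), 0.0, seed=0)
        plan = make_folds(split, k=5, seed=1)
        assert sorted(len(f) for f in plan.folds) == [5, 5, 5, 5, 6]

    def test_per_class_counts_within_one(self):
        split = stratified_split(labels(20, 5), 0.0, seed=0)
        plan = make_folds(split, k=5, seed=2)
        y = split.labels
        for cls in (0, 1):
            per_fold = [int((y[f] == cls).sum()) for f in plan.folds]
            assert max(per_fold) - min(per_fold) <= 1

    def test_k_exceeding_class_count_rejected(self):
        split = stratified_split(labels(20, 4), 0.0, seed=0)
        with pytest.raises(DomainError):
            make_folds(split, k=5, seed=0)

    def test_no_leakage_into_test_partition(self):
        split = stratified_split(labels(20, 20), 0.2, seed=7)
        plan = make_folds(split, k=5, seed=7)
        fold_members = np.concatenate(plan.folds)
        assert len(np.intersect1d(fold_members, split.test_idx)) == 0
        assert np.array_equal(np.sort(fold_members), split.train_idx)


class TestTrainClassifier:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(-2, 0.5, size=(10, 2))
        X1 = rng.normal(+2, 0.5, size=(10, 2))
        return np.vstack([X0, X1]), labels(10, 10)[::-1]

    def test_one_nn_memorizes_training_set(self):
        X, y = self._toy()
        spec = ModelSpec("KNN", "MACCS", (("n_neighbors", 1),), seed=0)
        tc = train_classifier(spec, X, y)
        assert np.array_equal(tc.predict_labels(X), y)

    def test_rf_separable_toy_perfect(self):
        X, y = self._toy()
        # verify the toy really is separable before asserting on the fit
        assert X[y == 1, 0].min() > X[y == 0, 0].max()
        spec = ModelSpec("RF", "MACCS", (("n_estimators", 50),), seed=1)
        tc = train_classifier(spec, X, y)
        assert (tc.predict_labels(X) == y).mean() == 1.0

    @pytest.mark.parametrize("alg", ["RF", "KNN", "SVM", "NN"])
    def test_identical_seed_identical_votes(self, alg):
        X, y = self._toy(3)
        hp = {"RF": (("n_estimators", 30),), "NN": (("max_iter", 200),)}.get(alg, ())
        probe = np.array([[0.3, -0.1], [1.5, 2.0]])
        runs = [
            train_classifier(ModelSpec(alg, "ECFP6", hp, seed=42), X, y).predict_scores(probe)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0], runs[1])

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(DomainError):
            train_classifier(ModelSpec("RF", "MACCS"), X, np.ones(4, dtype=int))

    def test_scores_in_unit_interval(self):
        X, y = self._toy(5)
        tc = train_classifier(ModelSpec("SVM", "MACCS", seed=0), X, y)
        s = tc.predict_scores(X)
        assert (s >= 0).all() and (s <= 1).all()


class TestSeedFanout:
    def test_stable_and_distinct(self):
        a = child_seed(7, "model", "T1", "RF", "MACCS")
        assert a == child_seed(7, "model", "T1", "RF", "MACCS")
        assert a != child_seed(7, "model", "T1", "RF", "ECFP6")
        assert a != child_seed(8, "model", "T1", "RF", "MACCS")
        assert 0 <= a < 2**31


class TestSuiteStructure:
    def test_canonical_model_names(self):
        assert len(ALL_MODEL_NAMES) == 16
        assert ALL_MODEL_NAMES[:8] == PER_TARGET_MODEL_NAMES
        assert ALL_MODEL_NAMES[8:] == PCM_MODEL_NAMES
        assert "RF_MACCS" in PER_TARGET_MODEL_NAMES
        assert "KNN_ECFP6_protein" in PCM_MODEL_NAMES

    def test_two_target_suite_cardinality(self, tiny_results):
        suite = tiny_results.suite
        assert suite.n_targets == 2
        assert suite.n_per_target_classifiers == 16
        assert suite.n_classifiers == 8 * 2 + 8

    def test_single_target_suite(self, tiny_benchmark):
        tid = "T01"
        suite = build_suite(
            {tid: tiny_benchmark.datasets[tid]},
            {tid: tiny_benchmark.sequences[tid]},
            fast_suite_config(), seed=0,
        )
        assert suite.n_classifiers == 16
        assert set(suite.models_for(tid)) == set(ALL_MODEL_NAMES)

    def test_unknown_target_error_lists_known(self, tiny_results):
        with pytest.raises(UnknownTargetError) as err:
            tiny_results.suite.models_for("NOPE")
        assert "T01" in str(err.value)

    def test_save_load_roundtrip(self, tiny_results, tiny_benchmark, tmp_path):
        from mtqsar.ensemble import vote_matrix

        suite = tiny_results.suite
        suite.save(tmp_path / "suite")
        back = ModelSuite.load(tmp_path / "suite")
        assert back.n_classifiers == suite.n_classifiers
        probe = tiny_benchmark.datasets["T01"].smiles()[:5]
        assert np.array_equal(
            vote_matrix(suite, probe, "T01"), vote_matrix(back, probe, "T01")
        )
        assert back.thresholds == suite.thresholds


class TestPoolPCM:
    def test_row_additivity(self, tiny_results, tiny_benchmark):
        suite = tiny_results.suite
        idx = {t: suite.splits[t].train_idx for t in suite.target_ids}
        X, y, prov = pool_pcm_dataset(
            tiny_benchmark.datasets, suite.registry, "MACCS", row_indices=idx
        )
        expected = sum(len(v) for v in idx.values())
        assert len(X) == len(y) == len(prov) == expected
        per_target_pos = {
            t: int(tiny_benchmark.datasets[t].labels()[idx[t]].sum())
            for t in suite.target_ids
        }
        assert y.sum() == sum(per_target_pos.values())

    def test_single_dataset_identity(self, tiny_results, tiny_benchmark):
        suite = tiny_results.suite
        ds = tiny_benchmark.datasets["T01"]
        X, y, _ = pool_pcm_dataset({"T01": ds}, suite.registry, "MACCS")
        from mtqsar.featurization import fingerprint_matrix

        fps = fingerprint_matrix(ds.smiles(), "MACCS")
        block = suite.registry.protein_block("T01")
        assert np.allclose(X, np.hstack([fps, np.tile(block, (len(fps), 1))]))
        assert np.array_equal(y, ds.labels())

    def test_missing_sequence_error(self, tiny_benchmark):
        with pytest.raises(DomainError) as err:
            build_suite(tiny_benchmark.datasets, {"T01": tiny_benchmark.sequences["T01"]},
                        fast_suite_config(), seed=0)
        assert "T02" in str(err.value)
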
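"""Classifier contracts: balanced accuracy, L1 shrinkage, nested CV."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import balanced_accuracy_score

import airrbench as ab
from airrbench.models import two_sample_ttest


def toy_matrix(n=40, p=30, informative=0, flip=0, seed=0):
    """Features ~ N(0,1) except one column equal to the labels."""
    rng = np.random.default_rng(seed)
    y = np.array([1, 0] * (n // 2))
    X = rng.normal(size=(n, p))
    X[:, informative] = y + 0.01 * rng.normal(size=n)
    for i in range(flip):
        X[i, informative] = 1 - y[i]
    return X, y


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,expected",
        [
            (10, 0, 10, 0, 1.0),
            (10, 0, 0, 10, 0.5),  # constant positive predictor
            (50, 50, 100, 0, 0.75),
        ],
    )
    def test_formula(self, tp, fn, tn, fp, expected):
        counts = ab.ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
        assert ab.balanced_accuracy(counts) == pytest.approx(expected)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ab.balanced_accuracy(ab.ConfusionCounts(tp=0, fn=0, tn=5, fp=5))

    def test_constant_predictor_scores_half_for_any_balance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_pos = int(rng.integers(1, 30))
            n_neg = int(rng.integers(1, 30))
            y_true = np.array([1] * n_pos + [0] * n_neg)
            y_pred = np.ones_like(y_true)
            counts = ab.confusion_counts(y_true, y_pred)
            assert ab.balanced_accuracy(counts) == 0.5

    def test_agrees_with_sklearn_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y_true = rng.integers(0, 2, size=30)
            y_pred = rng.integers(0, 2, size=30)
            if len(set(y_true)) < 2:
                continue
            ours = ab.balanced_accuracy(ab.confusion_counts(y_true, y_pred))
            assert ours == pytest.approx(balanced_accuracy_score(y_true, y_pred))


class TestTrainModel:
    def test_separable_toy_fits_perfectly_at_large_C(self):
        X, y = toy_matrix()
        model = ab.train_model(X, y, "logreg_l1", {"C": 10.0}, seed=0)
        counts = ab.confusion_counts(y, model.predict(X))
        assert ab.balanced_accuracy(counts) == 1.0

    def test_tiny_C_shrinks_all_coefficients_to_zero(self):
        X, y = toy_matrix(seed=1)
        model = ab.train_model(X, y, "logreg_l1", {"C": 1e-6}, seed=0)
        assert np.count_nonzero(model.named_steps["clf"].coef_) == 0

    def test_informative_feature_gets_largest_coefficient(self):
        X, y = toy_matrix(informative=7, seed=2)
        model = ab.train_model(X, y, "logreg_l1", {"C": 1.0}, seed=0)
        coef = np.abs(model.named_steps["clf"].coef_.ravel())
        assert coef.argmax() == 7

    def test_sparsity_non_increasing_as_C_decreases(self):
        X, y = toy_matrix(n=60, p=40, flip=6, seed=3)
        nnz = []
        for C in (5.0, 1.0, 0.1, 0.05, 0.01):
            model = ab.train_model(X, y, "logreg_l1", {"C": C}, seed=0)
            nnz.append(np.count_nonzero(model.named_steps["clf"].coef_))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_single_class_labels_rejected(self):
        X, _ = toy_matrix()
        with pytest.raises(ValueError):
            ab.train_model(X, np.ones(X.shape[0]), "logreg_l1")

    @pytest.mark.parametrize("kind", ["svc_l1", "svc_l2", "random_forest"])
    def test_comparators_fit_and_predict(self, kind):
        X, y = toy_matrix(seed=4)
        model = ab.train_model(X, y, kind, seed=0)
        assert set(model.predict(X)) <= {0, 1}


class TestFeatureSelection:
    def test_threshold_one_retains_all_features(self):
        X, y = toy_matrix(seed=5)
        clf = ab.FeatureSelectedLogReg(p_threshold=1.0).fit(X, y)
        assert clf.n_selected_ == X.shape[1]

    def test_strong_feature_survives_small_threshold(self):
        X, y = toy_matrix(informative=3, seed=6)
        clf = ab.FeatureSelectedLogReg(p_threshold=1e-4).fit(X, y)
        assert clf.support_[3]

    def test_empty_selection_falls_back_to_majority(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 10))
        y = np.array([1] * 10 + [0] * 20)
        clf = ab.FeatureSelectedLogReg(p_threshold=1e-12).fit(X, y)
        assert clf.n_selected_ == 0
        assert (clf.predict(X) == 0).all()

    def test_ttest_matches_scipy_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 12))
        mask = np.array([True] * 12 + [False] * 13)
        t, p = two_sample_ttest(X, mask)
        t_ref, p_ref = stats.ttest_ind(X[mask], X[~mask], equal_var=True)
        assert np.allclose(t, t_ref)
        assert np.allclose(p, p_ref)

    def test_ttest_sparse_matches_dense(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(1.0, size=(20, 15)).astype(float)
        mask = np.array([True] * 10 + [False] * 10)
        td, pd_ = two_sample_ttest(X, mask)
        ts, ps = two_sample_ttest(sp.csr_matrix(X), mask)
        assert np.allclose(td, ts)
        assert np.allclose(pd_, ps)

    def test_zero_variance_column_gets_p_one(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        mask = np.array([True] * 5 + [False] * 5)
        _, p = two_sample_ttest(X, mask)
        assert p[0] == 1.0


class TestNestedCV:
    def _dataset(self, witness_rate, n=30, size=200, seed=0):
        cell = ab.ExperimentCell(
            witness_rate=witness_rate, n_examples=n, repertoire_size=size
        )
        ds = ab.simulate_cell_dataset(cell, seed=seed)
        return ds, ab.encode_dataset(ds, 4)

    def test_outer_folds_and_strong_signal(self):
        ds, enc = self._dataset(5.0, seed=1)  # witness count 10 of 200
        result = ab.nested_cv(enc, ab.TrainingConfig(seed=1), y=ds.labels)
        assert len(result.fold_scores) == 5
        assert result.mean_balanced_accuracy > 0.9
        assert all(set(h) == {"C"} for h in result.chosen_hyperparameters)

    def test_no_signal_stays_near_chance(self):
        ds, enc = self._dataset(0.0, n=40, seed=2)
        result = ab.nested_cv(enc, ab.TrainingConfig(seed=2), y=ds.labels)
        assert 0.25 <= result.mean_balanced_accuracy <= 0.75

    def test_too_few_examples_rejected(self):
        ds, enc = self._dataset(5.0, n=20, seed=3)
        with pytest.raises(ValueError):
            ab.nested_cv(enc.values[:8], ab.TrainingConfig(), y=ds.labels[:8])

    def test_single_class_rejected(self):
        ds, enc = self._dataset(5.0, n=20, seed=4)
        with pytest.raises(ValueError):
            ab.nested_cv(enc, ab.TrainingConfig(), y=np.zeros(20))


class TestReplication:
    def test_replicates_are_deterministic_and_summarized(self):
        cell = ab.ExperimentCell(witness_rate=5.0, n_examples=20, repertoire_size=200)
        a = ab.replicate_experiment(cell, n_replications=2, seed=5)
        b = ab.replicate_experiment(cell, n_replications=2, seed=5)
        assert a == b
        assert a.n_replications == 2
        assert len(a.replicate_scores) == 2
        assert a.sd_balanced_accuracy >= 0.0
        assert 0.0 <= a.mean_balanced_accuracy <= 1.0

    def test_single_replication_has_zero_sd(self):
        cell = ab.ExperimentCell(witness_rate=5.0, n_examples=20, repertoire_size=200)
        point = ab.replicate_experiment(cell, n_replications=1, seed=6)
        assert point.sd_balanced_accuracy == 0.0

    def test_invalid_replication_count_rejected(self):
        cell = ab.ExperimentCell(witness_rate=5.0, n_examples=20, repertoire_size=200)
        with pytest.raises(ValueError):
            ab.replicate_experiment(cell, n_replications=0)


class TestTransfer:
    def test_matched_distribution_transfer_performs_well(self):
        signal = ab.random_signal(3, 4, seed=10)
        spec = ab.ImplantingSpec(witness_rate=5.0)
        train = ab.build_labeled_dataset(30, 200, signal, spec, seed=11)
        test = ab.build_labeled_dataset(30, 200, signal, spec, seed=12)
        score = ab.evaluate_transfer(train, test, ab.TrainingConfig(seed=11))
        assert score > 0.85

    def test_disjoint_feature_space_predicts_at_chance(self):
        signal = ab.random_signal(3, 4, seed=13)
        spec = ab.ImplantingSpec(witness_rate=5.0)
        train = ab.build_labeled_dataset(20, 200, signal, spec, seed=14)
        # encode test with an index containing none of its k-mers: the
        # model sees all-zero rows and falls back to a constant prediction
        enc = ab.encode_dataset(train, 4)
        model = ab.train_model(enc, train.labels, "logreg_l1", {"C": 1.0}, seed=0)
        empty = sp.csr_matrix((20, enc.shape[1]))
        preds = model.predict(empty)
        assert len(set(preds)) == 1
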
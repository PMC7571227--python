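import numpy as np
import pytest

from ldvbeat import (
    ClassifierSpec,
    fit,
    gaussian_kernel,
    grid_spaces,
    loso_split,
    predict,
    predict_proba,
    svm_dual,
)
from ldvbeat.classify import KINDS
from ldvbeat.windowing import BEAT, NO_BEAT, WindowDataset


def make_dataset(X, y, subjects=None):
    X = np.asarray(X, dtype=float)
    if subjects is None:
        subjects = ["s0"] * len(X)
    return WindowDataset(X, y, np.arange(len(X)) * 100,
                         np.array(subjects, dtype=object))


def separable_1d(n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([
        10.0 + rng.normal(scale=0.5, size=n_per_class),
        -10.0 + rng.normal(scale=0.5, size=n_per_class),
    ]).reshape(-1, 1)
    y = np.array([BEAT] * n_per_class + [NO_BEAT] * n_per_class)
    return make_dataset(X, y)


class TestGaussianKernel:
    def test_identical_inputs_give_one(self):
        assert gaussian_kernel([1.0, 2.0], [1.0, 2.0], 0.5) == 1.0

    def test_worked_value(self):
        assert gaussian_kernel([0, 0], [1, 1], 0.1) == pytest.approx(
            np.exp(-0.2), abs=1e-12
        )

    def test_symmetry(self):
        a, b = [0.3, -1.2, 4.0], [2.0, 0.1, -0.5]
        assert gaussian_kernel(a, b, 0.7) == gaussian_kernel(b, a, 0.7)

    @pytest.mark.parametrize("gamma", [0.0, -1.0])
    def test_nonpositive_gamma_rejected(self, gamma):
        with pytest.raises(ValueError):
            gaussian_kernel([0.0], [1.0], gamma)


class TestGridSpaces:
    def test_svm_grid_has_nine_points(self):
        g = grid_spaces("svm")
        assert len(g["gamma"]) * len(g["C"]) == 9
        assert g["gamma"] == [0.001, 0.01, 0.1]
        assert g["C"] == [1, 10, 100]

    def test_rf_grid_has_thirty_three_points(self):
        g = grid_spaces("rf")
        assert len(g["max_depth"]) * len(g["n_estimators"]) == 33
        assert g["n_estimators"][-1] == 600

    def test_dt_depths_evenly_spaced_in_5_20(self):
        assert grid_spaces("dt")["max_depth"] == [5, 10, 15, 20]

    def test_knn_neighbors(self):
        assert grid_spaces("knn")["n_neighbors"] == [3, 5, 7, 9]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            grid_spaces("mlp")


class TestFitAndPredict:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_clusters_fit_perfectly(self, kind):
        ds = separable_1d()
        model = fit(ClassifierSpec(kind, seed=0), ds)
        assert np.array_equal(predict(model, ds.X), ds.y)
        probs = predict_proba(model, ds.X)
        assert np.all((0 <= probs) & (probs <= 1))
        assert np.all(probs[ds.y == BEAT] > 0.5)
        assert np.all(probs[ds.y == NO_BEAT] < 0.5)

    def test_single_class_rejected(self):
        ds = make_dataset(np.zeros((10, 2)), [BEAT] * 10)
        with pytest.raises(ValueError, match="single class"):
            fit(ClassifierSpec("svm"), ds)

    def test_wrong_window_length_rejected(self):
        model = fit(ClassifierSpec("knn", seed=0), separable_1d())
        with pytest.raises(ValueError, match="length"):
            predict_proba(model, np.zeros((3, 7)))

    def test_knn_probability_is_neighbor_fraction(self):
        """With K=3, the beat probability of any query is the fraction of
        beat labels among its 3 nearest training points."""
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2],
                      [0.05], [0.15], [5.05], [5.15]])
        y = np.array([BEAT, BEAT, BEAT, NO_BEAT, NO_BEAT, NO_BEAT,
                      BEAT, BEAT, NO_BEAT, NO_BEAT])
        ds = make_dataset(X, y)
        model = fit(
            ClassifierSpec("knn", grid={"n_neighbors": [3]}, seed=0, scale=False),
            ds,
        )
        probs = predict_proba(model, np.array([[0.12], [5.12], [2.6]]))
        assert set(np.round(probs * 3).astype(int)) <= {0, 1, 2, 3}
        assert probs[0] == pytest.approx(1.0)
        assert probs[1] == pytest.approx(0.0)

    def test_scaling_invariance_of_predictions(self):
        """Standardization makes predictions invariant to affine rescaling
        of the raw LDV amplitudes."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        ds1 = make_dataset(X, y)
        ds2 = make_dataset(X * 1000.0, y)
        for kind in ("svm", "knn"):
            m1 = fit(ClassifierSpec(kind, seed=1), ds1)
            m2 = fit(ClassifierSpec(kind, seed=1), ds2)
            p1 = predict_proba(m1, ds1.X)
            p2 = predict_proba(m2, ds2.X)
            np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_single_tree_forest_reduces_to_its_tree(self):
        """An RF restricted to one tree predicts exactly as its sole
        internal decision tree (averaging over one member)."""
        ds = separable_1d(seed=4)
        model = fit(
            ClassifierSpec("rf", grid={"max_depth": [3], "n_estimators": [1]},
                           seed=2),
            ds,
        )
        forest = model.model
        tree = forest.estimators_[0]
        Xs = model.scaler.transform(ds.X)
        np.testing.assert_allclose(
            forest.predict_proba(Xs), tree.predict_proba(Xs)
        )
        assert tree.get_depth() <= 3


class TestSvmDual:
    def _xor_dataset(self):
        pts = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        labels = np.array([BEAT, BEAT, NO_BEAT, NO_BEAT])
        X = np.repeat(pts, 10, axis=0)
        y = np.repeat(labels, 10)
        return make_dataset(X, y)

    def test_xor_training_accuracy_and_dual_constraints(self):
        ds = self._xor_dataset()
        model = fit(
            ClassifierSpec("svm", grid={"gamma": [0.1], "C": [100]}, seed=0),
            ds,
        )
        assert np.array_equal(predict(model, ds.X), ds.y)
        d = svm_dual(model)
        assert abs(d["dual_coef"].sum()) <= 1e-6
        assert np.all(np.abs(d["dual_coef"]) <= d["C"] + 1e-6)

    def test_decision_values_match_kernel_expansion(self):
        """The SVC decision function equals the brute-force kernel sum over
        support vectors plus the bias, to 1e-6."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] * X[:, 1] > 0).astype(int)
        ds = make_dataset(X, y)
        model = fit(ClassifierSpec("svm", seed=5), ds)
        d = svm_dual(model)
        svc = model.model.calibrated_classifiers_[0].estimator
        Xs = model.scaler.transform(ds.X)
        expected = np.array([
            sum(
                a * gaussian_kernel(x, sv, d["gamma"])
                for a, sv in zip(d["dual_coef"], d["support_vectors"])
            ) + d["bias"]
            for x in Xs
        ])
        np.testing.assert_allclose(svc.decision_function(Xs), expected, atol=1e-6)


class TestLosoSplit:
    def _multi_subject(self, n_subjects=4, per=6):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n_subjects * per, 3))
        y = np.tile([BEAT, NO_BEAT], n_subjects * per // 2)
        subs = np.repeat([f"s{i}" for i in range(n_subjects)], per)
        return make_dataset(X, y, subs)

    def test_one_fold_per_subject(self):
        ds = self._multi_subject(4)
        folds = list(loso_split(ds))
        assert len(folds) == 4

    def test_test_subject_excluded_from_training(self):
        for subj, train, test in loso_split(self._multi_subject()):
            assert set(test.subject_ids) == {subj}
            assert subj not in set(train.subject_ids)

    def test_folds_partition_dataset(self):
        ds = self._multi_subject()
        seen = []
        for _, _, test in loso_split(ds):
            seen.extend(test.start_samples.tolist())
        assert sorted(seen) == sorted(ds.start_samples.tolist())

    def test_single_subject_rejected(self):
        ds = self._multi_subject(1)
        with pytest.raises(ValueError):
            list(loso_split(ds))
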
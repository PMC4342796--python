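"""Classifiers, cross-validation, ROC/AUC, and Gini importances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import markcast as mc
from markcast.manifest import ContextMeta
from markcast.model import (
    average_curves,
    mann_whitney_auc,
    DEFAULT_HYPERPARAMS,
)


def _meta(did):
    return ContextMeta(did, "heart", 5.0, "mouse", "H3K4me1")


def make_matrix(features, labels):
    features = np.asarray(features)
    meta = [_meta(f"d{j}") for j in range(features.shape[1])]
    return mc.LabeledFeatureMatrix(
        [f"r{i}" for i in range(features.shape[0])],
        features,
        np.asarray(labels),
        [m.dataset_id for m in meta],
        meta,
    )


def brute_force_auc(scores, labels):
    """Mean over all (positive, negative) pairs of [s_p > s_n] + 0.5 [tie]."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


scores_labels_st = st.lists(
    st.tuples(
        st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 1)),
        st.integers(0, 1),
    ),
    min_size=4,
    max_size=60,
).filter(lambda sl: len({y for _, y in sl}) == 2)


class TestClassifierSpec:
    def test_defaults_applied(self):
        spec = mc.ClassifierSpec("random_forest")
        assert spec.hyperparams["n_estimators"] == 10
        assert spec.hyperparams["max_depth"] == 5

    def test_override_requires_flag(self):
        with pytest.raises(mc.ConfigurationError):
            mc.ClassifierSpec("random_forest", {"n_estimators": 100})
        spec = mc.ClassifierSpec(
            "random_forest", {"n_estimators": 100}, allow_override=True
        )
        assert spec.hyperparams["n_estimators"] == 100

    def test_unknown_algorithm(self):
        with pytest.raises(mc.ConfigurationError):
            mc.ClassifierSpec("deep_net")

    def test_unknown_hyperparameter(self):
        with pytest.raises(mc.ConfigurationError):
            mc.ClassifierSpec("knn", {"metric": "cosine"})


class TestStratifiedFolds:
    def test_ten_to_one_design(self):
        """10 positives + 100 negatives over 5 folds: every test fold
        holds exactly 2 positives and 20 negatives."""
        labels = np.array([1] * 10 + [0] * 100)
        folds = mc.stratified_folds(labels, mc.CVConfig(n_folds=5, seed=0))
        assert len(folds) == 5
        for _, test in folds:
            assert (labels[test] == 1).sum() == 2
            assert (labels[test] == 0).sum() == 20

    def test_two_fold_minimal(self):
        folds = mc.stratified_folds([1, 0], mc.CVConfig(n_folds=2, seed=1))
        tested = sorted(int(t[0]) for _, t in folds)
        assert tested == [0, 1]

    @given(
        st.lists(st.integers(0, 1), min_size=10, max_size=80).filter(
            lambda ys: min(sum(ys), len(ys) - sum(ys)) >= 3
        ),
        st.integers(0, 5),
    )
    def test_partition_property(self, labels, seed):
        folds = mc.stratified_folds(labels, mc.CVConfig(n_folds=3, seed=seed))
        tested = np.concatenate([t for _, t in folds])
        assert sorted(tested.tolist()) == list(range(len(labels)))
        for train, test in folds:
            assert set(train) | set(test) == set(range(len(labels)))
            assert not set(train) & set(test)

    def test_single_class_raises(self):
        with pytest.raises(mc.EvaluationError):
            mc.stratified_folds([1, 1, 1, 1], mc.CVConfig(n_folds=2))

    def test_more_folds_than_samples_raises(self):
        with pytest.raises(mc.EvaluationError):
            mc.stratified_folds([1, 0, 0], mc.CVConfig(n_folds=4))


class TestRocAndAuc:
    def test_perfect_separation(self):
        curve = mc.roc_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == 1.0

    def test_total_ties_give_half(self):
        curve = mc.roc_and_auc([0.3] * 6, [1, 0, 1, 0, 1, 0])
        assert curve.auc == 0.5

    def test_single_class_raises(self):
        with pytest.raises(mc.EvaluationError):
            mc.roc_and_auc([0.1, 0.2], [1, 1])

    def test_curve_endpoints_and_trapezoid(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.3).astype(int)
        curve = mc.roc_and_auc(scores, labels)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        area = float(np.trapezoid(curve.tpr, curve.fpr))
        assert area == pytest.approx(curve.auc, abs=1e-12)

    @given(scores_labels_st)
    def test_matches_pairwise_oracle(self, sl):
        scores = [s for s, _ in sl]
        labels = [y for _, y in sl]
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @given(scores_labels_st)
    def test_antisymmetry(self, sl):
        scores = np.array([s for s, _ in sl])
        labels = [y for _, y in sl]
        assert mann_whitney_auc(-scores, labels) == pytest.approx(
            1.0 - mann_whitney_auc(scores, labels), abs=1e-12
        )

    @given(scores_labels_st)
    def test_monotone_transform_invariance(self, sl):
        scores = np.array([s for s, _ in sl])
        labels = [y for _, y in sl]
        transformed = np.exp(0.5 * scores) + 3.0  # strictly increasing
        a, b = mc.roc_and_auc(scores, labels), mc.roc_and_auc(transformed, labels)
        assert b.auc == pytest.approx(a.auc, abs=1e-12)
        np.testing.assert_allclose(b.fpr, a.fpr)
        np.testing.assert_allclose(b.tpr, a.tpr)


class TestTrainScore:
    @pytest.mark.parametrize("algorithm", mc.ALGORITHMS)
    def test_separable_feature_ranks_correctly(self, algorithm):
        """When feature 0 equals the label exactly, test rows with the
        feature on must outscore rows with it off, for every algorithm."""
        rng = np.random.default_rng(1)
        n = 120
        labels = np.array([1] * 40 + [0] * 80)
        features = np.column_stack(
            [labels, rng.integers(0, 2, n), rng.integers(0, 2, n)]
        )
        train = make_matrix(features, labels)
        test = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
        scores = mc.train_score(mc.ClassifierSpec(algorithm), train, test, seed=0)
        on, off = scores[[0, 2]], scores[[1, 3]]
        assert on.min() > off.max()

    def test_knn_unanimous_neighbors(self):
        """A test row identical to 3 training positives and far from all
        negatives scores exactly 1.0."""
        features = np.array(
            [[1, 1, 1, 1]] * 3 + [[0, 0, 0, 0]] * 6, dtype=np.uint8
        )
        labels = np.array([1] * 3 + [0] * 6)
        train = make_matrix(features, labels)
        scores = mc.train_score(
            mc.ClassifierSpec("knn"), train, np.array([[1, 1, 1, 1]])
        )
        assert scores[0] == 1.0

    def test_knn_distance_ties_broken_by_row_order(self):
        # four equidistant training rows; the first three (order!) decide
        features = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.uint8)
        labels = np.array([1, 1, 1, 0])
        train = make_matrix(features, labels)
        scores = mc.train_score(
            mc.ClassifierSpec("knn"), train, np.array([[0, 0]])
        )
        assert scores[0] == 1.0

    def test_decision_tree_represents_xor(self):
        """Depth-5 tree reaches >=0.95 training accuracy on a 2-feature
        XOR layout (XOR needs depth >= 2)."""
        rng = np.random.default_rng(2)
        f1 = rng.integers(0, 2, 200)
        f2 = rng.integers(0, 2, 200)
        labels = (f1 ^ f2).astype(int)
        if len(np.unique(labels)) < 2:  # pragma: no cover - n=200 coin flip
            labels[0] = 1 - labels[0]
        train = make_matrix(np.column_stack([f1, f2]), labels)
        scores = mc.train_score(
            mc.ClassifierSpec("decision_tree"), train, train.features, seed=0
        )
        accuracy = ((scores > 0.5).astype(int) == labels).mean()
        assert accuracy >= 0.95

    def test_single_class_train_raises(self):
        train = make_matrix(np.array([[1], [0]]), np.array([1, 1]))
        with pytest.raises(mc.EvaluationError):
            mc.train_score(mc.ClassifierSpec("knn"), train, np.array([[1]]))


class TestCrossValidate:
    def test_perfect_feature_gives_auc_one(self):
        rng = np.random.default_rng(3)
        labels = np.array([1] * 30 + [0] * 90)
        features = np.column_stack([labels, rng.integers(0, 2, 120)])
        report = mc.cross_validate(
            mc.ClassifierSpec("random_forest"),
            make_matrix(features, labels),
            mc.CVConfig(n_folds=5, seed=0),
        )
        assert report.mean_auc == 1.0
        assert len(report.per_fold) == 5

    def test_null_features_near_half(self):
        """Label-independent features give chance-level AUC."""
        rng = np.random.default_rng(4)
        labels = np.array([1] * 50 + [0] * 150)
        features = rng.integers(0, 2, size=(200, 6))
        report = mc.cross_validate(
            mc.ClassifierSpec("random_forest"),
            make_matrix(features, labels),
            mc.CVConfig(n_folds=5, seed=0),
        )
        assert 0.4 <= report.mean_auc <= 0.6

    def test_report_shape_and_average_curve(self):
        rng = np.random.default_rng(5)
        labels = np.array([1] * 40 + [0] * 120)
        features = np.column_stack(
            [labels ^ (rng.random(160) < 0.2), rng.integers(0, 2, 160)]
        ).astype(np.uint8)
        report = mc.cross_validate(
            mc.ClassifierSpec("decision_tree"),
            make_matrix(features, labels),
            mc.CVConfig(n_folds=5, seed=1),
        )
        assert report.mean_auc == pytest.approx(
            np.mean(report.fold_aucs), abs=1e-15
        )
        grid = report.averaged_curve
        assert len(grid.fpr) == 101
        assert grid.tpr[0] == 0.0 and grid.tpr[-1] == 1.0
        assert report.importances is not None
        assert "mean AUC" in report.summary()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        labels = np.array([1] * 30 + [0] * 90)
        features = rng.integers(0, 2, size=(120, 4))
        matrix = make_matrix(features, labels)
        cfg = mc.CVConfig(n_folds=5, seed=9)
        a = mc.cross_validate(mc.ClassifierSpec("adaboost"), matrix, cfg)
        b = mc.cross_validate(mc.ClassifierSpec("adaboost"), matrix, cfg)
        assert a.fold_aucs == b.fold_aucs


class TestGiniImportance:
    def test_informative_feature_dominates(self):
        """One label feature + three pure-noise features: the informative
        one takes > 0.8 of the normalized importance."""
        rng = np.random.default_rng(0)
        labels = np.repeat([1, 0], 500)
        features = np.column_stack(
            [labels] + [rng.integers(0, 2, 1000) for _ in range(3)]
        )
        imp = mc.gini_importance(
            mc.ClassifierSpec("random_forest"),
            make_matrix(features, labels),
            seed=0,
        )
        assert imp["d0"] > 0.8

    def test_duplicated_feature_shares_importance(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([1, 0], 500)
        noise = [rng.integers(0, 2, 1000) for _ in range(3)]
        single = mc.gini_importance(
            mc.ClassifierSpec("random_forest"),
            make_matrix(np.column_stack([labels] + noise), labels),
            seed=0,
        )
        dup = mc.gini_importance(
            mc.ClassifierSpec("random_forest"),
            make_matrix(np.column_stack([labels, labels] + noise), labels),
            seed=0,
        )
        assert abs((dup["d0"] + dup["d1"]) - single["d0"]) < 0.1

    def test_normalization(self):
        rng = np.random.default_rng(2)
        labels = np.array([1] * 40 + [0] * 60)
        features = rng.integers(0, 2, size=(100, 5))
        imp = mc.gini_importance(
            mc.ClassifierSpec("decision_tree"), make_matrix(features, labels)
        )
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_column_permutation_permutes_importances(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([1, 0], 200)
        features = np.column_stack(
            [labels ^ (rng.random(400) < 0.1), rng.integers(0, 2, 400),
             labels ^ (rng.random(400) < 0.4)]
        ).astype(np.uint8)
        matrix = make_matrix(features, labels)
        perm = mc.LabeledFeatureMatrix(
            matrix.region_ids,
            matrix.features[:, ::-1],
            matrix.labels,
            matrix.dataset_ids[::-1],
            matrix.meta[::-1],
        )
        # exact equivariance holds for the full-search decision tree; a
        # seeded random forest ties its per-tree feature subsampling to
        # column order, so it is only approximately equivariant
        spec = mc.ClassifierSpec("decision_tree")
        a = mc.gini_importance(spec, matrix, seed=4)
        b = mc.gini_importance(spec, perm, seed=4)
        for did in matrix.dataset_ids:
            assert b[did] == pytest.approx(a[did], abs=1e-12)

    def test_non_tree_spec_rejected(self):
        matrix = make_matrix(np.array([[1], [0]]), np.array([1, 0]))
        with pytest.raises(mc.ConfigurationError):
            mc.gini_importance(mc.ClassifierSpec("knn"), matrix)


class TestEnhancerModel:
    def test_fit_wires_through(self):
        rng = np.random.default_rng(7)
        labels = np.array([1] * 30 + [0] * 90)
        features = np.column_stack(
            [labels ^ (rng.random(120) < 0.1), rng.integers(0, 2, 120)]
        ).astype(np.uint8)
        model = mc.EnhancerModel(make_matrix(features, labels))
        res = model.fit(cv=mc.CVConfig(n_folds=5, seed=2))
        assert isinstance(res, mc.CVReport)
        assert res.mean_auc > 0.8
        assert res.importances is not None

    def test_plot_roc_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        rng = np.random.default_rng(8)
        labels = np.array([1] * 20 + [0] * 60)
        features = np.column_stack([labels, rng.integers(0, 2, 80)])
        res = mc.EnhancerModel(make_matrix(features, labels)).fit(
            cv=mc.CVConfig(n_folds=4, seed=0)
        )
        ax = res.plot_roc()
        assert ax.get_xlabel() == "False positive rate"


def test_average_curves_grid():
    c1 = mc.roc_and_auc([0.9, 0.1], [1, 0])
    c2 = mc.roc_and_auc([0.2, 0.8], [1, 0])
    avg = average_curves([c1, c2])
    assert len(avg.fpr) == 101
    assert avg.tpr[0] == 0.0 and avg.tpr[-1] == 1.0


def test_default_hyperparams_match_contract():
    assert DEFAULT_HYPERPARAMS["linear_svm"] == {"penalty": "l2", "C": 0.1}
    assert DEFAULT_HYPERPARAMS["knn"] == {"k": 3}
    assert DEFAULT_HYPERPARAMS["adaboost"]["n_estimators"] == 50
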
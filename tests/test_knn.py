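"""KNN pipeline tests: feature extraction, prediction vs independent
oracles, cross-validation behavior, EI closed form, Bayesian optimization."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.neighbors import KNeighborsClassifier

from emgintent import knn
from emgintent.knn import (
    DEFAULT_CONFIG,
    FeatureVector,
    KNNConfig,
    bayes_optimize,
    build_feature_matrix,
    cross_validate,
    expected_improvement,
    knn_predict,
)
from emgintent.types import ALL_CLASSES, MotionClass


# ---------------------------------------------------------------- features
class TestFeatureExtraction:
    def test_one_vector_per_class_with_fixed_length(self, mini_dataset):
        extraction = build_feature_matrix(mini_dataset.recordings, seed=0)
        assert len(extraction.features) + extraction.n_excluded == 12
        assert len(extraction.features) >= 10
        assert all(len(f.values) == 12 for f in extraction.features)

    def test_agonist_onset_slope_reflects_rise_rate(self, mini_dataset):
        extraction = build_feature_matrix(mini_dataset.recordings, seed=0)
        by_label = {f.label: f for f in extraction.features}
        fast = by_label.get(MotionClass("elbow_flexion", "fast"))
        slow = by_label.get(MotionClass("elbow_flexion", "slow"))
        assert fast is not None and slow is not None
        # biceps = channel 1; onset slope at feature index 2*1
        assert fast.values[2] > 0
        assert fast.values[2] > 1.5 * slow.values[2]
        # offset slope is a decay
        assert fast.values[3] < 0

    def test_quiescent_trial_excluded(self, quiet_trial):
        extraction = build_feature_matrix([quiet_trial], n_range=(1, 2), seed=0)
        assert extraction.features == []
        assert extraction.excluded == ["quiet"]


# ---------------------------------------------------------------- predict
def brute_force_predict(train, labels, query, cfg):
    """Independent oracle: full distance sort + explicit vote table."""
    metric = "cityblock" if cfg.metric == "cityblock" else "euclidean"
    d = cdist(train, query[None, :], metric=metric).ravel()
    order = np.argsort(d, kind="stable")[: cfg.k]
    votes = {}
    for i in order:
        wgt = 1.0 if cfg.weighting == "uniform" else 1.0 / (d[i] + 1e-12)
        votes.setdefault(labels[i], [0.0, []])
        votes[labels[i]][0] += wgt
        votes[labels[i]][1].append(d[i])
    return min(
        votes,
        key=lambda lab: (-votes[lab][0], np.mean(votes[lab][1]), lab),
    )


class TestKNNPredict:
    def test_query_equal_to_training_point(self):
        train = np.array([[0.0, 0.0], [5.0, 5.0]])
        labels = np.array([3, 7])
        assert knn_predict(train, labels, np.array([5.0, 5.0]), KNNConfig(1)) == 7

    def test_equal_distance_majority_vote(self):
        train = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        labels = np.array([0, 0, 1])
        got = knn_predict(train, labels, np.zeros(2), KNNConfig(3, "euclidean", "uniform"))
        assert got == 0

    def test_cityblock_metric_ranking(self):
        # city-block distance |3| + |4| = 7 ranks behind euclidean-closer point
        train = np.array([[3.0, 4.0], [0.0, 6.0]])
        labels = np.array([1, 2])
        got = knn_predict(train, labels, np.zeros(2), KNNConfig(1, "cityblock"))
        assert got == 2  # cityblock 6 < 7

    @pytest.mark.parametrize("metric", ["euclidean", "cityblock"])
    @pytest.mark.parametrize("weighting", ["uniform", "inverse_distance"])
    def test_matches_brute_force_oracle(self, metric, weighting):
        rng = np.random.default_rng(0)
        train = rng.standard_normal((200, 5))
        labels = rng.integers(0, 4, size=200)
        cfg = KNNConfig(7, metric, weighting)
        for _ in range(25):
            q = rng.standard_normal(5)
            assert knn_predict(train, labels, q, cfg) == brute_force_predict(
                train, labels, q, cfg
            )

    def test_agrees_with_sklearn_on_continuous_data(self):
        rng = np.random.default_rng(1)
        train = rng.standard_normal((150, 4))
        labels = rng.integers(0, 3, size=150)
        queries = rng.standard_normal((40, 4))
        ours = [
            knn_predict(train, labels, q, KNNConfig(5, "euclidean", "inverse_distance"))
            for q in queries
        ]
        ref = (
            KNeighborsClassifier(n_neighbors=5, weights="distance")
            .fit(train, labels)
            .predict(queries)
        )
        assert np.array_equal(ours, ref)

    def test_rejects_k_larger_than_training_set(self):
        with pytest.raises(ValueError):
            knn_predict(np.zeros((3, 2)), np.zeros(3), np.zeros(2), KNNConfig(5))


# ---------------------------------------------------------------- CV
def toy_features(n_subjects=3, per_class=5, gap=10.0, noise=0.1, seed=0, shuffle_labels=False):
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((12, 12)) * gap
    feats = []
    for s in range(n_subjects):
        for label in ALL_CLASSES:
            for r in range(per_class):
                v = centers[label.class_id] + noise * rng.standard_normal(12)
                feats.append(
                    FeatureVector(f"S{s}-{label.class_id}-{r}", f"S{s}", label, v)
                )
    if shuffle_labels:
        labels = [f.label for f in feats]
        perm = rng.permutation(len(labels))
        feats = [
            FeatureVector(f.trial_id, f.subject_id, labels[perm[i]], f.values)
            for i, f in enumerate(feats)
        ]
    return feats


class TestCrossValidate:
    def test_perfectly_separable_classes_reach_full_accuracy(self):
        cv = cross_validate(toy_features(gap=10.0, noise=0.1), KNNConfig(3))
        assert cv.mean_accuracy == 1.0

    def test_label_permutation_near_chance(self):
        feats = toy_features(n_subjects=3, per_class=5, shuffle_labels=True, seed=2)
        cv = cross_validate(feats, DEFAULT_CONFIG, seed=2)
        n = 3 * 12 * 5
        se = np.sqrt((1 / 12) * (11 / 12) / n)
        assert abs(cv.mean_accuracy - 1 / 12) < 3 * se + 0.02

    def test_confusion_totals_match_predictions(self):
        feats = toy_features()
        cv = cross_validate(feats, KNNConfig(3), repeats=2)
        assert cv.confusion.sum() == 2 * len(feats)

    def test_fold_mean_equals_mean_accuracy(self):
        cv = cross_validate(toy_features(), KNNConfig(3))
        assert cv.mean_accuracy == pytest.approx(np.mean(cv.fold_accuracies))

    def test_rejects_single_subject(self):
        feats = [f for f in toy_features() if f.subject_id == "S0"]
        with pytest.raises(ValueError):
            cross_validate(feats, KNNConfig(3))

    def test_holdout_accuracy_on_separable_data(self):
        acc = knn.holdout_accuracy(toy_features(), KNNConfig(3), fraction=0.1, seed=0)
        assert acc == 1.0


# ---------------------------------------------------------------- EI + BO
class TestExpectedImprovement:
    def test_no_improvement_at_best_with_zero_sigma(self):
        assert expected_improvement(0.5, 0.0, 0.5) == 0.0

    def test_certain_improvement(self):
        assert expected_improvement(best=0.5, mu=0.5 - 10, sigma=0.0) == pytest.approx(10.0)

    def test_standard_normal_value(self):
        # E[max(0, -Z)] for Z ~ N(0,1) = 1/sqrt(2*pi)
        assert expected_improvement(0.0, 1.0, 0.0) == pytest.approx(0.3989, abs=1e-4)

    @pytest.mark.parametrize("mu,sigma,best", [(0.3, 0.1, 0.25), (0.1, 0.05, 0.2), (0.5, 0.3, 0.4)])
    def test_matches_monte_carlo(self, mu, sigma, best):
        rng = np.random.default_rng(42)
        draws = rng.normal(mu, sigma, size=1_000_000)
        imp = np.maximum(0.0, best - draws)
        mc_se = imp.std() / 1000.0
        assert abs(expected_improvement(mu, sigma, best) - imp.mean()) < 3 * mc_se

    def test_rejects_negative_sigma(self):
        with pytest.raises(ValueError):
            expected_improvement(0.0, -1.0, 0.0)


@pytest.fixture(scope="module")
def separable():
    return toy_features(n_subjects=2, per_class=3, gap=5.0, noise=0.5, seed=3)


class TestBayesOptimize:
    def test_best_no_worse_than_default(self, separable):
        trace = bayes_optimize(separable, budget=12, seed=0)
        default_val = trace.evaluated[0][1]
        assert trace.evaluated[0][0] == DEFAULT_CONFIG
        assert trace.best_value <= default_val

    def test_best_so_far_non_increasing(self, separable):
        trace = bayes_optimize(separable, budget=12, seed=0)
        bsf = trace.best_so_far
        assert np.all(np.diff(bsf) <= 0)
        assert trace.best_value == bsf[-1]

    def test_degenerate_space_returns_only_k(self, separable):
        trace = bayes_optimize(separable, budget=5, seed=1, k_range=(4, 4))
        assert trace.best_config.k == 4
        assert trace.iterations <= 5
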
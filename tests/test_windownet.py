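"""Rolling-window classifier tests: window features, training behavior,
probability series, confident-onset rule and lead times."""

from types import SimpleNamespace

import numpy as np
import pytest

from emgintent import study, windownet
from emgintent.changepoint import STATUS_LOW_CONTRAST, ChangePointSet
from emgintent.synth import DEFAULT_CONFIG, GeneratorConfig
from emgintent.types import EMGTrial, MotionClass
from emgintent.windownet import (
    STATUS_CONFIDENT,
    STATUS_CP_INCONCLUSIVE,
    STATUS_NOT_REACHED,
    ClassProbabilitySeries,
    NetworkSpec,
    build_window_dataset,
    confident_onset,
    curate_training_windows,
    lead_time,
    predict_series,
    rolling_window_features,
    train_network,
)


def make_trial(samples, label=MotionClass("elbow_flexion", "fast")):
    return EMGTrial(subject_id="S", label=label, samples=samples, trial_id="t")


class TestRollingWindows:
    def test_window_count_arithmetic(self):
        trial = make_trial(np.zeros((6, 1000)))
        feats, times = rolling_window_features(trial, 150, 1)
        assert len(feats) == 851

    def test_single_window_at_full_stride(self):
        trial = make_trial(np.zeros((6, 1000)))
        feats, _ = rolling_window_features(trial, 1000, 1)
        assert len(feats) == 1

    def test_exact_line_recovers_slope(self):
        t_ms = np.arange(1200)
        samples = np.vstack([m * t_ms / 1000.0 for m in range(1, 7)])  # mV, slope m mV/s
        feats, _ = rolling_window_features(make_trial(samples), 150, 75)
        assert np.allclose(feats, np.arange(1, 7)[None, :], atol=1e-9)

    def test_timestamps_at_window_end(self):
        trial = make_trial(np.zeros((6, 1000)))
        _, times = rolling_window_features(trial, 150, 10)
        assert times[0] == 150.0
        assert np.all(np.diff(times) == 10.0)

    def test_rejects_window_longer_than_trial(self):
        with pytest.raises(ValueError):
            rolling_window_features(make_trial(np.zeros((6, 1000))), 2000, 1)


class TestNetworkSpec:
    def test_rejects_wrong_layer_count(self):
        with pytest.raises(ValueError):
            NetworkSpec(layer_sizes=(6, 64, 12))

    def test_hidden_sizes(self):
        assert NetworkSpec().hidden_sizes == (64, 64, 32, 16)


def separable_windows(seed=0, n=400):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 6)) * 0.05
    y = rng.integers(0, 2, size=n)
    X[y == 1] += 2.0
    return X, y


class TestTraining:
    def test_separable_classes_learned(self):
        X, y = separable_windows()
        model = train_network(X, y, NetworkSpec(epochs=50))
        acc = (model.predict_proba(X).argmax(axis=1) == y).mean()
        assert acc >= 0.99

    def test_shuffled_labels_stay_near_chance_on_holdout(self):
        X, y = separable_windows(seed=1, n=600)
        y_shuffled = np.random.default_rng(2).permutation(y)
        model = train_network(X[:400], y_shuffled[:400], NetworkSpec(epochs=30))
        acc = (model.predict_proba(X[400:]).argmax(axis=1) == y_shuffled[400:]).mean()
        assert acc < 0.7

    def test_same_seed_identical_weights(self):
        X, y = separable_windows()
        m1 = train_network(X, y, NetworkSpec(epochs=5, seed=3))
        m2 = train_network(X, y, NetworkSpec(epochs=5, seed=3))
        for a, b in zip(m1.mlp.coefs_, m2.mlp.coefs_):
            assert np.array_equal(a, b)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            train_network(np.zeros((10, 6)), np.zeros(10), NetworkSpec())

    def test_curation_keeps_active_windows(self):
        rng = np.random.default_rng(0)
        X = 0.05 * rng.standard_normal((400, 6))
        X[:80] += 5.0  # high activity
        mask = curate_training_windows(X, np.zeros(400), seed=0)
        assert mask[:80].all()
        assert mask[80:].mean() < 0.4


class TestPredictSeries:
    def test_rows_on_simplex(self, burst_trial):
        X, y = separable_windows()
        y12 = np.where(y == 1, 11, 0)
        model = train_network(X, y12, NetworkSpec(epochs=5))
        series = predict_series(model, burst_trial, 150, 25)
        assert np.allclose(series.probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(series.probs >= 0)

    def test_uniform_dummy_model(self, burst_trial):
        dummy = SimpleNamespace(
            predict_proba=lambda f: np.full((len(f), 12), 1.0 / 12)
        )
        series = predict_series(dummy, burst_trial, 150, 50)
        assert np.allclose(series.probs, 1.0 / 12)

    def test_causality_under_truncation(self, burst_trial):
        X, y = separable_windows()
        model = train_network(X, np.where(y == 1, 11, 0), NetworkSpec(epochs=5))
        full = predict_series(model, burst_trial, 150, 10)
        cut = EMGTrial(
            subject_id=burst_trial.subject_id,
            label=burst_trial.label,
            samples=burst_trial.samples[:, :1500],
            trial_id="cut",
        )
        truncated = predict_series(model, cut, 150, 10)
        n = len(truncated.probs)
        assert np.array_equal(full.probs[:n], truncated.probs)


def series_from(probs):
    probs = np.asarray(probs, float)
    times = 10.0 * (np.arange(len(probs)) + 1)
    return ClassProbabilitySeries(times, probs)


class TestConfidentOnset:
    def test_sustained_dominance_found_at_first_window_of_run(self):
        probs = np.full((200, 12), 1.0 / 12)
        probs[100:] = 0.01
        probs[100:, 3] = 1.0 - 0.11
        series = series_from(probs / probs.sum(axis=1, keepdims=True))
        onset = confident_onset(series, MotionClass.from_id(3))
        assert onset.status == STATUS_CONFIDENT
        assert onset.time_ms == series.times_ms[100]

    def test_uniform_series_never_confident(self):
        series = series_from(np.full((50, 12), 1.0 / 12))
        assert confident_onset(series, MotionClass.from_id(0)).status == STATUS_NOT_REACHED

    def test_single_window_blip_rejected_by_persistence(self):
        probs = np.full((50, 12), 1.0 / 12)
        probs[10] = 0.01
        probs[10, 5] = 1.0 - 0.11
        series = series_from(probs / probs.sum(axis=1, keepdims=True))
        onset = confident_onset(series, MotionClass.from_id(5), persistence=5)
        assert onset.status == STATUS_NOT_REACHED

    def test_margin_requirement(self):
        probs = np.full((50, 12), 0.08)
        probs[:, 2] = 0.09  # dominant but below margin over runner-up
        probs /= probs.sum(axis=1, keepdims=True)
        onset = confident_onset(series_from(probs), MotionClass.from_id(2), 0.05)
        assert onset.status == STATUS_NOT_REACHED


def cps(indices, deltas, status="ok"):
    return ChangePointSet(
        indices=np.asarray(indices),
        total_cost=1.0,
        flank_window=100,
        rms_deltas=np.asarray(deltas, float),
        status=status,
    )


class TestLeadTime:
    def test_signed_arithmetic(self):
        onset = windownet.PredictionOnset(STATUS_CONFIDENT, 490.0)
        rec = lead_time(onset, cps([500], [1.0]))
        assert rec.status == STATUS_CONFIDENT
        assert rec.lead_ms == pytest.approx(10.0)

    def test_uncertain_onset_propagates(self):
        rec = lead_time(windownet.PredictionOnset(STATUS_NOT_REACHED), cps([500], [1.0]))
        assert rec.status == STATUS_NOT_REACHED
        assert rec.lead_ms is None

    def test_low_contrast_changepoints_take_precedence(self):
        onset = windownet.PredictionOnset(STATUS_CONFIDENT, 490.0)
        rec = lead_time(onset, cps([500], [1.0], status=STATUS_LOW_CONTRAST))
        assert rec.status == STATUS_CP_INCONCLUSIVE


class TestPreactivationSensitivity:
    def test_ramp_ablation_reduces_mean_lead(self):
        """With 50 ms pre-activation ramps and margin 0, the network's
        confident predictions lead the change point on average; removing
        the pre-onset ramp reduces the mean lead."""
        with_ramp = study.lead_time_study(
            seed=13, trials_per_class=4, dominance_margin=0.0
        )
        without = study.lead_time_study(
            seed=13,
            trials_per_class=4,
            dominance_margin=0.0,
            generator_config=GeneratorConfig(preactivation_lead_ms=0.0),
        )
        assert with_ramp.mean_lead_ms is not None
        assert with_ramp.mean_lead_ms > 0
        assert without.mean_lead_ms is None or without.mean_lead_ms < with_ramp.mean_lead_ms
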
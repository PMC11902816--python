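"""End-to-end study protocols on synthetic data.

Each function regenerates its inputs from a seed and runs one stage of the
analysis at desk scale: change-point onset localization, the slope-feature
KNN pipeline (default and Bayesian-optimized), and the rolling-window
network's lead-time analysis. They are the single source for both the
acceptance checks and the reporting CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import changepoint as cp
from . import knn, sigproc, synth, windownet
from .reporting import MotionLeadSummary, global_lead_stats, summarize_lead_times
from .types import ALL_CLASSES, SAMPLE_RATE_HZ, EMGTrial
from .windownet import LeadTimeRecord


def _summed_envelope(trial: EMGTrial, smooth_ms: float = 50.0) -> np.ndarray:
    envs = sigproc.preprocess_trial(trial, smooth_ms)
    return np.sum([e.samples for e in envs], axis=0)


def dataset_shape_study(seed: int = 0) -> Dict[str, int]:
    """Protocol arithmetic: one subject, 12 classes x 25 repetitions."""
    ds = synth.generate_dataset(n_subjects=1, trials_per_class=25, seed=seed)
    return {
        "n_motion_trials": ds.n_motion_trials,
        "n_recordings": ds.n_recordings,
    }


def localization_study(
    seed: int = 0,
    n_recordings: int = 100,
    n_cycles: int = 5,
    w: int = cp.DEFAULT_FLANK_WINDOW,
    n_range: Tuple[int, int] = (8, 12),
) -> Dict[str, float]:
    """Mean absolute offset (ms) between detected change points and
    ground-truth electrical onsets over ``n_recordings`` multi-burst
    recordings spanning all 12 classes."""
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    synergy = synth.make_default_synergy(seed)
    profile = synth.sample_profile("S01", rng)
    duration = n_cycles * (synth.DEFAULT_CONFIG.gap_s[1] + 0.8) + 0.5

    errors: List[float] = []
    for i in range(n_recordings):
        label = ALL_CLASSES[i % len(ALL_CLASSES)]
        trial = synth.generate_trial(
            label,
            profile,
            synergy,
            n_cycles=n_cycles,
            duration_s=duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        total = _summed_envelope(trial)
        cps = cp.detect_change_points(total, n_range, w=w, seed=i)
        detected_ms = cps.times_ms
        for onset_ms in trial.ground_truth.electrical_onsets_ms:
            errors.append(float(np.min(np.abs(detected_ms - onset_ms))))
    return {
        "mean_abs_offset_ms": float(np.mean(errors)),
        "n_onsets": len(errors),
    }


@dataclass
class KNNStudyResult:
    default_accuracy_pct: float
    default_sd_pct: float
    optimized_accuracy_pct: float
    optimized_sd_pct: float
    best_config: knn.KNNConfig
    n_features: int
    n_excluded: int
    confusion: np.ndarray


def knn_study(
    seed: int = 0,
    n_subjects: int = 6,
    trials_per_class: int = 25,
    budget: int = 30,
) -> KNNStudyResult:
    """Subject-wise 6-fold CV of the slope-feature KNN pipeline with the
    default configuration (k=10, Euclidean, uniform votes), then after GP
    Bayesian optimization of (k, metric, weighting)."""
    ds = synth.generate_dataset(n_subjects, trials_per_class, seed=seed)
    extraction = knn.build_feature_matrix(ds.recordings, seed=seed)
    features = extraction.features

    default_cv = knn.cross_validate(features, knn.DEFAULT_CONFIG, seed=seed)
    trace = knn.bayes_optimize(features, budget=budget, seed=seed)
    best_cv = knn.cross_validate(features, trace.best_config, seed=seed)
    return KNNStudyResult(
        default_accuracy_pct=100.0 * default_cv.mean_accuracy,
        default_sd_pct=100.0 * default_cv.sd_accuracy,
        optimized_accuracy_pct=100.0 * best_cv.mean_accuracy,
        optimized_sd_pct=100.0 * best_cv.sd_accuracy,
        best_config=trace.best_config,
        n_features=len(features),
        n_excluded=extraction.n_excluded,
        confusion=best_cv.confusion,
    )


@dataclass
class LeadTimeStudyResult:
    mean_lead_ms: Optional[float]
    sd_lead_ms: Optional[float]
    n_confident: int
    n_test_trials: int
    records: List[LeadTimeRecord]
    summaries: List[MotionLeadSummary]


def lead_time_study(
    seed: int = 0,
    n_subjects: int = 2,
    trials_per_class: int = 6,
    window_len: int = windownet.DEFAULT_WINDOW_LEN,
    train_stride: int = 5,
    eval_stride: int = 1,
    epochs: int = 10,
    train_fraction: float = 2.0 / 3.0,
    dominance_margin: float = windownet.DEFAULT_DOMINANCE_MARGIN,
    persistence: int = windownet.DEFAULT_PERSISTENCE,
    generator_config: synth.GeneratorConfig = synth.DEFAULT_CONFIG,
) -> LeadTimeStudyResult:
    """Train the 7-layer window classifier on per-window OLS slopes and
    measure, per held-out trial, the lead of its first confident prediction
    over the detected myoelectric change point.

    Single-burst trials; the split is stratified by class and grouped by
    trial so overlapping windows never straddle the split.
    """
    ds = synth.generate_dataset(
        n_subjects,
        trials_per_class,
        seed=seed,
        config=generator_config,
        cycles_per_recording=1,
    )
    trials = ds.recordings
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    by_class: Dict[int, List[int]] = {}
    for i, t in enumerate(trials):
        by_class.setdefault(t.label.class_id, []).append(i)
    train_idx, test_idx = [], []
    for idx in by_class.values():
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])

    train_set = windownet.build_window_dataset(
        [trials[i] for i in train_idx], window_len, train_stride
    )
    mask = windownet.curate_training_windows(
        train_set.features, train_set.labels, seed=seed % 2**31
    )
    spec = windownet.NetworkSpec(epochs=epochs, seed=seed % 2**31)
    model = windownet.train_network(
        train_set.features[mask], train_set.labels[mask], spec
    )

    records: List[LeadTimeRecord] = []
    for i in test_idx:
        trial = trials[i]
        series = windownet.predict_series(model, trial, window_len, eval_stride)
        onset = windownet.confident_onset(
            series, trial.label, dominance_margin, persistence
        )
        total = _summed_envelope(trial)
        cps = cp.detect_change_points(total, (1, 4), seed=i)
        records.append(windownet.lead_time(onset, cps, trial.trial_id, trial.label))

    mean_ms, sd_ms, n_conf = global_lead_stats(records)
    return LeadTimeStudyResult(
        mean_lead_ms=mean_ms,
        sd_lead_ms=sd_ms,
        n_confident=n_conf,
        n_test_trials=len(test_idx),
        records=records,
        summaries=summarize_lead_times(records),
    )
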
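"""Slope-feature KNN classification of the 12 motion classes.

Feature vectors are per-recording: change points are detected once on the
across-channel sum of envelopes, split into onsets (rising RMS) and offsets
(falling RMS), and the envelope slope at each is read off every channel;
onset and offset slopes are averaged across the recording's activation
cycles, giving a fixed 12-entry vector (6 channels x {onset, offset}).

Classification is k-nearest-neighbor with Euclidean or city-block distance
and uniform or inverse-distance vote weighting, evaluated by
leave-one-subject-out cross-validation. Hyperparameters are tuned by
Gaussian-process Bayesian optimization with the Expected Improvement
acquisition, minimizing the cross-validated misclassification rate over the
full enumerable configuration space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from . import changepoint as cp
from . import sigproc
from .types import N_CHANNELS, N_CLASSES, EMGTrial, MotionClass

#: Guard in inverse-distance vote weights.
WEIGHT_EPS = 1e-12

METRICS = ("euclidean", "cityblock")
WEIGHTINGS = ("uniform", "inverse_distance")


@dataclass(frozen=True)
class KNNConfig:
    k: int = 10
    metric: str = "euclidean"
    weighting: str = "uniform"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric: {self.metric!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting: {self.weighting!r}")


DEFAULT_CONFIG = KNNConfig()
#: Reference tuned configuration: k=8, city-block, inverse-distance votes.
OPTIMIZED_REFERENCE_CONFIG = KNNConfig(8, "cityblock", "inverse_distance")


@dataclass
class FeatureVector:
    trial_id: str
    subject_id: str
    label: MotionClass
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        self.values = v


@dataclass
class FeatureExtraction:
    """Feature vectors plus the recordings excluded as inconclusive."""

    features: List[FeatureVector]
    excluded: List[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def extract_features(
    trial: EMGTrial,
    n_range: Tuple[int, int],
    w: int = cp.DEFAULT_FLANK_WINDOW,
    fit_window: int = 50,
    smooth_ms: float = 50.0,
    grid_step: int = cp.DEFAULT_GRID_STEP,
    seed: int = 0,
) -> Optional[FeatureVector]:
    """Slope features of one recording, or None when change-point detection
    is inconclusive (low contrast or single-sided)."""
    envs = sigproc.preprocess_trial(trial, smooth_ms)
    total = np.sum([e.samples for e in envs], axis=0)
    cps = cp.detect_change_points(total, n_range, w=w, grid_step=grid_step, seed=seed)
    if cps.status != cp.STATUS_OK:
        return None
    onsets, offsets = cps.onset_indices, cps.offset_indices
    if len(onsets) == 0 or len(offsets) == 0:
        return None
    values = np.empty(2 * N_CHANNELS)
    for c in range(N_CHANNELS):
        on = [cp.slope_at(envs[c], i, fit_window, channel=c).slope for i in onsets]
        off = [cp.slope_at(envs[c], i, fit_window, channel=c).slope for i in offsets]
        values[2 * c] = np.mean(on)
        values[2 * c + 1] = np.mean(off)
    return FeatureVector(trial.trial_id, trial.subject_id, trial.label, values)


def build_feature_matrix(
    trials: Sequence[EMGTrial],
    n_range: Optional[Tuple[int, int]] = None,
    **kwargs,
) -> FeatureExtraction:
    """One feature vector per recording; inconclusive recordings are
    excluded and reported. ``n_range`` defaults to a window around twice
    the recording's cycle count (one onset + one offset per cycle)."""
    features, excluded = [], []
    for trial in trials:
        if n_range is None:
            n_cycles = (
                len(trial.ground_truth.electrical_onsets_ms)
                if trial.ground_truth is not None
                else 1
            )
            rng_n = (max(2 * n_cycles - 2, 1), 2 * n_cycles + 2)
        else:
            rng_n = n_range
        fv = extract_features(trial, rng_n, **kwargs)
        if fv is None:
            excluded.append(trial.trial_id)
        else:
            features.append(fv)
    return FeatureExtraction(features, excluded)


def _distances(train: np.ndarray, query: np.ndarray, metric: str) -> np.ndarray:
    diff = train - query[None, :]
    if metric == "euclidean":
        return np.sqrt(np.sum(diff * diff, axis=1))
    return np.sum(np.abs(diff), axis=1)


def knn_predict(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    query: np.ndarray,
    cfg: KNNConfig = DEFAULT_CONFIG,
) -> int:
    """Class id with the largest (weighted) vote among the k nearest
    training points. Ties break to the smallest mean neighbor distance,
    then to the lowest class id."""
    if len(train_values) < cfg.k:
        raise ValueError("k exceeds the training-set size")
    d = _distances(np.asarray(train_values, float), np.asarray(query, float), cfg.metric)
    nn = np.argsort(d, kind="stable")[: cfg.k]
    labels = np.asarray(train_labels)[nn]
    dists = d[nn]
    weights = (
        np.ones(cfg.k) if cfg.weighting == "uniform" else 1.0 / (dists + WEIGHT_EPS)
    )
    votes: Dict[int, float] = {}
    mean_d: Dict[int, float] = {}
    for lab in np.unique(labels):
        m = labels == lab
        votes[int(lab)] = float(weights[m].sum())
        mean_d[int(lab)] = float(dists[m].mean())
    # max vote, then min mean distance, then lowest class id
    return min(votes, key=lambda lab: (-votes[lab], mean_d[lab], lab))


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    confusion: np.ndarray
    repeats: int
    fold_subjects: List[str]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0


def _standardize(train: np.ndarray, test: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """z-score both sets with training-fold statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def cross_validate(
    features: Sequence[FeatureVector],
    cfg: KNNConfig = DEFAULT_CONFIG,
    repeats: int = 1,
    seed: int = 0,
) -> CVResult:
    """Leave-one-subject-out cross-validation.

    Subject-defined folds are deterministic; repeats re-randomize only the
    training-set presentation order, which can flip exact-tie votes.
    """
    subjects = sorted({f.subject_id for f in features})
    if len(subjects) < 2:
        raise ValueError("subject-wise CV needs at least 2 subjects")
    values = np.array([f.values for f in features])
    labels = np.array([f.label.class_id for f in features])
    subj = np.array([f.subject_id for f in features])
    rng = np.random.default_rng(seed)

    fold_acc = []
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for _ in range(repeats):
        for s in subjects:
            test_m = subj == s
            train_v, train_l = values[~test_m], labels[~test_m]
            order = rng.permutation(len(train_v))
            train_v, train_l = train_v[order], train_l[order]
            tr, te = _standardize(train_v, values[test_m])
            pred = np.array([knn_predict(tr, train_l, q, cfg) for q in te])
            truth = labels[test_m]
            fold_acc.append(float(np.mean(pred == truth)))
            for t, p in zip(truth, pred):
                confusion[t, p] += 1
    return CVResult(np.array(fold_acc), confusion, repeats, subjects)


def holdout_accuracy(
    features: Sequence[FeatureVector],
    cfg: KNNConfig,
    fraction: float = 0.1,
    seed: int = 0,
) -> float:
    """Final stratified holdout evaluation after tuning: ``fraction`` of the
    data (rounded to the nearest integer per class) is held out, the rest
    trains the classifier."""
    values = np.array([f.values for f in features])
    labels = np.array([f.label.class_id for f in features])
    rng = np.random.default_rng(seed)
    test_idx = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_hold = max(int(round(fraction * len(idx))), 1)
        test_idx.extend(rng.choice(idx, size=n_hold, replace=False))
    test_m = np.zeros(len(labels), dtype=bool)
    test_m[test_idx] = True
    tr, te = _standardize(values[~test_m], values[test_m])
    pred = np.array([knn_predict(tr, labels[~test_m], q, cfg) for q in te])
    return float(np.mean(pred == labels[test_m]))


def expected_improvement(mu: float, sigma: float, best: float) -> float:
    """Expected Improvement for minimization: E[max(0, best - X)] with
    X ~ Normal(mu, sigma^2); the closed form is
    (best - mu) * Phi(z) + sigma * phi(z), z = (best - mu) / sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return max(0.0, best - mu)
    z = (best - mu) / sigma
    return float((best - mu) * norm.cdf(z) + sigma * norm.pdf(z))


def _encode(cfg: KNNConfig) -> np.ndarray:
    """Encode a configuration for the GP surrogate: scaled k plus one-hot
    metric and weighting."""
    return np.array(
        [
            cfg.k / 30.0,
            float(cfg.metric == "cityblock"),
            float(cfg.weighting == "inverse_distance"),
        ]
    )


@dataclass
class BayesOptTrace:
    evaluated: List[Tuple[KNNConfig, float]]
    best_config: KNNConfig
    best_value: float
    iterations: int

    @property
    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate([v for _, v in self.evaluated])


def bayes_optimize(
    features: Sequence[FeatureVector],
    budget: int = 30,
    seed: int = 0,
    k_range: Tuple[int, int] = (1, 30),
    cv_repeats: int = 1,
    n_initial: int = 6,
) -> BayesOptTrace:
    """GP Bayesian optimization of the KNN hyperparameters.

    The objective is the misclassification rate of subject-wise CV. The
    search space (k x metric x weighting) is small enough to enumerate, so
    the EI acquisition is maximized exactly over all unevaluated
    configurations. The initial design contains the default configuration
    plus random configurations.
    """
    if budget < 5:
        raise ValueError("budget must be >= 5")
    rng = np.random.default_rng(seed)
    space = [
        KNNConfig(k, m, wt)
        for k, m, wt in itertools.product(
            range(k_range[0], k_range[1] + 1), METRICS, WEIGHTINGS
        )
    ]

    def objective(cfg: KNNConfig) -> float:
        return 1.0 - cross_validate(features, cfg, repeats=cv_repeats, seed=seed).mean_accuracy

    evaluated: List[Tuple[KNNConfig, float]] = []
    seen = set()

    def evaluate(cfg: KNNConfig) -> None:
        evaluated.append((cfg, objective(cfg)))
        seen.add(cfg)

    evaluate(DEFAULT_CONFIG if DEFAULT_CONFIG in space else space[0])
    n_init = min(n_initial, budget, len(space))
    for i in rng.permutation(len(space)):
        if len(evaluated) >= n_init:
            break
        if space[i] not in seen:
            evaluate(space[i])

    # fixed kernel hyperparameters: the encoded space is bounded and tiny, so
    # a preset squared-exponential with jitter is stable and deterministic
    kernel = ConstantKernel(1.0, "fixed") * RBF(
        length_scale=[0.3, 1.0, 1.0], length_scale_bounds="fixed"
    ) + WhiteKernel(noise_level=1e-4, noise_level_bounds="fixed")
    while len(evaluated) < min(budget, len(space)):
        X = np.array([_encode(c) for c, _ in evaluated])
        y = np.array([v for _, v in evaluated])
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=seed)
        gp.fit(X, y)
        best = float(y.min())
        remaining = [c for c in space if c not in seen]
        if not remaining:
            break
        Xr = np.array([_encode(c) for c in remaining])
        mu, sd = gp.predict(Xr, return_std=True)
        ei = np.array(
            [expected_improvement(m, s, best) for m, s in zip(mu, sd)]
        )
        evaluate(remaining[int(np.argmax(ei))])

    best_cfg, best_val = min(evaluated, key=lambda cv: cv[1])
    return BayesOptTrace(evaluated, best_cfg, best_val, len(evaluated))
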
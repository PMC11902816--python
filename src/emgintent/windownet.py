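"""Rolling-window neural classification and lead-time analysis.

Raw (unfiltered) 6-channel sEMG is segmented into rolling windows; each
window is reduced to six per-channel ordinary-least-squares slope
coefficients (mV/s), which feed a seven-layer feed-forward classifier:
input (6 features) -> four fully connected ReLU hidden layers
(64, 64, 32, 16) -> pre-classification linear layer (12) -> softmax
classification layer. Window timestamps are taken at the window end, so
every prediction is causal.

The per-window class-probability trajectories yield a trial's "confident
onset": the earliest time where the true class strictly dominates all
others by at least a margin, sustained over a persistence run. The lead
time is the first agonist change-point time minus that onset time —
positive when the network anticipates the myoelectric change point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .changepoint import STATUS_LOW_CONTRAST, ChangePointSet
from .types import N_CHANNELS, N_CLASSES, SAMPLE_RATE_HZ, EMGTrial, MotionClass

STATUS_CONFIDENT = "confident"
STATUS_NOT_REACHED = "certainty_not_reached"
STATUS_CP_INCONCLUSIVE = "changepoint_inconclusive"

DEFAULT_WINDOW_LEN = 150
DEFAULT_DOMINANCE_MARGIN = 0.05
DEFAULT_PERSISTENCE = 5


@dataclass(frozen=True)
class NetworkSpec:
    """Seven-layer architecture: widths from the input feature count to the
    12-class softmax output."""

    layer_sizes: Tuple[int, ...] = (6, 64, 64, 32, 16, 12, 12)
    activation: str = "relu"
    epochs: int = 10
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) != 7:
            raise ValueError("the network has exactly 7 layers")
        if self.layer_sizes[-1] != N_CLASSES or self.layer_sizes[-2] != N_CLASSES:
            raise ValueError("final linear and classification layers must be 12 wide")

    @property
    def hidden_sizes(self) -> Tuple[int, ...]:
        return self.layer_sizes[1:-2]


def _window_slopes(segment: np.ndarray) -> np.ndarray:
    """Per-channel OLS slope of a (6, L) raw segment, in mV/s."""
    n = segment.shape[1]
    t = np.arange(n) / SAMPLE_RATE_HZ
    tc = t - t.mean()
    denom = float(np.sum(tc * tc))
    return (segment - segment.mean(axis=1, keepdims=True)) @ tc / denom


def rolling_window_features(
    trial: EMGTrial, window_len: int = DEFAULT_WINDOW_LEN, stride: int = 1
) -> Tuple[np.ndarray, np.ndarray]:
    """All rolling-window slope features of a trial.

    Returns ``(features, end_times_ms)`` with ``features`` of shape
    (n_windows, 6) and one row per window; the window ending at sample e
    covers [e - window_len, e) and is stamped at time e (causal).
    """
    x = trial.samples
    T = x.shape[1]
    if window_len > T:
        raise ValueError("window longer than the trial")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = np.arange(0, T - window_len + 1, stride)
    n = window_len
    t = np.arange(n) / SAMPLE_RATE_HZ
    tc = t - t.mean()
    denom = float(np.sum(tc * tc))
    # vectorized via sliding windows: slope = sum(tc * (x - mean)) / sum(tc^2)
    sw = np.lib.stride_tricks.sliding_window_view(x, n, axis=1)[:, starts, :]
    means = sw.mean(axis=2, keepdims=True)
    feats = ((sw - means) @ tc / denom).T  # (n_windows, 6)
    end_times_ms = (starts + n) * 1000.0 / SAMPLE_RATE_HZ
    return feats, end_times_ms


@dataclass
class WindowDataset:
    """Labeled window features pooled across trials, grouped by trial so a
    train/test split never separates overlapping windows."""

    features: np.ndarray
    labels: np.ndarray
    trial_index: np.ndarray
    trial_ids: List[str]


def build_window_dataset(
    trials: Sequence[EMGTrial], window_len: int = DEFAULT_WINDOW_LEN, stride: int = 5
) -> WindowDataset:
    feats, labels, t_index, ids = [], [], [], []
    for i, trial in enumerate(trials):
        f, _ = rolling_window_features(trial, window_len, stride)
        feats.append(f)
        labels.append(np.full(len(f), trial.label.class_id))
        t_index.append(np.full(len(f), i))
        ids.append(trial.trial_id)
    return WindowDataset(
        np.concatenate(feats), np.concatenate(labels), np.concatenate(t_index), ids
    )


def curate_training_windows(
    features: np.ndarray,
    labels: np.ndarray,
    activity_percentile: float = 75.0,
    quiet_keep_fraction: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Boolean mask balancing the training set by activity.

    Quiescent windows outnumber activation-phase windows roughly 4:1 and
    carry no class information (they teach only the uniform prior), so all
    windows whose largest per-channel |slope| reaches the given percentile
    are kept and the low-activity bulk is subsampled. Improves activation-
    phase discrimination at a fixed epoch budget.
    """
    activity = np.max(np.abs(features), axis=1)
    threshold = np.percentile(activity, activity_percentile)
    rng = np.random.default_rng(seed)
    return (activity >= threshold) | (rng.random(len(activity)) < quiet_keep_fraction)


@dataclass
class WindowNet:
    """Trained window classifier: feature scaler + the 7-layer network."""

    spec: NetworkSpec
    scaler: StandardScaler
    mlp: MLPClassifier
    classes_: np.ndarray

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Probability rows over all 12 classes (absent training classes get
        probability 0), each row on the simplex."""
        p = self.mlp.predict_proba(self.scaler.transform(features))
        full = np.zeros((len(features), N_CLASSES))
        full[:, self.classes_] = p
        return full


def train_network(
    features: np.ndarray, labels: np.ndarray, spec: NetworkSpec = NetworkSpec()
) -> WindowNet:
    """Fit the classifier; deterministic for a fixed spec seed.

    Convergence warnings at small epoch budgets are silenced; the final
    training loss remains inspectable as ``model.mlp.loss_``.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs at least 2 classes")
    scaler = StandardScaler().fit(features)
    mlp = MLPClassifier(
        hidden_layer_sizes=spec.hidden_sizes,
        activation=spec.activation,
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=spec.batch_size,
        max_iter=spec.epochs,
        shuffle=True,
        random_state=spec.seed,
        n_iter_no_change=spec.epochs,
        alpha=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence at small epoch budgets
        mlp.fit(scaler.transform(features), labels)
    return WindowNet(spec, scaler, mlp, mlp.classes_)


@dataclass
class ClassProbabilitySeries:
    times_ms: np.ndarray
    probs: np.ndarray  # (n_windows, 12)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != N_CLASSES:
            raise ValueError("probs must be (n_windows, 12)")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")
        self.probs = p
        self.times_ms = np.asarray(self.times_ms, dtype=float)


def predict_series(
    model: WindowNet,
    trial: EMGTrial,
    window_len: int = DEFAULT_WINDOW_LEN,
    stride: int = 1,
) -> ClassProbabilitySeries:
    feats, end_times = rolling_window_features(trial, window_len, stride)
    return ClassProbabilitySeries(end_times, model.predict_proba(feats))


@dataclass
class PredictionOnset:
    status: str
    time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.status == STATUS_CONFIDENT) != (self.time_ms is not None):
            raise ValueError("time_ms defined iff status is confident")


def confident_onset(
    series: ClassProbabilitySeries,
    true_label: MotionClass,
    dominance_margin: float = DEFAULT_DOMINANCE_MARGIN,
    persistence: int = DEFAULT_PERSISTENCE,
) -> PredictionOnset:
    """Earliest window where P(true class) strictly exceeds every other
    class by at least ``dominance_margin``, sustained for ``persistence``
    consecutive windows."""
    if len(series.probs) == 0:
        raise ValueError("empty probability series")
    p_true = series.probs[:, true_label.class_id]
    others = np.delete(series.probs, true_label.class_id, axis=1)
    runner_up = others.max(axis=1)
    dominant = (p_true > runner_up) & (p_true - runner_up >= dominance_margin)
    run = 0
    for i, d in enumerate(dominant):
        run = run + 1 if d else 0
        if run >= persistence:
            start = i - persistence + 1
            return PredictionOnset(STATUS_CONFIDENT, float(series.times_ms[start]))
    return PredictionOnset(STATUS_NOT_REACHED)


@dataclass
class LeadTimeRecord:
    trial_id: str
    status: str
    lead_ms: Optional[float] = None
    label: Optional[MotionClass] = None

    def __post_init__(self) -> None:
        if self.status == STATUS_CONFIDENT and (
            self.lead_ms is None or not np.isfinite(self.lead_ms)
        ):
            raise ValueError("confident records need a finite lead")


def lead_time(
    onset: PredictionOnset,
    cps: ChangePointSet,
    trial_id: str = "",
    label: Optional[MotionClass] = None,
) -> LeadTimeRecord:
    """Signed lead: change-point time minus confident-onset time (ms).

    Positive lead means the network's confident prediction precedes the
    detected myoelectric change point. An inconclusive change-point set
    takes precedence over the onset status.
    """
    if cps.status == STATUS_LOW_CONTRAST or len(cps.onset_indices) == 0:
        return LeadTimeRecord(trial_id, STATUS_CP_INCONCLUSIVE, label=label)
    if onset.status != STATUS_CONFIDENT:
        return LeadTimeRecord(trial_id, onset.status, label=label)
    cp_time_ms = float(cps.onset_indices[0]) * 1000.0 / SAMPLE_RATE_HZ
    return LeadTimeRecord(
        trial_id, STATUS_CONFIDENT, lead_ms=cp_time_ms - onset.time_ms, label=label
    )
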
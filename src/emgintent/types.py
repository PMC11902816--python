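"""Core domain containers for sEMG motion-intent analysis.

A recording session yields labeled multi-channel surface-EMG trials: six
muscles around the elbow sampled at 1 kHz, each trial tagged with one of
twelve motion classes (six motion types x two magnitudes). Synthetic trials
additionally carry ground truth: the electrical (myoelectric) onset of each
activation cycle and the kinematic onset that follows it after the
electromechanical delay (EMD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The six instrumented muscles, in channel order.
MUSCLES = (
    "brachioradialis",
    "biceps_brachii",
    "triceps_brachii",
    "deltoid_posterior",
    "deltoid_medius",
    "deltoid_anterior",
)

N_CHANNELS = len(MUSCLES)

#: The six motion types of the protocol, in class order.
MOTION_TYPES = (
    "wrist_extension",
    "elbow_flexion",
    "elbow_extension",
    "arm_flexion_supinated",
    "arm_abduction_pronated",
    "arm_extension_neutral",
)

MAGNITUDES = ("fast", "slow")

N_CLASSES = len(MOTION_TYPES) * len(MAGNITUDES)

SAMPLE_RATE_HZ = 1000


@dataclass(frozen=True)
class MotionClass:
    """One of the 12 motion categories: a motion type at a magnitude."""

    motion_type: str
    magnitude: str

    def __post_init__(self) -> None:
        if self.motion_type not in MOTION_TYPES:
            raise ValueError(f"unknown motion type: {self.motion_type!r}")
        if self.magnitude not in MAGNITUDES:
            raise ValueError(f"unknown magnitude: {self.magnitude!r}")

    @property
    def class_id(self) -> int:
        """Unique integer id in [0, 11]."""
        return (
            MOTION_TYPES.index(self.motion_type) * len(MAGNITUDES)
            + MAGNITUDES.index(self.magnitude)
        )

    @classmethod
    def from_id(cls, class_id: int) -> "MotionClass":
        if not 0 <= class_id < N_CLASSES:
            raise ValueError(f"class id out of range: {class_id}")
        return cls(
            MOTION_TYPES[class_id // len(MAGNITUDES)],
            MAGNITUDES[class_id % len(MAGNITUDES)],
        )

    def __str__(self) -> str:
        return f"{self.motion_type}:{self.magnitude}"


#: All 12 motion classes in class-id order.
ALL_CLASSES = tuple(MotionClass.from_id(i) for i in range(N_CLASSES))


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject signal idiosyncrasies (muscle mass, skin impedance, ...).

    ``gain`` scales every channel multiplicatively, ``noise_sd`` is the
    baseline (quiescent) noise standard deviation in mV, ``mains_amplitude``
    the 60 Hz interference amplitude in mV, and ``synergy_jitter`` the s.d.
    of the per-subject perturbation applied to the synergy matrix.
    """

    subject_id: str
    gain: np.ndarray  # shape (6,), dimensionless, > 0
    noise_sd: float = 0.01
    mains_amplitude: float = 0.05
    synergy_jitter: float = 0.03

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        object.__setattr__(self, "gain", g)
        if g.shape != (N_CHANNELS,) or np.any(g <= 0):
            raise ValueError("gain must be 6 positive per-channel factors")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.mains_amplitude < 0:
            raise ValueError("mains_amplitude must be >= 0")


@dataclass
class TrialGroundTruth:
    """Known activation timing of a synthetic trial (times in ms)."""

    electrical_onsets_ms: np.ndarray
    electrical_offsets_ms: np.ndarray
    emd_ms: np.ndarray
    kinematic_onsets_ms: np.ndarray
    preactivation_lead_ms: float = 0.0

    def __post_init__(self) -> None:
        on = np.asarray(self.electrical_onsets_ms, dtype=float)
        off = np.asarray(self.electrical_offsets_ms, dtype=float)
        emd = np.asarray(self.emd_ms, dtype=float)
        kin = np.asarray(self.kinematic_onsets_ms, dtype=float)
        if not (len(on) == len(off) == len(emd) == len(kin)):
            raise ValueError("per-cycle arrays must have equal length")
        if np.any(np.diff(on) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(off <= on):
            raise ValueError("each offset must follow its onset")
        if np.any((emd < 50.0) | (emd > 190.0)):
            raise ValueError("EMD must lie in [50, 190] ms")
        if not np.allclose(kin - on, emd):
            raise ValueError("kinematic onset must equal electrical onset + EMD")
        self.electrical_onsets_ms = on
        self.electrical_offsets_ms = off
        self.emd_ms = emd
        self.kinematic_onsets_ms = kin


@dataclass
class EMGTrial:
    """One labeled 6-channel recording (samples in mV, shape (6, T))."""

    subject_id: str
    label: MotionClass
    samples: np.ndarray
    sample_rate_hz: int = SAMPLE_RATE_HZ
    ground_truth: Optional[TrialGroundTruth] = None
    trial_id: str = field(default="")

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[0] != N_CHANNELS:
            raise ValueError("samples must have shape (6, T)")
        if s.shape[1] < 1000:
            raise ValueError("trial must be at least 1 s long (T >= 1000)")
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise ValueError("sample rate must be 1000 Hz")
        self.samples = s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz
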
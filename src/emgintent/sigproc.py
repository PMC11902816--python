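"""Zero-phase conditioning of raw sEMG into envelope signals.

The conditioning chain is: 4th-order Butterworth bandstop at 58-61 Hz
(mains removal), mean subtraction per trial, 4th-order Butterworth bandpass
at 25-250 Hz (myoelectric band), then a full-wave-rectified moving-RMS
envelope. All filters are applied forward and backward (zero phase), so the
envelope stays time-aligned with the underlying activation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .types import SAMPLE_RATE_HZ, EMGTrial


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth band filter: ``kind`` in {"bandstop", "bandpass"}."""

    kind: str
    order: int
    low_hz: float
    high_hz: float
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.kind not in ("bandstop", "bandpass"):
            raise ValueError(f"unknown filter kind: {self.kind!r}")
        if not (0 < self.low_hz < self.high_hz < self.sample_rate_hz / 2):
            raise ValueError("need 0 < low_hz < high_hz < Nyquist")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")

    def sos(self) -> np.ndarray:
        """Second-order-section realization (stable at order 4 even for the
        narrow 58-61 Hz stopband)."""
        return sps.butter(
            self.order,
            (self.low_hz, self.high_hz),
            btype=self.kind,
            fs=self.sample_rate_hz,
            output="sos",
        )


MAINS_BANDSTOP = FilterSpec("bandstop", 4, 58.0, 61.0)
MYOELECTRIC_BANDPASS = FilterSpec("bandpass", 4, 25.0, 250.0)


@dataclass
class EnvelopeSignal:
    """Nonnegative envelope series (mV) at 1 kHz."""

    samples: np.ndarray
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if np.any(s < 0):
            raise ValueError("envelope must be nonnegative")
        self.samples = s

    def __len__(self) -> int:
        return len(self.samples)


def zero_phase_filter(signal: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply the filter forward and backward (odd-reflection edge padding).

    The net phase shift is zero and the effective magnitude response is the
    squared single-pass Butterworth response.
    """
    x = np.asarray(signal, dtype=float)
    padlen = 3 * (spec.order + 1)
    if x.size <= 3 * spec.order or x.size <= padlen:
        raise ValueError(f"signal too short for order-{spec.order} zero-phase filtering")
    return sps.sosfiltfilt(spec.sos(), x, padtype="odd", padlen=padlen)


def center(signal: np.ndarray) -> np.ndarray:
    """Subtract the trial mean from every sample."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot center an empty signal")
    return x - x.mean()


def envelope(signal: np.ndarray, smooth_ms: float = 50.0) -> EnvelopeSignal:
    """Moving-RMS envelope of a conditioned signal.

    The window is centered (zero-phase smoothing) with reflected edges;
    the result is nonnegative, the same length as the input, and scales
    linearly with pointwise amplitude scaling.
    """
    if smooth_ms <= 0:
        raise ValueError("smooth_ms must be > 0")
    x = np.asarray(signal, dtype=float)
    w = max(int(round(smooth_ms * SAMPLE_RATE_HZ / 1000.0)), 1)
    mean_sq = uniform_filter1d(x * x, size=w, mode="reflect")
    return EnvelopeSignal(np.sqrt(np.maximum(mean_sq, 0.0)))


def preprocess_channel(signal: np.ndarray, smooth_ms: float = 50.0) -> EnvelopeSignal:
    """Full chain for one channel: bandstop -> center -> bandpass -> envelope."""
    x = zero_phase_filter(signal, MAINS_BANDSTOP)
    x = center(x)
    x = zero_phase_filter(x, MYOELECTRIC_BANDPASS)
    return envelope(x, smooth_ms)


def preprocess_trial(trial: EMGTrial, smooth_ms: float = 50.0) -> List[EnvelopeSignal]:
    """Condition every channel of a trial into an envelope signal."""
    return [preprocess_channel(trial.samples[c], smooth_ms) for c in range(trial.samples.shape[0])]
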
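"""Change-point detection by flanking-RMS contrast cost minimization.

A change point is a sample index where the signal's local mean/RMS shifts
most sharply. Candidate points are scored by the RMS of the windows
immediately before and after them; the cost of a candidate set is the sum
of inverse flanking-RMS differences, so minimizing the cost maximizes the
contrast at every selected point. The global minimum over a decimated
candidate grid is found exactly by dynamic programming; the literal
random-candidate scheme is available as a Monte-Carlo alternative. A sweep
over the number of points n selects, within the given range, every point
whose contrast exceeds a reference contrast.

Slope features: the ordinary-least-squares slope of the envelope over a
short forward-looking window starting at each change point, in mV/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .sigproc import EnvelopeSignal
from .types import SAMPLE_RATE_HZ

#: Guard against division by zero on flat flanks.
COST_EPS = 1e-9

#: Default flanking-window length, samples (100 ms at 1 kHz).
DEFAULT_FLANK_WINDOW = 100

#: Default candidate-grid decimation step, samples.
DEFAULT_GRID_STEP = 10

STATUS_OK = "ok"
STATUS_LOW_CONTRAST = "low_contrast"


@dataclass
class ChangePointSet:
    """The selected change points of one series.

    ``rms_deltas`` holds the signed flanking contrast (RMS after minus RMS
    before) at each index: positive at activation onsets, negative at
    offsets. ``status`` is ``"low_contrast"`` when no candidate's contrast
    clears the noise floor, mirroring inconclusive-detection failure modes.
    """

    indices: np.ndarray
    total_cost: float
    flank_window: int
    rms_deltas: np.ndarray
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(idx) <= 0):
            raise ValueError("change-point indices must be strictly increasing")
        self.indices = idx
        self.rms_deltas = np.asarray(self.rms_deltas, dtype=float)

    @property
    def n(self) -> int:
        return len(self.indices)

    @property
    def times_ms(self) -> np.ndarray:
        return self.indices * 1000.0 / SAMPLE_RATE_HZ

    @property
    def onset_indices(self) -> np.ndarray:
        """Indices where the RMS rises (activation onsets)."""
        return self.indices[self.rms_deltas > 0]

    @property
    def offset_indices(self) -> np.ndarray:
        return self.indices[self.rms_deltas < 0]


def flank_rms(signal: np.ndarray, idx: int, w: int) -> Tuple[float, float]:
    """RMS of the windows immediately before ([idx-w, idx)) and after
    ([idx, idx+w)) a candidate change point."""
    x = np.asarray(signal, dtype=float)
    if not (w <= idx and idx + w <= x.size):
        raise ValueError(f"index {idx} too close to an edge for window {w}")
    before = float(np.sqrt(np.mean(x[idx - w : idx] ** 2)))
    after = float(np.sqrt(np.mean(x[idx : idx + w] ** 2)))
    return before, after


def candidate_cost(
    signal: np.ndarray, indices: Sequence[int], w: int, eps: float = COST_EPS
) -> float:
    """Sum over candidates of 1 / (|RMS_after - RMS_before| + eps); lower
    cost means larger flanking contrasts."""
    total = 0.0
    for idx in indices:
        before, after = flank_rms(signal, idx, w)
        total += 1.0 / (abs(after - before) + eps)
    return total


def _grid_deltas(
    signal: np.ndarray, w: int, grid_step: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Candidate indices on the decimated grid and their signed flanking
    contrasts, computed with a cumulative sum of squares."""
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 2 * w + 1:
        raise ValueError("signal shorter than two flanking windows")
    cand = np.arange(w, n - w + 1, grid_step)
    csq = np.concatenate(([0.0], np.cumsum(x * x)))
    before = np.sqrt((csq[cand] - csq[cand - w]) / w)
    after = np.sqrt((csq[cand + w] - csq[cand]) / w)
    return cand, after - before


def _dp_tables(
    costs: np.ndarray, max_n: int, sep_slots: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact DP over an ordered candidate grid.

    dp[m, j] = minimal total cost of choosing m points from candidates
    0..j with the m-th point at j and consecutive points at least
    ``sep_slots`` grid slots apart. Returns (dp, backpointers).
    """
    c = len(costs)
    dp = np.full((max_n + 1, c), np.inf)
    back = np.full((max_n + 1, c), -1, dtype=int)
    dp[1] = costs
    for m in range(2, max_n + 1):
        prev = dp[m - 1]
        # prefix minimum of prev up to j - sep_slots
        best = np.inf
        best_i = -1
        for j in range(c):
            i = j - sep_slots
            if i >= 0 and prev[i] < best:
                best = prev[i]
                best_i = i
            if best_i >= 0:
                dp[m, j] = costs[j] + best
                back[m, j] = best_i
    return dp, back


def _reconstruct(back: np.ndarray, m: int, j: int) -> list:
    picks = [j]
    while m > 1:
        j = back[m, j]
        picks.append(j)
        m -= 1
    return picks[::-1]


def minimize_cost_fixed_n(
    signal: np.ndarray,
    n: int,
    w: int = DEFAULT_FLANK_WINDOW,
    grid_step: int = DEFAULT_GRID_STEP,
    min_spacing: Optional[int] = None,
    solver: str = "dp",
    seed: int = 0,
    restarts: int = 200,
    eps: float = COST_EPS,
) -> ChangePointSet:
    """Find the n-point candidate set of minimal cost.

    ``solver="dp"`` performs an exact dynamic-programming search over the
    decimated candidate grid; ``solver="random"`` draws ``restarts`` random
    valid candidate sets and keeps the best (the literal random-selection
    scheme, with no optimality guarantee).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_spacing is None:
        min_spacing = 2 * w
    cand, deltas = _grid_deltas(signal, w, grid_step)
    sep_slots = max(int(np.ceil(min_spacing / grid_step)), 1)
    if (n - 1) * sep_slots >= len(cand):
        raise ValueError(f"cannot place {n} points {min_spacing} samples apart")
    costs = 1.0 / (np.abs(deltas) + eps)

    if solver == "dp":
        dp, back = _dp_tables(costs, n, sep_slots)
        j = int(np.argmin(dp[n]))
        if not np.isfinite(dp[n, j]):
            raise ValueError("no feasible placement of n points")
        picks = _reconstruct(back, n, j)
        total = float(dp[n, j])
    elif solver == "random":
        rng = np.random.default_rng(seed)
        best_total, picks = np.inf, None
        for _ in range(restarts):
            slots = np.sort(rng.choice(len(cand), size=n, replace=False))
            if n > 1 and np.any(np.diff(slots) < sep_slots):
                continue
            total = float(costs[slots].sum())
            if total < best_total:
                best_total, picks = total, list(slots)
        if picks is None:
            raise ValueError("random solver found no feasible candidate set")
        total = best_total
    else:
        raise ValueError(f"unknown solver: {solver!r}")

    picks = np.asarray(picks, dtype=int)
    return ChangePointSet(
        indices=cand[picks],
        total_cost=total,
        flank_window=w,
        rms_deltas=deltas[picks],
    )


def detect_change_points(
    signal: np.ndarray,
    n_range: Tuple[int, int],
    w: int = DEFAULT_FLANK_WINDOW,
    grid_step: int = DEFAULT_GRID_STEP,
    min_spacing: Optional[int] = None,
    seed: int = 0,
    solver: str = "dp",
    contrast_fraction: float = 0.25,
    noise_floor: Optional[float] = None,
    low_contrast_mult: float = 3.0,
    eps: float = COST_EPS,
) -> ChangePointSet:
    """Sweep n over ``n_range`` and keep the best-penalized candidate set.

    Cross-n comparison: a point is worth adding iff its flanking contrast
    exceeds the reference contrast ``contrast_fraction * max |dRMS|``, so
    the penalized objective is cost(n) - n / reference_contrast. When every
    candidate's contrast falls below ``low_contrast_mult`` times the noise
    floor (default: the series median, a robust quiescent-RMS estimate for
    mostly-quiet recordings), the result is flagged low-contrast instead of
    returning spurious points.
    """
    n_lo, n_hi = n_range
    if n_lo < 1 or n_hi < n_lo:
        raise ValueError("n_range must be a nonempty range with n >= 1")
    x = np.asarray(signal, dtype=float)
    if noise_floor is None:
        noise_floor = float(np.median(np.abs(x)))

    _, deltas = _grid_deltas(x, w, grid_step)
    max_contrast = float(np.abs(deltas).max())
    delta_ref = max(contrast_fraction * max_contrast, eps)

    best: Optional[ChangePointSet] = None
    best_penalized = np.inf
    for n in range(n_lo, n_hi + 1):
        try:
            cps = minimize_cost_fixed_n(
                x, n, w, grid_step, min_spacing, solver=solver, seed=seed + n, eps=eps
            )
        except ValueError:
            continue  # n points do not fit; smaller n may still work
        penalized = cps.total_cost - n / delta_ref
        if penalized < best_penalized:
            best_penalized = penalized
            best = cps
    if best is None:
        raise ValueError("no n in n_range admits a feasible candidate set")
    if max_contrast < low_contrast_mult * noise_floor:
        best.status = STATUS_LOW_CONTRAST
    return best


@dataclass(frozen=True)
class SlopeFeature:
    """OLS slope of an envelope at a change point (mV/s)."""

    channel: int
    index: int
    slope: float


def slope_at(
    env: EnvelopeSignal, idx: int, fit_window: int = 50, channel: int = 0
) -> SlopeFeature:
    """Least-squares slope of the envelope over [idx, idx + fit_window).

    Forward-looking so that an onset's slope captures the activation rise.
    """
    y = env.samples if isinstance(env, EnvelopeSignal) else np.asarray(env, dtype=float)
    if idx < 0 or idx + fit_window > y.size:
        raise ValueError("slope fit window extends outside the signal")
    t_s = np.arange(fit_window) / SAMPLE_RATE_HZ
    seg = y[idx : idx + fit_window]
    slope = float(np.polyfit(t_s, seg, 1)[0])
    if not np.isfinite(slope):
        raise ValueError("non-finite slope")
    return SlopeFeature(channel=channel, index=idx, slope=slope)
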
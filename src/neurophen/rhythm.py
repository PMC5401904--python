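"""Left-right locomotor rhythm classification from paired ventral-root traces.

Pipeline: rectified-integrated envelope -> iterative-threshold burst
detection -> right-onset phase within each left burst cycle -> circular
statistics -> label (alternating / synchronous / arrhythmic / no_rhythm).

The classification thresholds are analysis definitions, not measured
quantities: resultant length R >= ``r_min`` (default 0.6) is required for any
rhythm, and the circular mean must fall within ``phase_tol`` (default 0.125
cycle) of phase 0.5 for "alternating" or of phase 0.0 for "synchronous".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "VRTracePair",
    "BurstTrain",
    "RhythmClassification",
    "envelope",
    "detect_bursts",
    "cycle_phases",
    "classify",
    "classify_pair",
]


@dataclass(frozen=True)
class VRTracePair:
    """Paired left/right ventral-root voltage traces."""

    left: np.ndarray
    right: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        if left.shape != right.shape or left.ndim != 1:
            raise ValueError("left and right must be 1-D and equally long")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def duration_s(self) -> float:
        return len(self.left) / self.sample_rate_hz


@dataclass(frozen=True)
class BurstTrain:
    """Ordered non-overlapping burst intervals of one trace, in seconds."""

    bursts: list[tuple[float, float]]
    side: str | None = None

    def __post_init__(self) -> None:
        prev_off = -np.inf
        for on, off in self.bursts:
            if off <= on:
                raise ValueError("burst offset must exceed onset")
            if on < prev_off:
                raise ValueError("bursts must be ordered and non-overlapping")
            prev_off = off

    @property
    def onsets(self) -> np.ndarray:
        return np.array([on for on, _ in self.bursts])

    def __len__(self) -> int:
        return len(self.bursts)


def envelope(
    trace: np.ndarray, smooth_window_s: float, sample_rate_hz: float
) -> np.ndarray:
    """Rectified-integrated envelope: moving average of |trace - median|."""
    trace = np.asarray(trace, dtype=float)
    window = int(round(smooth_window_s * sample_rate_hz))
    if window < 2:
        raise ValueError("smoothing window must span at least 2 samples")
    if window > len(trace):
        raise ValueError("smoothing window longer than the trace")
    rect = np.abs(trace - np.median(trace))
    return uniform_filter1d(rect, size=window, mode="nearest")


def detect_bursts(
    env: np.ndarray,
    sample_rate_hz: float,
    k_threshold: float = 5.0,
    min_duration_s: float = 0.2,
    merge_gap_s: float = 0.1,
    side: str | None = None,
) -> BurstTrain:
    """Bursts as maximal supra-threshold runs of the envelope.

    The threshold is estimated in two passes so that the bursts themselves do
    not inflate the baseline statistics: a first cut at
    ``median + k * robust SD`` of the whole envelope selects baseline
    samples, then the final threshold is ``baseline median + k * baseline
    robust SD``. Sub-threshold gaps shorter than ``merge_gap_s`` are fused and
    runs shorter than ``min_duration_s`` discarded. An envelope with no
    baseline (everything above threshold) yields an empty train, which
    downstream classification reports as ``no_rhythm``.
    """
    env = np.asarray(env, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be non-negative")

    def robust(x: np.ndarray) -> tuple[float, float]:
        med = float(np.median(x))
        return med, 1.4826 * float(np.median(np.abs(x - med)))

    med, sd = robust(env)
    baseline = env <= med + k_threshold * sd
    if not baseline.any():
        return BurstTrain([], side=side)
    base_med, base_sd = robust(env[baseline])
    thr = base_med + k_threshold * base_sd

    above = env > thr
    if not above.any():
        return BurstTrain([], side=side)
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[above[edges + 1]] + 1)
    stops = list(edges[~above[edges + 1]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(env))

    merged: list[list[int]] = []
    max_gap = merge_gap_s * sample_rate_hz
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = min_duration_s * sample_rate_hz
    bursts = [
        (s / sample_rate_hz, e / sample_rate_hz)
        for s, e in merged
        if e - s >= min_len
    ]
    return BurstTrain(bursts, side=side)


def cycle_phases(left: BurstTrain, right: BurstTrain) -> np.ndarray:
    """Right-onset phases within consecutive left burst cycles, in [0, 1).

    For each left cycle [onset_i, onset_{i+1}) every right onset t inside it
    contributes (t - onset_i) / (onset_{i+1} - onset_i). Requires at least
    3 left bursts to define at least two cycles.
    """
    if len(left) < 3:
        raise ValueError("need at least 3 left bursts to define cycles")
    l_on = left.onsets
    r_on = right.onsets
    phases = []
    for i in range(len(l_on) - 1):
        t0, t1 = l_on[i], l_on[i + 1]
        inside = r_on[(r_on >= t0) & (r_on < t1)]
        phases.extend((inside - t0) / (t1 - t0))
    return np.asarray(phases, dtype=float)


@dataclass(frozen=True)
class RhythmClassification:
    """Circular summary of left-right coordination and its label."""

    phases: np.ndarray
    circular_mean: float
    resultant_length: float
    label: str

    def summary(self) -> str:
        return (
            f"{self.label}: n_phases={len(self.phases)}, "
            f"mean={self.circular_mean:.3f}, R={self.resultant_length:.3f}"
        )


def _circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


def classify(
    phases: np.ndarray,
    r_min: float = 0.6,
    phase_tol: float = 0.125,
) -> RhythmClassification:
    """Label a phase sample as alternating, synchronous, or arrhythmic.

    Uses the circular mean mu and resultant length R of the phases (on the
    unit circle): R < ``r_min`` -> arrhythmic; otherwise alternating if mu is
    within ``phase_tol`` of 0.5, synchronous if within ``phase_tol`` of 0.0,
    else arrhythmic. An empty phase list is ``no_rhythm``.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        return RhythmClassification(phases, np.nan, np.nan, "no_rhythm")
    if np.any((phases < 0) | (phases >= 1)):
        raise ValueError("phases must lie in [0, 1)")
    angles = 2 * np.pi * phases
    c, s = np.mean(np.cos(angles)), np.mean(np.sin(angles))
    r = float(np.hypot(c, s))
    mu = float(np.arctan2(s, c) / (2 * np.pi) % 1.0)
    if r < r_min:
        label = "arrhythmic"
    elif _circular_distance(mu, 0.5) <= phase_tol:
        label = "alternating"
    elif _circular_distance(mu, 0.0) <= phase_tol:
        label = "synchronous"
    else:
        label = "arrhythmic"
    return RhythmClassification(phases, mu, r, label)


def classify_pair(
    pair: VRTracePair,
    smooth_window_s: float = 0.1,
    k_threshold: float = 5.0,
    min_duration_s: float = 0.2,
    merge_gap_s: float = 0.1,
    r_min: float = 0.6,
    phase_tol: float = 0.125,
) -> RhythmClassification:
    """End-to-end classification of a left/right ventral-root trace pair."""
    trains = []
    for trace, side in ((pair.left, "left"), (pair.right, "right")):
        env = envelope(trace, smooth_window_s, pair.sample_rate_hz)
        trains.append(
            detect_bursts(
                env,
                pair.sample_rate_hz,
                k_threshold=k_threshold,
                min_duration_s=min_duration_s,
                merge_gap_s=merge_gap_s,
                side=side,
            )
        )
    left, right = trains
    if len(left) < 3 or len(right) == 0:
        return RhythmClassification(np.array([]), np.nan, np.nan, "no_rhythm")
    phases = cycle_phases(left, right)
    return classify(phases, r_min=r_min, phase_tol=phase_tol)
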
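"""Calcium-trace event extraction.

Converts raw multi-neuron fluorescence recordings into binary event rasters:
rolling-percentile baseline -> ΔF/F -> robust-threshold onset detection.
All detection parameters are analysis choices exposed in
:class:`DetectionParams` and should be reported alongside results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceRecording",
    "DetectionParams",
    "EventRaster",
    "compute_dff",
    "robust_noise_sd",
    "detect_events",
    "detect",
    "active_mask",
]

#: factor converting a median absolute deviation to a Gaussian-consistent SD
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class FluorescenceRecording:
    """Raw fluorescence of one imaged cluster.

    Parameters
    ----------
    values : ndarray, shape (n_neurons, n_frames)
        Fluorescence in arbitrary units, one row per neuron.
    dt_s : float
        Sampling interval in seconds (0.1 s, i.e. 100 ms imaging interval,
        by default).
    cluster_id : str, optional
        Free-form label carried through downstream results.
    """

    values: np.ndarray
    dt_s: float = 0.1
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D (neurons x frames) array")
        if vals.shape[0] < 2:
            raise ValueError("a recording needs at least 2 neurons")
        if vals.shape[1] < 10:
            raise ValueError("a recording needs at least 10 frames")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values contain NaN or infinities")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt_s


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of ΔF/F computation and onset detection.

    ``baseline_percentile`` / ``baseline_window_frames`` define the rolling
    baseline F0; ``z_threshold`` is the onset level in robust-noise SDs above
    the ΔF/F median; ``min_separation_frames`` suppresses re-crossings closer
    than this to an accepted onset; ``noise_floor`` (ΔF/F units) bounds the
    noise-scale estimate from below so that noiseless traces still have a
    finite, re-crossable threshold.
    """

    baseline_percentile: float = 20.0
    baseline_window_frames: int = 100
    z_threshold: float = 3.5
    min_separation_frames: int = 5
    noise_floor: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.baseline_percentile < 100:
            raise ValueError("baseline_percentile must be in (0, 100)")
        if self.baseline_window_frames < 2:
            raise ValueError("baseline_window_frames must be >= 2")
        if not self.z_threshold > 0:
            raise ValueError("z_threshold must be positive")
        if self.min_separation_frames < 0:
            raise ValueError("min_separation_frames must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")

    def with_(self, **kwargs) -> "DetectionParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EventRaster:
    """Binary (neurons x frames) matrix of detected transient onsets."""

    onsets: np.ndarray
    dt_s: float = 0.1
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        ons = np.asarray(self.onsets)
        if ons.ndim != 2:
            raise ValueError("onsets must be a 2-D (neurons x frames) array")
        if not np.isin(ons, (0, 1)).all():
            raise ValueError("onsets must be binary")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")
        object.__setattr__(self, "onsets", ons.astype(np.uint8))

    @property
    def n_neurons(self) -> int:
        return self.onsets.shape[0]

    @property
    def n_frames(self) -> int:
        return self.onsets.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.onsets.sum())


def compute_dff(
    recording: FluorescenceRecording,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Baseline-normalised fluorescence change ΔF/F = (F - F0) / F0.

    F0 is, per neuron, the rolling ``baseline_percentile`` of the raw trace
    over a centred window of ``baseline_window_frames``; windows are truncated
    (not padded) at the recording edges.

    Raises
    ------
    ValueError
        If the estimated baseline is non-positive anywhere (fluorescence must
        be a positive signal for ΔF/F to be meaningful).
    """
    frames_by_neurons = pd.DataFrame(recording.values.T)
    f0 = (
        frames_by_neurons.rolling(
            params.baseline_window_frames, center=True, min_periods=1
        )
        .quantile(params.baseline_percentile / 100.0)
        .to_numpy()
        .T
    )
    if np.any(f0 <= 0):
        raise ValueError(
            "non-positive baseline fluorescence: ΔF/F is undefined"
        )
    return (recording.values - f0) / f0


def robust_noise_sd(dff: np.ndarray) -> np.ndarray:
    """Per-neuron robust noise scale: 1.4826 x median absolute deviation.

    The MAD is insensitive to the sparse large-amplitude transients that
    inflate a plain standard deviation.
    """
    med = np.median(dff, axis=1, keepdims=True)
    return MAD_TO_SD * np.median(np.abs(dff - med), axis=1)


def detect_events(
    dff: np.ndarray,
    params: DetectionParams = DetectionParams(),
    dt_s: float = 0.1,
    cluster_id: str | None = None,
) -> EventRaster:
    """Mark transient onsets where ΔF/F crosses a robust threshold from below.

    The per-neuron threshold level is ``median(ΔF/F) + z_threshold * sigma``
    with ``sigma = max(1.4826 * MAD, noise_floor)``. An onset is the first
    frame of each upward crossing; later crossings within
    ``min_separation_frames`` of an accepted onset are suppressed (greedy,
    earliest-first).
    """
    dff = np.asarray(dff, dtype=float)
    if dff.ndim != 2:
        raise ValueError("dff must be 2-D (neurons x frames)")
    if not np.all(np.isfinite(dff)):
        raise ValueError("dff must be finite")
    if dff.shape[1] < params.baseline_window_frames:
        raise ValueError(
            "recording has fewer frames than baseline_window_frames"
        )
    sigma = np.maximum(robust_noise_sd(dff), params.noise_floor)
    level = np.median(dff, axis=1) + params.z_threshold * sigma

    above = dff >= level[:, None]
    rising = above.copy()
    rising[:, 1:] &= ~above[:, :-1]

    onsets = np.zeros_like(rising, dtype=np.uint8)
    gap = params.min_separation_frames
    for i in range(rising.shape[0]):
        last = -gap - 1
        for t in np.flatnonzero(rising[i]):
            if t - last > gap:
                onsets[i, t] = 1
                last = t
    return EventRaster(onsets, dt_s=dt_s, cluster_id=cluster_id)


def detect(
    recording: FluorescenceRecording,
    params: DetectionParams = DetectionParams(),
) -> EventRaster:
    """Full trace-to-raster pipeline: ΔF/F then onset detection."""
    dff = compute_dff(recording, params)
    return detect_events(
        dff, params, dt_s=recording.dt_s, cluster_id=recording.cluster_id
    )


def active_mask(raster: EventRaster) -> np.ndarray:
    """Boolean per-neuron mask: True iff the neuron has >= 1 onset."""
    return raster.onsets.any(axis=1)
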
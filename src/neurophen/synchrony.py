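"""Network-synchrony statistics of event rasters.

Implements the cluster-level activity summaries used to contrast genotypes:
synchrony-size histograms with a distinguished "all" bin, active-neuron
fraction binning, per-neuron response-frequency distributions with a log-log
power-law fit, a complete-synchronization classifier, and per-bin
Mann-Whitney group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventRaster, active_mask

__all__ = [
    "SynchronyHistogram",
    "ActiveFractionHistogram",
    "PowerLawFit",
    "FrequencyDistribution",
    "synchronous_groups",
    "synchrony_histogram",
    "active_fraction",
    "bin_active_fractions",
    "response_frequencies",
    "frequency_histogram",
    "fit_power_law",
    "frequency_distribution",
    "classify_full_sync",
    "compare_groups",
    "significance_stars",
]


def synchronous_groups(raster: EventRaster, window_frames: int = 1) -> list[int]:
    """Sizes (distinct-neuron counts) of synchronous onset groups.

    Onsets are merged transitively: two onsets belong to the same group when
    their frames differ by at most ``window_frames``, closed over chains.
    Because closeness is one-dimensional in time, the groups are exactly the
    runs obtained by splitting the sorted onset frames at gaps larger than
    ``window_frames``. Every onset belongs to exactly one group.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    neurons, frames = np.nonzero(raster.onsets)
    if len(frames) == 0:
        return []
    order = np.argsort(frames, kind="stable")
    frames, neurons = frames[order], neurons[order]
    sizes = []
    start = 0
    for i in range(1, len(frames) + 1):
        if i == len(frames) or frames[i] - frames[i - 1] > window_frames:
            sizes.append(int(len(np.unique(neurons[start:i]))))
            start = i
    return sizes


@dataclass(frozen=True)
class SynchronyHistogram:
    """Counts of synchronous groups by size, with size == n in the "all" bin."""

    counts: np.ndarray  # index k -> groups of size k+1, for sizes 1..n-1
    all_count: int
    cluster_size: int

    @property
    def n_groups(self) -> int:
        return int(self.counts.sum()) + self.all_count

    def as_series(self) -> pd.Series:
        labels = [str(s) for s in range(1, self.cluster_size)] + ["all"]
        return pd.Series(
            np.concatenate([self.counts, [self.all_count]]), index=labels
        )


def synchrony_histogram(
    group_sizes: list[int], cluster_size: int
) -> SynchronyHistogram:
    """Histogram of synchronous-group sizes 1..n-1 plus the "all" (=n) bin."""
    if cluster_size < 2:
        raise ValueError("cluster_size must be >= 2")
    counts = np.zeros(cluster_size - 1, dtype=int)
    all_count = 0
    for s in group_sizes:
        if not 1 <= s <= cluster_size:
            raise ValueError(f"group size {s} outside [1, {cluster_size}]")
        if s == cluster_size:
            all_count += 1
        else:
            counts[s - 1] += 1
    return SynchronyHistogram(counts, all_count, cluster_size)


def active_fraction(raster: EventRaster) -> float:
    """Percentage of neurons with at least one onset, in [0, 100]."""
    return 100.0 * active_mask(raster).mean()


@dataclass(frozen=True)
class ActiveFractionHistogram:
    """12-bin histogram: {exactly 0}, ten interior bins of width 10, {exactly 100}."""

    counts: np.ndarray  # length 12

    @property
    def n_clusters(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        labels = ["0"] + [f"[{10*k},{10*(k+1)})" for k in range(10)] + ["100"]
        return pd.Series(self.counts, index=labels)


def bin_active_fractions(values: list[float] | np.ndarray) -> ActiveFractionHistogram:
    """Bin active-fraction percentages with exact 0 and 100 kept separate.

    Values strictly between 0 and 100 fall in half-open bins
    [0,10), [10,20), ..., [90,100).
    """
    counts = np.zeros(12, dtype=int)
    for v in np.asarray(values, dtype=float):
        if not 0 <= v <= 100:
            raise ValueError(f"active fraction {v} outside [0, 100]")
        if v == 0:
            counts[0] += 1
        elif v == 100:
            counts[11] += 1
        else:
            counts[1 + int(v // 10)] += 1
    return ActiveFractionHistogram(counts)


def response_frequencies(raster: EventRaster) -> np.ndarray:
    """Per-neuron onset counts (responses per recording)."""
    return raster.onsets.sum(axis=1).astype(int)


def frequency_histogram(counts_per_neuron: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-width histogram of neuron counts versus response frequency.

    Returns ``(frequencies, n_neurons)`` for frequencies 1..max observed;
    neurons with zero responses are not part of the frequency axis.
    """
    counts_per_neuron = np.asarray(counts_per_neuron, dtype=int)
    if counts_per_neuron.size == 0 or counts_per_neuron.max() < 1:
        return np.array([], dtype=int), np.array([], dtype=int)
    binc = np.bincount(counts_per_neuron)
    freqs = np.arange(1, len(binc))
    return freqs, binc[1:]


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log least-squares line through a frequency histogram."""

    slope: float
    intercept: float
    r2: float
    fitted: bool
    n_bins: int

    def summary(self) -> str:
        if not self.fitted:
            return "power-law fit: not fitted (fewer than 3 non-empty bins)"
        return (
            f"power-law fit: slope={self.slope:.3f} intercept={self.intercept:.3f} "
            f"r2={self.r2:.3f} over {self.n_bins} bins"
        )


def fit_power_law(freqs: np.ndarray, n_neurons: np.ndarray) -> PowerLawFit:
    """Least-squares line through (log10 frequency, log10 neuron count).

    Zero-count bins are excluded (their logarithm is undefined); at least
    3 non-empty bins with frequency >= 1 are required, otherwise the result
    is returned with ``fitted=False`` and NaN coefficients.
    """
    freqs = np.asarray(freqs, dtype=float)
    n_neurons = np.asarray(n_neurons, dtype=float)
    keep = (freqs >= 1) & (n_neurons > 0)
    if keep.sum() < 3:
        return PowerLawFit(np.nan, np.nan, np.nan, False, int(keep.sum()))
    x = np.log10(freqs[keep])
    y = np.log10(n_neurons[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(slope), float(intercept), float(r2), True, int(keep.sum()))


@dataclass(frozen=True)
class FrequencyDistribution:
    """Per-neuron response counts, their unit-width histogram, and the fit."""

    counts_per_neuron: np.ndarray
    freqs: np.ndarray
    n_neurons_at_freq: np.ndarray
    fit: PowerLawFit


def frequency_distribution(raster: EventRaster) -> FrequencyDistribution:
    """Response-frequency distribution of one raster, with power-law fit."""
    counts = response_frequencies(raster)
    freqs, hist = frequency_histogram(counts)
    return FrequencyDistribution(counts, freqs, hist, fit_power_law(freqs, hist))


def classify_full_sync(raster: EventRaster, window_frames: int = 1) -> bool:
    """True iff at least one synchronous group spans every neuron."""
    sizes = synchronous_groups(raster, window_frames)
    return bool(sizes) and max(sizes) == raster.n_neurons


def significance_stars(p: float) -> str:
    """Star tier used in the histogram comparisons."""
    if p < 0.0001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    bin_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-bin two-sided Mann-Whitney U comparison of two cluster groups.

    ``values_a`` / ``values_b`` are (clusters x bins) arrays of per-cluster
    per-bin values. Exact enumeration is used when both groups have <= 8
    clusters and the pooled bin values are tie-free; otherwise the
    tie-corrected normal approximation. A Bonferroni-adjusted column is
    emitted in addition to the uncorrected p-values.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 clusters")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must have the same number of bins")
    n_bins = a.shape[1]
    if bin_labels is None:
        bin_labels = [str(i) for i in range(n_bins)]

    rows = []
    for j in range(n_bins):
        x, y = a[:, j], b[:, j]
        pooled = np.concatenate([x, y])
        exact_ok = len(x) <= 8 and len(y) <= 8 and len(np.unique(pooled)) == len(pooled)
        method = "exact" if exact_ok else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append((bin_labels[j], float(res.statistic), float(res.pvalue), method))
    table = pd.DataFrame(rows, columns=["bin", "U", "p", "method"])
    table["stars"] = table["p"].map(significance_stars)
    table["p_bonferroni"] = np.minimum(table["p"] * n_bins, 1.0)
    return table
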
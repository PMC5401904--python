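"""Matplotlib views of the standard result summaries."""

from __future__ import annotations

import numpy as np

from .synchrony import ActiveFractionHistogram, PowerLawFit, SynchronyHistogram

__all__ = [
    "plot_synchrony_histogram",
    "plot_active_fractions",
    "plot_frequency_loglog",
    "plot_phase_histogram",
]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_synchrony_histogram(hist: SynchronyHistogram, ax=None, **bar_kw):
    """Bar plot of synchrony sizes with the "all" bin on the right."""
    ax = _get_ax(ax)
    series = hist.as_series()
    ax.bar(range(len(series)), series.to_numpy(), **bar_kw)
    ax.set_xticks(range(len(series)), series.index, rotation=90, fontsize=7)
    ax.set_xlabel("synchrony size (neurons)")
    ax.set_ylabel("number of events")
    return ax


def plot_active_fractions(hist: ActiveFractionHistogram, ax=None, **bar_kw):
    """Bar plot of the 12-bin active-neuron fraction histogram."""
    ax = _get_ax(ax)
    series = hist.as_series()
    ax.bar(range(12), series.to_numpy(), **bar_kw)
    ax.set_xticks(range(12), series.index, rotation=45, fontsize=7)
    ax.set_xlabel("active neurons (%)")
    ax.set_ylabel("clusters")
    return ax


def plot_frequency_loglog(
    freqs: np.ndarray, n_neurons: np.ndarray, fit: PowerLawFit | None = None, ax=None
):
    """Log-log neuron-count vs response-frequency scatter with fitted line."""
    ax = _get_ax(ax)
    keep = (np.asarray(freqs) >= 1) & (np.asarray(n_neurons) > 0)
    ax.loglog(np.asarray(freqs)[keep], np.asarray(n_neurons)[keep], "o", mfc="none")
    if fit is not None and fit.fitted:
        x = np.asarray(freqs, dtype=float)[keep]
        ax.loglog(x, 10**fit.intercept * x**fit.slope, "-", label=f"slope {fit.slope:.3f}")
        ax.legend()
    ax.set_xlabel("responses per recording")
    ax.set_ylabel("number of neurons")
    return ax


def plot_phase_histogram(phases: np.ndarray, bins: int = 20, ax=None, **hist_kw):
    """Histogram of right-onset phases within the left burst cycle."""
    ax = _get_ax(ax)
    ax.hist(np.asarray(phases), bins=bins, range=(0, 1), **hist_kw)
    ax.set_xlabel("right onset phase (cycle fraction)")
    ax.set_ylabel("count")
    return ax
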
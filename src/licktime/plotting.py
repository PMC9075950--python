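"""Basic display helpers: PSTHs and phase histograms.

Smoothing (Gaussian kernel, sigma = 50 ms) is applied only here, for
display; statistics always run on the raw binned values.
"""

from __future__ import annotations

import numpy as np

from .types import RateSeries


def smooth_for_display(series: RateSeries, sigma_s: float = 0.05) -> np.ndarray:
    """Gaussian-smoothed copy of the PSTH values (display only)."""
    if series.bin_width_s is None or series.values.size < 3:
        return series.values.copy()
    half = max(1, int(np.ceil(3 * sigma_s / series.bin_width_s)))
    x = np.arange(-half, half + 1) * series.bin_width_s
    k = np.exp(-0.5 * (x / sigma_s) ** 2)
    k /= k.sum()
    return np.convolve(series.values, k, mode="same")


def plot_psth(series: RateSeries, ax=None, label=None, smooth=True):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    y = smooth_for_display(series) if smooth else series.values
    ax.plot(series.times, y, label=label)
    if series.sem is not None:
        ax.fill_between(
            series.times, y - series.sem, y + series.sem, alpha=0.3
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("rate (Hz)")
    if label:
        ax.legend()
    return ax


def plot_phase_histogram(histogram: np.ndarray, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n = histogram.size
    edges = 2 * np.pi * np.arange(n + 1) / n
    ax.bar(
        edges[:-1],
        histogram,
        width=np.diff(edges),
        align="edge",
        edgecolor="k",
    )
    ax.set_xlabel("lick phase (rad)")
    ax.set_ylabel("spike count")
    ax.set_xticks([0, np.pi, 2 * np.pi])
    ax.set_xticklabels(["0", "π", "2π"])
    return ax
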
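"""Trajectory statistics: moments, histograms, autocorrelation, spectra, bimodality.

All statistics are pure functions of a series or :class:`Trajectory`;
stationary quantities discard a configurable burn-in (default the first 20%
of the samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "TrajectoryStats",
    "stationary_stats",
    "autocorrelation",
    "power_spectrum",
    "bimodality",
    "batch_mean_sem",
]


@dataclass
class TrajectoryStats:
    mean: float
    variance: float
    fano: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def _burned(series, burn_in: float) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    start = int(burn_in * x.size)
    return x[start:]


def stationary_stats(
    series, burn_in: float = 0.2, integer_bins: bool | None = None
) -> TrajectoryStats:
    """Stationary mean/variance/Fano factor and histogram after burn-in.

    Integer-valued series get unit-width bins centred on integers; continuous
    series use the Freedman-Diaconis rule.
    """
    x = _burned(series, burn_in)
    mean = float(np.mean(x))
    var = float(np.var(x))
    if integer_bins is None:
        integer_bins = bool(np.allclose(x, np.round(x)))
    if integer_bins:
        lo, hi = int(np.floor(x.min())), int(np.ceil(x.max()))
        edges = np.arange(lo - 0.5, hi + 1.5)
    else:
        edges = np.histogram_bin_edges(x, bins="fd")
    counts, edges = np.histogram(x, bins=edges)
    return TrajectoryStats(
        mean=mean,
        variance=var,
        fano=var / mean if mean > 0 else float("nan"),
        hist_edges=edges,
        hist_counts=counts,
    )


def autocorrelation(series, max_lag: int) -> np.ndarray:
    """Biased normalized autocovariance, acf[0] = 1.

    A constant series returns 1 at all lags by convention (a deterministic
    steady state has no decorrelation to measure).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 * max_lag:
        raise ValueError("series must be at least twice max_lag long")
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / x.size
    if c0 == 0.0:
        return np.ones(max_lag + 1)
    n = x.size
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = np.dot(x[: n - k], x[k:]) / n / c0
    return acf


def power_spectrum(series, dt: float, nperseg: int | None = None):
    """Averaged periodogram (Welch) of the mean-subtracted series.

    Returns ``(frequencies, power)``; the zero-frequency bin is excluded.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    if nperseg is None:
        nperseg = min(x.size, max(256, x.size // 8))
    freqs, power = _signal.welch(x, fs=1.0 / dt, nperseg=nperseg, detrend="constant")
    return freqs[1:], power[1:]


def dominant_frequency(series, dt: float, nperseg: int | None = None) -> tuple[float, float]:
    """Location of the largest spectral peak and the frequency bin width."""
    freqs, power = power_spectrum(series, dt, nperseg)
    i = int(np.argmax(power))
    return float(freqs[i]), float(freqs[1] - freqs[0])


def bimodality(
    counts,
    smooth_window: int = 5,
    dip_ratio: float = 0.8,
    min_prominence: float = 0.1,
) -> tuple[bool, list[int]]:
    """Detect bimodality of a histogram.

    The counts are smoothed with a moving average (``smooth_window`` bins).
    The histogram is bimodal iff some pair of local maxima -- each at least
    ``min_prominence`` of the tallest peak, so that tail ripples are ignored
    -- is separated by a minimum of at most ``dip_ratio`` of the lower peak
    of the pair.  Returns the verdict and the candidate mode bin indices.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need at least two bins")
    w = min(smooth_window, c.size)
    kernel = np.ones(w) / w
    # edge padding so a boundary mode (e.g. a spike at zero) is not damped
    padded = np.pad(c, (w // 2, w - 1 - w // 2), mode="edge")
    s = np.convolve(padded, kernel, mode="valid")
    maxima: list[int] = []
    for i in range(s.size):
        left = s[i - 1] if i > 0 else -np.inf
        right = s[i + 1] if i < s.size - 1 else -np.inf
        if s[i] > left and s[i] >= right and s[i] > 0:
            maxima.append(i)
    floor = min_prominence * s.max()
    maxima = [i for i in maxima if s[i] >= floor]
    if len(maxima) < 2:
        return False, maxima
    for a in range(len(maxima)):
        for b in range(a + 1, len(maxima)):
            i, j = maxima[a], maxima[b]
            dip = s[i + 1 : j].min() if j > i + 1 else min(s[i], s[j])
            if dip <= dip_ratio * min(s[i], s[j]):
                return True, maxima
    return False, maxima


def batch_mean_sem(series, n_batches: int = 20) -> tuple[float, float]:
    """Batch-means estimate of the mean and its standard error.

    Splits the (stationary) series into ``n_batches`` contiguous batches;
    the s.e. of the overall mean follows from the spread of batch means,
    which absorbs autocorrelation on scales shorter than a batch.
    """
    x = np.asarray(series, dtype=float)
    n = (x.size // n_batches) * n_batches
    if n < n_batches:
        raise ValueError("series too short for batching")
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    sem = float(means.std(ddof=1) / np.sqrt(n_batches))
    return float(means.mean()), sem
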
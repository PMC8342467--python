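"""Spike-train irregularity statistics.

These are the classic single-train metrics used to decide whether a cell
"looks bursty": the local coefficient of variation CV2, the local
variation LV, the ISI histogram (with a documented peak detector replacing
by-eye modality judgements), and the spike-count autocorrelation.  The
central negative result they support: a population can run an effective
burst code while every one of these statistics is matched by non-burst
models.

For a sequence of n ISIs,

    CV2 = (2/(n-1)) sum_i |ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i)
    LV  = (3/(n-1)) sum_i (ISI_{i+1} - ISI_i)^2 / (ISI_{i+1} + ISI_i)^2

Both are 0 for a perfectly regular train, ~1 for a Poisson process, and
invariant under uniform time rescaling.  For a gamma renewal process with
shape kappa, E[LV] = 3/(2 kappa + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .encoder import MarkedSpikeTrain

__all__ = [
    "IrregularityStats",
    "ISIHistogram",
    "cv2",
    "lv",
    "irregularity_stats",
    "isi_histogram",
    "spike_autocorrelation",
    "read_spike_times",
]

#: peaks must rise at least this fraction of the global maximum above their
#: surroundings to count as a mode.
PEAK_PROMINENCE_FRACTION = 0.05


class InsufficientDataError(ValueError):
    """Fewer ISIs than the statistic needs."""


def _check_isis(isis) -> np.ndarray:
    isis = np.asarray(isis, dtype=float)
    if isis.ndim != 1:
        raise ValueError("ISIs must be a 1-D sequence")
    if isis.size < 2:
        raise InsufficientDataError("need at least two ISIs")
    if np.any(isis <= 0):
        raise ValueError("ISIs must be positive")
    return isis


def cv2(isis) -> float:
    """Local coefficient of variation of an ordered ISI sequence."""
    isis = _check_isis(isis)
    a, b = isis[1:], isis[:-1]
    return float(2.0 * np.mean(np.abs(a - b) / (a + b)))


def lv(isis) -> float:
    """Local variation of an ordered ISI sequence."""
    isis = _check_isis(isis)
    a, b = isis[1:], isis[:-1]
    return float(3.0 * np.mean(((a - b) / (a + b)) ** 2))


@dataclass(frozen=True)
class IrregularityStats:
    cv2: float
    lv: float
    mean_rate: float  # Hz
    n_isis: int

    def to_dict(self) -> dict:
        return {"cv2": self.cv2, "lv": self.lv,
                "mean_rate_hz": self.mean_rate, "n_isis": self.n_isis}


def irregularity_stats(train: MarkedSpikeTrain) -> IrregularityStats:
    isis = train.isis()
    return IrregularityStats(cv2=cv2(isis), lv=lv(isis),
                             mean_rate=train.spike_rate_hz(),
                             n_isis=int(isis.size))


@dataclass
class ISIHistogram:
    """Normalized ISI density with a peak-count modality flag."""

    edges: np.ndarray
    density: np.ndarray   # 1/ms, integrates to 1 over the edges
    n_peaks: int
    peak_positions: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def isi_histogram(train_or_isis, bin_edges=None,
                  smoothing_sd: float | None = None) -> ISIHistogram:
    """ISI density with optional Gaussian smoothing and mode counting.

    Peaks are local maxima of the (smoothed) density with prominence at
    least 5% of the global maximum — a fixed, reproducible stand-in for
    judging modality by eye.  Edge bins can carry a mode (the density is
    padded below its minimum before peak finding).
    """
    if isinstance(train_or_isis, MarkedSpikeTrain):
        isis = train_or_isis.isis()
    else:
        isis = np.asarray(train_or_isis, dtype=float)
    if isis.size < 1:
        raise InsufficientDataError("need at least one ISI")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 200.0 + 1.0, 1.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts, edges = np.histogram(isis, bins=bin_edges)
    widths = np.diff(edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no ISIs fall inside the histogram range")
    density = counts / (total * widths)
    if smoothing_sd is not None:
        if not smoothing_sd > 0:
            raise ValueError("smoothing_sd must be positive")
        sigma_bins = smoothing_sd / float(widths[0])
        density = gaussian_filter1d(density, sigma_bins, mode="constant")
        area = np.sum(density * widths)
        if area > 0:
            density = density / area
    pad = density.min() - 1.0
    padded = np.r_[pad, density, pad]
    peaks, _ = find_peaks(padded,
                          prominence=PEAK_PROMINENCE_FRACTION * density.max())
    peaks = peaks - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ISIHistogram(edges=edges, density=density, n_peaks=int(len(peaks)),
                        peak_positions=centers[peaks])


def spike_autocorrelation(train: MarkedSpikeTrain, bin: float = 1.0,
                          max_lag: float = 100.0):
    """Spike-count autocorrelation, units [spikes]^2.

    Returns (lags_ms, correlogram, zero_lag_value): the average product of
    spike counts in bins separated by each lag, symmetric in lag, with the
    zero-lag bin reported separately.  For a homogeneous Poisson process
    the correlogram is flat at (rate * bin)^2 away from zero lag.
    """
    if not bin > 0 or not max_lag > 0:
        raise ValueError("bin and max_lag must be positive")
    n_bins = int(np.round(train.duration / bin))
    counts = np.zeros(n_bins)
    idx = np.minimum((train.times / bin).astype(np.int64), n_bins - 1)
    np.add.at(counts, idx, 1.0)
    k_max = int(np.round(max_lag / bin))
    pos = np.empty(k_max)
    for k in range(1, k_max + 1):
        pos[k - 1] = np.dot(counts[:-k], counts[k:]) / (n_bins - k)
    zero = float(np.dot(counts, counts) / n_bins)
    lags = np.concatenate([-bin * np.arange(k_max, 0, -1),
                           bin * np.arange(1, k_max + 1)])
    corr = np.concatenate([pos[::-1], pos])
    return lags, corr, zero


def read_spike_times(path_or_buf, duration: float | None = None) -> MarkedSpikeTrain:
    """Load a plain-text spike-time list (one time in ms per line)."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    times = [float(ln) for ln in text.split() if ln.strip()]
    return MarkedSpikeTrain.from_times(np.sort(np.asarray(times)), duration)
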
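"""Coherence-based lower bound on the linearly decodable information rate.

For each channel (driver input vs event-decoding potential; modulator input
vs burst-fraction estimate) the magnitude-squared coherence Phi(f) is
estimated with Welch's method (Hanning window, half-overlapping segments),
and converted to a lower bound on the mutual information rate of a
stationary Gaussian channel,

    I_lb = -integral_0^{f_Nyq} log2(1 - Phi(f)) df    [bits/s].

The bound is exact for jointly Gaussian processes and is a lower bound in
general; because the coherence of finite data is biased upward by roughly
1/(number of segments), estimates carry a positive noise floor that shrinks
with the number of averaged segments.  The total multiplexed rate is
defined as the sum of the two channel rates, which for independent inputs
never exceeds the joint information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .signals import SignalTrace

__all__ = [
    "SpectralParams",
    "InfoResult",
    "welch_coherence",
    "stein_info_rate",
    "multiplex_info",
    "normalize_info",
]

#: coherence cap; the integrand diverges at Phi = 1, which only arises from
#: degenerate estimation (e.g. a trace compared with itself).
COHERENCE_CLIP = 1.0 - 1e-6


@dataclass(frozen=True)
class SpectralParams:
    """Welch estimation settings.

    ``window_length`` is the Hanning-window length in seconds (8.192 s at
    the 1 ms decoding grid makes a 8192-sample window); ``overlap`` is in
    seconds and defaults to half the window.
    """

    window_length: float = 8.192
    overlap: float | None = None
    detrend: str = "constant"

    def nperseg(self, dt_ms: float) -> int:
        return int(round(self.window_length * 1000.0 / dt_ms))

    def noverlap(self, dt_ms: float) -> int:
        if self.overlap is None:
            return self.nperseg(dt_ms) // 2
        return int(round(self.overlap * 1000.0 / dt_ms))


@dataclass
class InfoResult:
    """Per-frequency and integrated information for the two channels."""

    frequencies: np.ndarray
    coherence_driver: np.ndarray
    coherence_modulator: np.ndarray
    density_driver: np.ndarray      # bits/s/Hz
    density_modulator: np.ndarray
    rate_driver: float              # bits/s
    rate_modulator: float
    normalized: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def rate_total(self) -> float:
        return self.rate_driver + self.rate_modulator

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency_Hz": self.frequencies,
            "coherence_driver": self.coherence_driver,
            "coherence_modulator": self.coherence_modulator,
            "info_density_driver": self.density_driver,
            "info_density_modulator": self.density_modulator,
        })

    def summary(self) -> dict:
        out = {
            "rate_driver_bits_per_s": self.rate_driver,
            "rate_modulator_bits_per_s": self.rate_modulator,
            "rate_total_bits_per_s": self.rate_total,
        }
        if self.normalized:
            out["normalized"] = dict(self.normalized)
        out.update(self.meta)
        return out


def welch_coherence(x: SignalTrace, y: SignalTrace, sp: SpectralParams):
    """Magnitude-squared coherence of two traces on a common grid.

    Traces longer than their common overlap are cropped from the front;
    fewer than two Welch segments is an error (the coherence of a single
    segment is identically 1).  Returns (frequencies_Hz, coherence).
    """
    if abs(x.dt - y.dt) > 1e-9:
        raise ValueError("traces must share the sampling interval")
    n = min(len(x), len(y))
    nperseg = sp.nperseg(x.dt)
    noverlap = sp.noverlap(x.dt)
    if n < nperseg + (nperseg - noverlap):
        raise ValueError(
            f"need at least 2 Welch segments: {n} samples < "
            f"{nperseg + nperseg - noverlap} for window {nperseg}")
    fs = 1000.0 / x.dt
    f, coh = _sig.coherence(x.values[:n], y.values[:n], fs=fs,
                            window="hann", nperseg=nperseg,
                            noverlap=noverlap, detrend=sp.detrend)
    return f, np.clip(coh, 0.0, COHERENCE_CLIP)


def stein_info_rate(frequencies: np.ndarray, coherence: np.ndarray):
    """Integrate -log2(1 - Phi) over frequency.

    ``frequencies`` in Hz spanning [0, Nyquist]; returns
    (density bits/s/Hz, rate bits/s).  Integrating over physical frequency
    up to fs/2 equals the normalized-frequency integral times the sampling
    rate.
    """
    coherence = np.asarray(coherence, dtype=float)
    if np.any(coherence < 0) or np.any(coherence > 1):
        raise ValueError("coherence must lie in [0, 1] after clipping")
    density = -np.log2(1.0 - np.clip(coherence, 0.0, COHERENCE_CLIP))
    rate = float(np.trapezoid(density, frequencies))
    return density, rate


def multiplex_info(driver_sig: SignalTrace, modulator_sig: SignalTrace,
                   decoded, sp: SpectralParams) -> InfoResult:
    """Information rates of the two multiplexed channels.

    Driver channel: coherence of the driver input with the event-decoding
    potential.  Modulator channel: coherence of the modulator input with
    the burst-fraction estimate.  Both inputs must be on the decoding grid
    (coherence magnitude is delay-invariant for stationary signals, so no
    alignment beyond a common grid is needed).
    """
    f, coh_d = welch_coherence(driver_sig, decoded.u_event, sp)
    _, coh_m = welch_coherence(modulator_sig, decoded.burst_fraction, sp)
    dens_d, rate_d = stein_info_rate(f, coh_d)
    dens_m, rate_m = stein_info_rate(f, coh_m)
    return InfoResult(f, coh_d, coh_m, dens_d, dens_m, rate_d, rate_m,
                      meta={"window_length_s": sp.window_length})


def normalize_info(results, perfect_baseline):
    """Normalize a sweep by the maxima of a perfect-decoder sweep.

    ``results`` and ``perfect_baseline`` are sequences of
    (rate_driver, rate_modulator) pairs or InfoResult objects over the same
    swept values.  Each channel is divided by the maximum of the
    corresponding perfect-decoder channel over the sweep, and the total by
    the maximum perfect total.  Returns a list of dicts with keys
    'driver', 'modulator', 'total' (unitless fractions).
    """
    def rates(seq):
        out = []
        for r in seq:
            if isinstance(r, InfoResult):
                out.append((r.rate_driver, r.rate_modulator))
            else:
                out.append((float(r[0]), float(r[1])))
        return out

    res = rates(results)
    base = rates(perfect_baseline)
    if not base:
        raise ValueError("perfect baseline is empty")
    max_d = max(d for d, _ in base)
    max_m = max(m for _, m in base)
    max_t = max(d + m for d, m in base)
    if min(max_d, max_m, max_t) <= 0:
        raise ValueError("perfect baseline has non-positive channel maxima")
    return [{"driver": d / max_d, "modulator": m / max_m,
             "total": (d + m) / max_t} for d, m in res]
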
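"""Burst-Spike-Response Model (BSRM) population encoder and reference generators.

The BSRM is a marked point process that multiplexes two signals into one
spike train.  A *driver* input sets the instantaneous rate of *events*
through an exponential link applied to a membrane potential with a relative
refractory kernel; at each event a *modulator* input sets, through a
sigmoid link, the probability that the event is a burst, in which case a
fixed number of intra-burst spikes with gamma-distributed short intervals
is appended.  Every spike carries a generative label (singlet event, first
spike of a burst, intra-burst spike), which is the simulator's ground truth
and what the perfect decoder reads.

Reference generators (homogeneous Poisson, refractory gamma renewal, and a
burst-free univariate SRM) produce the non-burst-coding control trains used
by the irregularity comparisons.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy.special import expit

from . import signals as _signals
from ._kernels import _bsrm_core, _renewal_core
from .signals import SignalParams, SignalTrace, sample_ou

__all__ = [
    "SpikeLabel",
    "EncoderParams",
    "MarkedSpikeTrain",
    "PopulationRaster",
    "CalibrationError",
    "refractory_kernel",
    "instantaneous_intensities",
    "simulate_bsrm",
    "simulate_population",
    "calibrate_event_threshold",
    "simulate_reference",
]


class SpikeLabel(IntEnum):
    SINGLET_EVENT = 0
    BURST_FIRST = 1
    INTRA_BURST = 2


_LABEL_NAMES = {0: "singlet_event", 1: "burst_first", 2: "intra_burst"}
_LABEL_CODES = {v: k for k, v in _LABEL_NAMES.items()}


class CalibrationError(RuntimeError):
    """Raised when the event-threshold search cannot reach the target rate."""


@dataclass(frozen=True)
class EncoderParams:
    """Parameters of the encoding cells.

    Defaults are the canonical operating point: resting potential 0 mV,
    burst threshold 4.5 mV with scale 1/3 mV, intra-burst gamma ISIs with
    scale 20/3 ms and shape 1.5 (mean 10 ms, i.e. a 100-200 Hz intra-burst
    rate), a 2 ms absolute refractory period, event-link scale 2 mV and a
    population of 200 cells.  ``tau_rel`` (relative refractory time
    constant) and ``theta_e`` (event threshold) are the experiment knobs;
    ``theta_e`` is normally set by :func:`calibrate_event_threshold` against
    a 10 Hz event-rate target.  ``lambda0`` is the event-intensity scale in
    Hz: the event rate is ``lambda0 * exp((v - theta_e) / alpha_e)``, so
    results only depend on the gauge-invariant combination of
    ``(lambda0, theta_e)``.

    ``eta_amp`` scales the relative refractory kernel,
    ``eta(t) = -eta_amp * exp(-t / tau_rel)``.  The default 10 mV is a
    typical spike-response reset scale; it is what lets long relative
    refractory periods carve the trough between the intra-burst and
    inter-event ISI modes (a unit amplitude against the 2 mV link scale
    suppresses the intensity by at most 39% and leaves the ISI
    distribution unimodal at every tau_rel).
    """

    tau_rel: float
    theta_e: float = 0.0
    eta_amp: float = 10.0
    v0: float = 0.0
    theta_b: float = 4.5
    alpha_b: float = 1.0 / 3.0
    gamma_scale: float = 20.0 / 3.0
    gamma_shape: float = 1.5
    delta_ref: float = 2.0
    alpha_e: float = 2.0
    n_ib: int = 1
    n_pop: int = 200
    lambda0: float = 10.0

    def __post_init__(self) -> None:
        if self.delta_ref < 0:
            raise ValueError("delta_ref must be >= 0")
        if not (self.gamma_scale > 0 and self.gamma_shape > 0):
            raise ValueError("gamma ISI scale and shape must be positive")
        if not (self.alpha_e > 0 and self.alpha_b > 0):
            raise ValueError("link scales alpha_e, alpha_b must be positive")
        if not self.tau_rel > 0:
            raise ValueError("tau_rel must be positive")
        if self.eta_amp < 0:
            raise ValueError("eta_amp must be >= 0")
        if self.n_ib < 1 or int(self.n_ib) != self.n_ib:
            raise ValueError("n_ib must be an integer >= 1")
        if self.n_pop < 1:
            raise ValueError("n_pop must be >= 1")
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be positive")


@dataclass
class MarkedSpikeTrain:
    """Spike times with per-spike generative labels.

    ``times`` are strictly increasing (ms) in [0, duration); ``labels``
    holds a :class:`SpikeLabel` code per spike.  Event spikes are the
    singlets plus the burst-first spikes; intra-burst spikes only ever
    appear as a run of exactly ``n_ib`` spikes following a burst-first
    spike (possibly truncated at the end of the simulation window).
    """

    times: np.ndarray
    labels: np.ndarray
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.times.shape != self.labels.shape:
            raise ValueError("times and labels must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def event_mask(self) -> np.ndarray:
        return self.labels != SpikeLabel.INTRA_BURST

    @property
    def event_times(self) -> np.ndarray:
        return self.times[self.event_mask]

    @property
    def n_events(self) -> int:
        return int(self.event_mask.sum())

    @property
    def n_bursts(self) -> int:
        return int((self.labels == SpikeLabel.BURST_FIRST).sum())

    def burst_fraction(self) -> float:
        """Empirical fraction of events that are bursts."""
        n_ev = self.n_events
        return self.n_bursts / n_ev if n_ev else np.nan

    def event_rate_hz(self) -> float:
        return self.n_events / (self.duration / 1000.0)

    def spike_rate_hz(self) -> float:
        return len(self) / (self.duration / 1000.0)

    def check_grammar(self, n_ib: int) -> None:
        """Verify the label grammar (singlet | burst_first intra^n_ib)*.

        The final burst of a train may be truncated by the end of the
        simulation window, so a shorter intra-burst run is tolerated there
        only.  Raises ``ValueError`` on the first violation.
        """
        labels = self.labels
        i, n = 0, labels.size
        while i < n:
            if labels[i] == SpikeLabel.SINGLET_EVENT:
                i += 1
            elif labels[i] == SpikeLabel.BURST_FIRST:
                j = i + 1
                while j < n and j - i <= n_ib and labels[j] == SpikeLabel.INTRA_BURST:
                    j += 1
                run = j - i - 1
                if run != n_ib and j < n:
                    raise ValueError(
                        f"burst at spike {i} has {run} intra-burst spikes, expected {n_ib}")
                i = j
            else:
                raise ValueError(f"orphan intra-burst label at spike {i}")

    # -- CSV round trip -----------------------------------------------------
    def to_csv(self, path_or_buf, neuron_id: int = 0) -> None:
        header = "# " + json.dumps({"duration": self.duration, **self.meta})
        buf = io.StringIO()
        buf.write(header + "\n")
        buf.write("time_ms,label,neuron_id\n")
        for t, lab in zip(self.times, self.labels):
            buf.write(f"{t:.10g},{_LABEL_NAMES[int(lab)]},{neuron_id}\n")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "MarkedSpikeTrain":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        meta = {}
        if lines and lines[0].startswith("#"):
            meta = json.loads(lines.pop(0)[1:].strip())
        if lines and lines[0].startswith("time_ms"):
            lines.pop(0)
        times, labels = [], []
        for ln in lines:
            t, lab = ln.split(",")[:2]
            times.append(float(t))
            labels.append(_LABEL_CODES[lab.strip()])
        duration = meta.pop("duration", (times[-1] + 1.0) if times else 1.0)
        return cls(np.array(times), np.array(labels, dtype=np.int8), duration, meta)

    @classmethod
    def from_times(cls, times: Sequence[float], duration: float | None = None,
                   label: SpikeLabel = SpikeLabel.SINGLET_EVENT) -> "MarkedSpikeTrain":
        """Wrap a plain list of spike times (all one label)."""
        t = np.asarray(times, dtype=float)
        if duration is None:
            duration = float(t[-1] + 1.0) if t.size else 1.0
        return cls(t, np.full(t.size, int(label), dtype=np.int8), duration)


@dataclass
class PopulationRaster:
    """A population of marked spike trains sharing one input pair."""

    trains: list
    duration: float
    params: EncoderParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trains:
            raise ValueError("raster must contain at least one train")
        for tr in self.trains:
            if abs(tr.duration - self.duration) > 1e-6:
                raise ValueError("all trains must share the raster duration")

    def __len__(self) -> int:
        return len(self.trains)

    def __iter__(self):
        return iter(self.trains)

    def event_rate_hz(self) -> float:
        return float(np.mean([tr.event_rate_hz() for tr in self.trains]))

    def burst_fraction(self) -> float:
        bursts = sum(tr.n_bursts for tr in self.trains)
        events = sum(tr.n_events for tr in self.trains)
        return bursts / events if events else np.nan


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def refractory_kernel(elapsed, tau_rel: float, amplitude: float = 1.0):
    """Relative refractory kernel eta: -amplitude * exp(-elapsed/tau_rel), causal."""
    elapsed = np.asarray(elapsed, dtype=float)
    out = np.where(elapsed > 0, -amplitude * np.exp(-elapsed / tau_rel), 0.0)
    return out if out.ndim else float(out)


def instantaneous_intensities(driver_v: SignalTrace, modulator_v: SignalTrace,
                              params: EncoderParams,
                              last_spike_time: float | None = None):
    """Event rate (Hz) and burst probability traces from the two inputs.

    The event-potential is ``v_e = eta(t - t') + driver + v0`` (eta omitted
    when ``last_spike_time`` is None) and the event rate is the exponential
    link ``lambda0 * exp((v_e - theta_e)/alpha_e)``; the burst potential is
    ``v_b = modulator + v0`` and the burst probability is the sigmoid link
    ``expit((v_b - theta_b)/alpha_b)``.
    """
    if not driver_v.same_grid(modulator_v):
        raise ValueError("driver and modulator traces must share the same grid")
    v_e = driver_v.values + params.v0
    if last_spike_time is not None:
        v_e = v_e + refractory_kernel(driver_v.times - last_spike_time,
                                      params.tau_rel, params.eta_amp)
    rate = params.lambda0 * np.exp((v_e - params.theta_e) / params.alpha_e)
    p = expit((modulator_v.values + params.v0 - params.theta_b) / params.alpha_b)
    rate_tr = SignalTrace(driver_v.t0, driver_v.dt, rate)
    p_tr = SignalTrace(driver_v.t0, driver_v.dt, p)
    return rate_tr, p_tr


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _kernel_seed(ss: np.random.SeedSequence) -> int:
    # numba's legacy RNG takes a 32-bit seed; keep it below 2**31.
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def simulate_bsrm(params: EncoderParams, driver: SignalTrace,
                  modulator: SignalTrace, seed) -> MarkedSpikeTrain:
    """Simulate one BSRM neuron over the span of the input traces.

    Events are sampled by per-step Bernoulli thinning with spike
    probability ``1 - exp(-rho(t) dt)`` on the input grid (exact in the
    dt -> 0 limit); intra-burst ISIs are gamma samples rejected below the
    absolute refractory period.  Identical (params, inputs, seed) gives an
    identical train.
    """
    if not driver.same_grid(modulator):
        raise ValueError("driver and modulator traces must share the same grid")
    if len(driver) < 1:
        raise ValueError("input traces must cover at least one step")
    kseed = _kernel_seed(_as_seedseq(seed))
    duration = len(driver) * driver.dt
    # Spike count is bounded by duration/delta_ref when delta_ref > 0; start
    # with a generous buffer and grow if the kernel reports overflow.
    if params.delta_ref > 0:
        cap = int(duration / params.delta_ref) + params.n_ib + 16
    else:
        cap = int(duration * 2) + 1024
    while True:
        times = np.empty(cap)
        labels = np.empty(cap, dtype=np.int8)
        k = _bsrm_core(driver.values, modulator.values, driver.dt,
                       params.v0, params.theta_b, params.alpha_b,
                       params.gamma_scale, params.gamma_shape,
                       params.delta_ref, params.tau_rel, params.eta_amp,
                       params.theta_e, params.alpha_e, int(params.n_ib),
                       params.lambda0, kseed, times, labels)
        if k >= 0:
            break
        cap *= 4
    return MarkedSpikeTrain(times[:k].copy(), labels[:k].copy(), duration,
                            meta={"model": "bsrm", "tau_rel": params.tau_rel,
                                  "theta_e": params.theta_e})


def simulate_population(params: EncoderParams, driver: SignalTrace,
                        modulator: SignalTrace, seed) -> PopulationRaster:
    """``n_pop`` independent BSRM neurons sharing one input pair.

    The seed is split into one substream per neuron, so neuron j of a
    population equals a single-cell simulation run on substream j.
    """
    ss = _as_seedseq(seed)
    children = ss.spawn(params.n_pop)
    trains = [simulate_bsrm(params, driver, modulator, child) for child in children]
    return PopulationRaster(trains, trains[0].duration, params)


def simulate_reference(kind: str, rate: float | None = None,
                       shape: float | None = None, delta_ref: float = 0.0,
                       duration: float | None = None, seed=0,
                       params: EncoderParams | None = None,
                       driver: SignalTrace | None = None) -> MarkedSpikeTrain:
    """Non-burst-coding reference spike trains (all labels singlet).

    kind='poisson'
        Exponential ISIs, optionally shifted by ``delta_ref``; the
        exponential mean is set so the overall mean ISI is 1000/rate ms.
    kind='gamma_renewal'
        i.i.d. Gamma(shape) ISIs, optionally shifted by ``delta_ref``, with
        the scale chosen so the mean ISI matches the requested rate.
    kind='srm'
        A univariate spike-response model: the BSRM with the burst pathway
        silenced (burst probability forced to 0), driven by ``driver``.
    """
    if kind == "srm":
        if params is None or driver is None:
            raise ValueError("srm reference needs params and a driver trace")
        no_burst = replace(params, theta_b=1e15)
        quiet = SignalTrace(driver.t0, driver.dt, np.zeros(len(driver)))
        train = simulate_bsrm(no_burst, driver, quiet, seed)
        train.meta["model"] = "srm"
        return train
    if kind not in ("poisson", "gamma_renewal"):
        raise ValueError(f"unknown reference kind: {kind!r}")
    if rate is None or not rate > 0:
        raise ValueError("rate must be positive")
    if duration is None or not duration > 0:
        raise ValueError("duration must be positive")
    mean_isi = 1000.0 / rate
    free = mean_isi - delta_ref
    if free <= 0:
        raise ValueError("requested rate is unreachable with this delta_ref")
    use_gamma = kind == "gamma_renewal"
    if use_gamma:
        if shape is None or not shape > 0:
            raise ValueError("gamma_renewal needs a positive shape")
        g_shape, g_scale = float(shape), free / shape
        exp_mean = 0.0
    else:
        g_shape, g_scale = 1.0, 1.0
        exp_mean = free
    n_max = int(duration / mean_isi * 3) + 200
    kseed = _kernel_seed(_as_seedseq(seed))
    times = np.empty(n_max)
    k = _renewal_core(n_max, delta_ref, exp_mean, g_shape, g_scale,
                      duration, kseed, use_gamma, times)
    return MarkedSpikeTrain(times[:k].copy(),
                            np.zeros(k, dtype=np.int8), duration,
                            meta={"model": kind, "rate": rate})


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_event_threshold(params: EncoderParams, target_event_rate: float,
                              driver_params: SignalParams = _signals.DRIVER,
                              modulator_params: SignalParams = _signals.MODULATOR,
                              tolerance: float = 0.5, seed=0,
                              sim_duration: float = 400_000.0,
                              dt: float = 0.1,
                              bracket: tuple[float, float] = (-30.0, 30.0)) -> float:
    """Find theta_e giving the target long-run event rate (Hz).

    Bisection on a common-random-numbers rate estimate: the O-U inputs and
    the thinning stream are frozen across evaluations, so the simulated
    event rate is a monotonically decreasing, nearly deterministic function
    of theta_e.  The returned threshold is validated on a fresh substream;
    a miss beyond ``tolerance`` raises :class:`CalibrationError`.
    """
    if not target_event_rate > 0:
        raise ValueError("target_event_rate must be positive")
    ss = _as_seedseq(seed)
    sig_ss, thin_ss, check_ss = ss.spawn(3)
    d_ss, m_ss = sig_ss.spawn(2)
    driver = sample_ou(driver_params, dt, sim_duration, d_ss)
    modulator = sample_ou(modulator_params, dt, sim_duration, m_ss)

    def rate_at(theta: float) -> float:
        p = replace(params, theta_e=theta)
        return simulate_bsrm(p, driver, modulator, thin_ss).event_rate_hz()

    lo, hi = bracket
    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not (r_lo >= target_event_rate >= r_hi):
        raise CalibrationError(
            f"target {target_event_rate} Hz outside bracket rates "
            f"[{r_hi:.3g}, {r_lo:.3g}] Hz for theta_e in [{lo}, {hi}] mV")
    theta = 0.5 * (lo + hi)
    for _ in range(60):
        theta = 0.5 * (lo + hi)
        r = rate_at(theta)
        if abs(r - target_event_rate) <= 0.25 * tolerance or hi - lo < 5e-3:
            break
        if r > target_event_rate:
            lo = theta
        else:
            hi = theta
    # validate on an independent substream
    d2, m2, t2 = check_ss.spawn(3)
    drv2 = sample_ou(driver_params, dt, sim_duration, d2)
    mod2 = sample_ou(modulator_params, dt, sim_duration, m2)
    achieved = simulate_bsrm(replace(params, theta_e=theta), drv2, mod2, t2).event_rate_hz()
    if abs(achieved - target_event_rate) > tolerance:
        raise CalibrationError(
            f"calibration validated at {achieved:.3f} Hz, target "
            f"{target_event_rate} Hz +/- {tolerance} (theta_e={theta:.4f})")
    return float(theta)
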
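"""Short-term-plasticity decoders.

Two post-synaptic cells read the encoding population through synapses whose
efficacy depends on spike history: a depressing synapse passes spikes
preceded by long ISIs (events), a facilitating synapse passes spikes
preceded by short ISIs (bursts).  Weighted spikes are averaged over the
population, filtered by a rise/decay synaptic kernel into membrane
potentials u_event and u_burst, and the burst-fraction estimate is the
lagged quotient u_burst(t) / u_event(t - lag).

Three weighting rules are available:

``stp1`` (sharp)
    Weight 1 iff the immediately preceding ISI is above (depressing) or
    below (facilitating) the ISI threshold theta_w; renewal dynamics.
``stp2`` (smooth)
    A linear-nonlinear cascade: a sigmoid applied to ``a * c + b`` where
    ``c`` sums a smooth causal kernel, ``1 - sigmoid((u - theta_w)/tau_sigma)``,
    over all earlier spikes.  With the facilitating gains (+40, -20) a
    spike is passed once it has been primed by enough recent spikes, which
    lets the rule count the n_ib priming intervals of longer bursts
    (gain 40 / n_ib).
``perfect``
    The oracle: weights taken from the simulator's generative labels
    (event channel marks singlets and burst-first spikes, burst channel
    marks the last intra-burst spike of each burst, which is when a
    facilitating synapse would fire as well).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._kernels import _stp2_priming
from .encoder import MarkedSpikeTrain, PopulationRaster, SpikeLabel
from .signals import SignalTrace

__all__ = [
    "STPParams",
    "SynapseParams",
    "DecodedTraces",
    "spike_weights",
    "perfect_weights",
    "population_activity",
    "synaptic_kernel",
    "synaptic_potential",
    "decode_burst_fraction",
    "decode_raster",
    "tune_decoder",
]


@dataclass(frozen=True)
class STPParams:
    """One synaptic weighting rule.

    ``rule`` is 'stp1', 'stp2' or 'perfect'; ``mode`` is 'event'
    (depressing readout) or 'burst' (facilitating readout).  ``theta_w``
    is the ISI threshold in ms, ``tau_sigma`` the STP2 smoothness in ms,
    and (a, b) the gain and offset of the cascade nonlinearity.
    """

    rule: str
    mode: str
    theta_w: float = 10.0
    tau_sigma: float | None = None
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.rule not in ("stp1", "stp2", "perfect"):
            raise ValueError(f"unknown STP rule {self.rule!r}")
        if self.mode not in ("event", "burst"):
            raise ValueError(f"unknown STP mode {self.mode!r}")
        if self.rule != "perfect" and not self.theta_w > 0:
            raise ValueError("theta_w must be positive")
        if self.rule == "stp2" and (self.tau_sigma is None or not self.tau_sigma > 0):
            raise ValueError("stp2 requires a positive tau_sigma")

    # -- factories ----------------------------------------------------------
    @classmethod
    def stp1_depressing(cls, theta_w: float) -> "STPParams":
        return cls("stp1", "event", theta_w, a=-1.0, b=0.5)

    @classmethod
    def stp1_facilitating(cls, theta_w: float) -> "STPParams":
        return cls("stp1", "burst", theta_w, a=1.0, b=-0.5)

    @classmethod
    def stp2_depressing(cls, theta_w: float, tau_sigma: float) -> "STPParams":
        return cls("stp2", "event", theta_w, tau_sigma, a=-40.0, b=20.0)

    @classmethod
    def stp2_facilitating(cls, theta_w: float, tau_sigma: float,
                          n_ib: int = 1) -> "STPParams":
        return cls("stp2", "burst", theta_w, tau_sigma, a=40.0 / n_ib, b=-20.0)

    @classmethod
    def perfect(cls, mode: str) -> "STPParams":
        return cls("perfect", mode)


@dataclass(frozen=True)
class SynapseParams:
    """Post-synaptic filter: resting potential, weight scale and rise/decay times."""

    v_syn: float = 1.0
    g_bar: float = 1.0
    tau_rise: float = 3.0
    tau_decay: float = 5.0

    def __post_init__(self) -> None:
        for name in ("v_syn", "g_bar", "tau_rise", "tau_decay"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DecodedTraces:
    """The decoder outputs: two membrane potentials and the burst-fraction quotient."""

    u_event: SignalTrace
    u_burst: SignalTrace
    burst_fraction: SignalTrace
    lag: float
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-spike weights
# ---------------------------------------------------------------------------

def perfect_weights(train: MarkedSpikeTrain, channel: str) -> np.ndarray:
    """Oracle weights from the generative labels.

    Event channel: 1 on singlet and burst-first spikes.  Burst channel: 1
    on the last intra-burst spike of each burst (0 elsewhere), aligning the
    oracle readout with the time a facilitating synapse would transmit.
    """
    labels = train.labels
    if channel == "event":
        return (labels != SpikeLabel.INTRA_BURST).astype(float)
    if channel != "burst":
        raise ValueError(f"unknown channel {channel!r}")
    w = np.zeros(labels.size)
    is_ib = labels == SpikeLabel.INTRA_BURST
    if labels.size:
        last_of_run = is_ib & np.r_[is_ib[1:] == False, True]  # noqa: E712
        w[last_of_run] = 1.0
    return w


def spike_weights(train: MarkedSpikeTrain, stp: STPParams) -> np.ndarray:
    """Per-spike weights in [0, 1] under the given STP rule.

    A spike with no predecessor counts as having an infinite preceding ISI
    (depressing weight 1, facilitating weight 0).  The STP2 kernel sum is
    strictly causal: it excludes the spike being weighted.
    """
    times = train.times
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be sorted and strictly increasing")
    if times.size == 0:
        return np.zeros(0)
    if stp.rule == "perfect":
        return perfect_weights(train, stp.mode)
    if stp.rule == "stp1":
        prev_isi = np.r_[np.inf, np.diff(times)]
        # ties at exactly theta_w (grid-locked spike times) go to the
        # depressing side so the two sharp rules partition every spike
        if stp.mode == "event":
            return (prev_isi >= stp.theta_w).astype(float)
        return (prev_isi < stp.theta_w).astype(float)
    # stp2
    c = _stp2_priming(times, stp.theta_w, stp.tau_sigma)
    a = stp.a if stp.a is not None else (40.0 if stp.mode == "burst" else -40.0)
    b = stp.b if stp.b is not None else (-20.0 if stp.mode == "burst" else 20.0)
    return expit(a * c + b)


# ---------------------------------------------------------------------------
# population traces
# ---------------------------------------------------------------------------

def population_activity(raster: PopulationRaster, stp: STPParams,
                        dt_bin: float = 1.0) -> SignalTrace:
    """Neuron-averaged weighted spike train, binned at dt_bin.

    Each bin holds (1/N) times the summed weights of the spikes it
    contains — binned delta mass, not a density — so the trace sums to
    (1/N) * total weight.
    """
    if not dt_bin > 0:
        raise ValueError("dt_bin must be positive")
    n_bins = int(np.round(raster.duration / dt_bin))
    a = np.zeros(n_bins)
    for tr in raster.trains:
        w = spike_weights(tr, stp)
        idx = np.minimum((tr.times / dt_bin).astype(np.int64), n_bins - 1)
        np.add.at(a, idx, w)
    a /= len(raster)
    return SignalTrace(0.0, dt_bin, a)


def synaptic_kernel(t, syn: SynapseParams):
    """kappa_syn(t) = g_bar (1 - exp(-t/tau_rise)) exp(-t/tau_decay), causal."""
    t = np.asarray(t, dtype=float)
    k = syn.g_bar * (1.0 - np.exp(-t / syn.tau_rise)) * np.exp(-t / syn.tau_decay)
    return np.where(t >= 0, k, 0.0)


def synaptic_potential(a: SignalTrace, syn: SynapseParams, n_pop: int) -> SignalTrace:
    """Membrane potential u = N [kappa_syn * A](t) + v_syn."""
    support = 12.0 * syn.tau_decay
    tk = np.arange(0.0, support, a.dt)
    kern = synaptic_kernel(tk, syn)
    u = n_pop * np.convolve(a.values, kern)[: len(a)] + syn.v_syn
    return SignalTrace(a.t0, a.dt, u)


def decode_burst_fraction(u_burst: SignalTrace, u_event: SignalTrace,
                          lag: float) -> SignalTrace:
    """Lagged quotient u_burst(t) / u_event(t - lag) on the overlap.

    The lag compensates the intra-burst intervals plus synaptic rise that
    delay the facilitating readout relative to the event readout; 9 ms is
    the doublet default.  u_event is bounded away from zero by the resting
    potential whenever all weights are non-negative, so the division is
    well defined.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if abs(u_burst.dt - u_event.dt) > 1e-9:
        raise ValueError("traces must share the sampling interval")
    shift = int(round(lag / u_burst.dt))
    if abs(shift * u_burst.dt - lag) > 1e-6:
        raise ValueError("lag must be a multiple of the trace dt")
    n = min(len(u_burst), len(u_event))
    if shift >= n:
        raise ValueError("lag exceeds the trace length")
    vals = u_burst.values[shift:n] / u_event.values[: n - shift]
    return SignalTrace(u_burst.t0 + lag, u_burst.dt, vals)


def decode_raster(raster: PopulationRaster, stp_event: STPParams,
                  stp_burst: STPParams, syn: SynapseParams = SynapseParams(),
                  dt_bin: float = 1.0, lag: float = 9.0) -> DecodedTraces:
    """Full decode: weights -> population activity -> potentials -> quotient."""
    a_e = population_activity(raster, stp_event, dt_bin)
    a_b = population_activity(raster, stp_burst, dt_bin)
    n = len(raster)
    u_e = synaptic_potential(a_e, syn, n)
    u_b = synaptic_potential(a_b, syn, n)
    bf = decode_burst_fraction(u_b, u_e, lag)
    return DecodedTraces(u_e, u_b, bf, lag,
                         meta={"rule": stp_event.rule, "theta_w": stp_event.theta_w})


# ---------------------------------------------------------------------------
# hyper-parameter search
# ---------------------------------------------------------------------------

def tune_decoder(raster: PopulationRaster, driver_sig: SignalTrace,
                 modulator_sig: SignalTrace, theta_w_grid,
                 lag_grid=(9.0,), rule: str = "stp1",
                 tau_sigma: float | None = None, n_ib: int = 1,
                 spectral=None, syn: SynapseParams = SynapseParams(),
                 dt_bin: float = 1.0):
    """Exhaustive grid search of (theta_w, lag) maximizing total decoded information.

    ``driver_sig`` and ``modulator_sig`` must already be on the decoding
    grid (dt_bin).  Ties break toward the smaller parameter (grids are
    scanned in ascending order and only strict improvements move the
    argmax).  Returns (theta_w, lag, best_total_bits_per_s, table) where
    table maps (theta_w, lag) -> total information.
    """
    from .information import SpectralParams, multiplex_info

    theta_w_grid = list(theta_w_grid)
    lag_grid = list(lag_grid)
    if not theta_w_grid or not lag_grid:
        raise ValueError("search grids must be non-empty")
    if spectral is None:
        spectral = SpectralParams()
    best = (None, None, -np.inf)
    table = {}
    for theta_w in sorted(theta_w_grid):
        if rule == "stp1":
            stp_e = STPParams.stp1_depressing(theta_w)
            stp_b = STPParams.stp1_facilitating(theta_w)
        elif rule == "stp2":
            stp_e = STPParams.stp2_depressing(theta_w, tau_sigma)
            stp_b = STPParams.stp2_facilitating(theta_w, tau_sigma, n_ib)
        else:
            raise ValueError("tune_decoder supports stp1 and stp2 rules")
        a_e = population_activity(raster, stp_e, dt_bin)
        a_b = population_activity(raster, stp_b, dt_bin)
        n = len(raster)
        u_e = synaptic_potential(a_e, syn, n)
        u_b = synaptic_potential(a_b, syn, n)
        for lag in sorted(lag_grid):
            bf = decode_burst_fraction(u_b, u_e, lag)
            decoded = DecodedTraces(u_e, u_b, bf, lag)
            res = multiplex_info(driver_sig, modulator_sig, decoded, spectral)
            table[(theta_w, lag)] = res.rate_total
            if res.rate_total > best[2]:
                best = (theta_w, lag, res.rate_total)
    return best[0], best[1], best[2], table
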
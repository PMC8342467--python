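"""Numba-compiled inner loops for the point-process simulators.

The grid-based thinning loop visits every 0.1 ms step of a simulation, so
the encoder would be unusably slow in pure Python for the population sizes
and durations the experiments need (200 cells, 50-100 s, several seeds).
These kernels keep the loops in machine code; everything user-facing lives
in :mod:`burstplex.encoder`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Spike labels shared with encoder.SpikeLabel (kept as plain ints here so the
# kernels do not depend on the enum type).
_SINGLET = 0
_BURST_FIRST = 1
_INTRA_BURST = 2


@njit(cache=False)
def _truncated_gamma(shape: float, scale: float, lower: float) -> float:
    """Gamma(shape, scale) sample conditioned on being >= lower."""
    for _ in range(10000):
        x = np.random.gamma(shape, scale)
        if x >= lower:
            return x
    # Pathological truncation (lower far in the tail): clamp rather than spin.
    return lower


@njit(cache=False)
def _bsrm_core(gamma_e, gamma_b, dt, v0, theta_b, alpha_b,
               gamma_scale, gamma_shape, delta_ref, tau_rel, eta_amp,
               theta_e, alpha_e, n_ib, lam0_hz, seed,
               times, labels):
    """Thinning simulation of the burst-marked point process.

    Events are generated by per-step Bernoulli thinning with probability
    1 - exp(-rho(t) dt); at each event a Bernoulli draw with the sigmoid
    burst probability decides whether exactly ``n_ib`` intra-burst spikes
    (gamma ISIs conditioned >= delta_ref) follow.  The event clock is
    suspended while the burst plays out and resumes after the last
    intra-burst spike; the refractory kernel is anchored at the last spike
    of any kind.  Returns the number of spikes written into ``times`` /
    ``labels``.
    """
    np.random.seed(seed)
    n = gamma_e.size
    duration = n * dt
    lam0_ms = lam0_hz / 1000.0
    cap = times.size
    tp = -1.0e12  # last spike time, any kind
    k = 0
    i = 0
    while i < n:
        t = i * dt
        if t - tp < delta_ref:
            i += 1
            continue
        v = gamma_e[i] + v0 - eta_amp * np.exp(-(t - tp) / tau_rel)
        rho = lam0_ms * np.exp((v - theta_e) / alpha_e)
        if np.random.random() < 1.0 - np.exp(-rho * dt):
            if k >= cap:
                return -1
            pb = 1.0 / (1.0 + np.exp(-(gamma_b[i] + v0 - theta_b) / alpha_b))
            is_burst = np.random.random() < pb
            times[k] = t
            labels[k] = _BURST_FIRST if is_burst else _SINGLET
            k += 1
            tp = t
            if is_burst:
                for _m in range(n_ib):
                    isi = _truncated_gamma(gamma_shape, gamma_scale, delta_ref)
                    ts = tp + isi
                    if ts >= duration:
                        break  # burst truncated at the edge of the trace
                    if k >= cap:
                        return -1
                    times[k] = ts
                    labels[k] = _INTRA_BURST
                    k += 1
                    tp = ts
                # resume the event clock strictly after the last spike
                i = int(tp / dt) + 1
                continue
        i += 1
    return k


@njit(cache=False)
def _renewal_core(n_max, mean_shift, exp_mean, gamma_shape, gamma_scale,
                  duration, seed, use_gamma, times):
    """Homogeneous renewal train: shifted-exponential or shifted-gamma ISIs."""
    np.random.seed(seed)
    t = 0.0
    k = 0
    while k < n_max:
        if use_gamma:
            isi = mean_shift + np.random.gamma(gamma_shape, gamma_scale)
        else:
            isi = mean_shift + np.random.exponential(exp_mean)
        t += isi
        if t >= duration:
            break
        times[k] = t
        k += 1
    return k


@njit(cache=False)
def _stp2_priming(times, theta_w, tau_sigma):
    """Causal STP2 kernel sum c_i = sum_{j<i} kappa(t_i - t_j).

    kappa(u) = 1 - sigmoid((u - theta_w) / tau_sigma) for u > 0; spikes
    further back than theta_w + 40 tau_sigma contribute < 1e-17 and are
    skipped.
    """
    n = times.size
    c = np.zeros(n)
    horizon = theta_w + 40.0 * tau_sigma
    start = 0
    for i in range(n):
        while times[i] - times[start] > horizon:
            start += 1
        acc = 0.0
        for j in range(start, i):
            u = times[i] - times[j]
            acc += 1.0 - 1.0 / (1.0 + np.exp(-(u - theta_w) / tau_sigma))
        c[i] = acc
    return c
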
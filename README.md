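# burstplex

A workbench for **burst-multiplexed neural coding**: can a neuron ascribe
different meanings to bursts and isolated spikes even when nothing in its
interspike-interval (ISI) statistics betrays a burst code?

Many cortical neurons emit occasional high-frequency bursts, and the burst
coding hypothesis holds that a burst is a distinct syllable of the neural
code.  The usual way to nominate a cell as a burst coder is a bimodal ISI
distribution — a short-ISI (intra-burst) mode separated from a long-ISI
(inter-event) mode.  `burstplex` provides the simulation and analysis
machinery to test the converse: populations that *do* multiplex two signals
through bursts, but whose ISI histograms, autocorrelations and irregularity
statistics (CV2, LV) look just like those of non-burst-coding neurons.
It is aimed at computational neuroscientists studying temporal codes and
spike-train statistics.

## The model

Two independent Ornstein–Uhlenbeck signals drive a population of N = 200
burst-spike-response model (BSRM) cells — marked point processes with
intensity

    lambda_t = rho(t)                  after a non-burst spike
             = Gamma(t - t_last)       inside a burst
             = 0                       within the 2 ms absolute dead time

where the **driver** sets the event rate through an exponential link,
`rho(t) = lambda0 * exp((gamma_e(t) + eta(t - t') - theta_e) / alpha_e)`
with relative refractory kernel `eta(u) = -eta_amp * e^{-u/tau_rel}`, and
the **modulator** sets the probability that an event is a burst through a
sigmoid link, `p(t) = sigmoid((gamma_b(t) - theta_b) / alpha_b)`.  A burst
appends `n_ib` intra-burst spikes with Gamma(1.5, 20/3 ms) intervals.

Downstream, two cells demultiplex the population without seeing the labels:
a **depressing** synapse passes spikes preceded by long ISIs (recovering
the driver), a **facilitating** synapse passes spikes preceded by short
ISIs, and the lagged quotient of the two membrane potentials estimates the
burst probability (recovering the modulator).  Channel performance is the
coherence-based lower bound on the linearly decodable information rate,

    I_lb = -∫ log2(1 - Phi(f)) df   [bits/s],

estimated with Welch's method and integrated over frequency; a label-reading
*perfect decoder* provides the oracle baseline.  See `docs/methods.md` for
every parameter, default and caveat.

## Worked example

```python
import numpy as np
from burstplex import (DRIVER, MODULATOR, EncoderParams, STPParams,
                       SpectralParams, calibrate_event_threshold,
                       decode_raster, multiplex_info, sample_ou,
                       simulate_population)

# pin the operating point: 10 Hz event rate at tau_rel = 6 ms
theta_e = calibrate_event_threshold(EncoderParams(tau_rel=6.0),
                                    target_event_rate=10.0, seed=0)

ss = np.random.SeedSequence(0)
d, m, pop = ss.spawn(3)
driver = sample_ou(DRIVER, dt=0.1, duration=50_000.0, seed=d)       # 50 s
modulator = sample_ou(MODULATOR, dt=0.1, duration=50_000.0, seed=m)
raster = simulate_population(EncoderParams(tau_rel=6.0, theta_e=theta_e,
                                           n_pop=200), driver, modulator, pop)
print(f"event rate: {raster.event_rate_hz():.2f} Hz, "
      f"burst fraction: {raster.burst_fraction():.3f}")

decoded = decode_raster(raster, STPParams.stp1_depressing(14.0),
                        STPParams.stp1_facilitating(14.0), lag=9.0)
info = multiplex_info(driver.decimate(10), modulator.decimate(10), decoded,
                      SpectralParams(window_length=4.096))
print(f"driver channel:    {info.rate_driver:.1f} bits/s")
print(f"modulator channel: {info.rate_modulator:.1f} bits/s")
print(f"total:             {info.rate_total:.1f} bits/s")
```

Output:

```
calibrated event threshold: -0.117 mV
event rate: 9.93 Hz, burst fraction: 0.242
driver channel:    156.0 bits/s
modulator channel: 75.6 bits/s
total:             231.6 bits/s
```

The calibrated population fires ~10 Hz events of which ~0.2 are doublet
bursts; with a 14 ms ISI threshold and the 9 ms readout lag, the event
channel linearly transmits ~156 bits/s about the driver and the
burst-fraction quotient ~76 bits/s about the modulator (both figures
include the positive small-sample bias of averaged coherence discussed in
the methods note; ratios between conditions are the robust quantities).

A CLI mirrors the library: `burstplex simulate|decode|info|metrics`,
`burstplex sweep {tau-rel|smoothness|burst-length|event-rate}` and
`burstplex compare-models`, each with `--config`, `--seed`, `--out` and
`--profile {full,fast}`.

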
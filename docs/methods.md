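# Methods

This note documents the models implemented in `burstplex`, the reasoning
behind every default that is not forced by the mathematics, and what the
simulations can and cannot say about real neurons.

## The encoding model

A population of `N = 200` cells receives two shared input signals and emits
marked spike trains.  Both inputs are stationary Ornstein–Uhlenbeck (O–U)
processes,

    dx = -(x / tau) dt + sqrt(2 sigma^2 / tau) dW,

sampled with the exact discretisation of the O–U transition density (initial
sample from the stationary law, so there is no burn-in and no step-size
drift).  The *driver* (tau = 10 ms, variance 1 mV²) sets the event rate; the
*modulator* (tau = 20 ms, SD 6 mV) sets the burst probability.

Each cell is a burst-spike-response model (BSRM): a self-inhibiting marked
point process that alternates between a modulated renewal process for
*events* and a gamma renewal process for *intra-burst spikes*.

- Event potential: `v_e(t) = gamma_e(t) + v0 + eta(t - t')`, with
  `eta(u) = -eta_amp * exp(-u / tau_rel)` anchored at the last spike of any
  kind, and an absolute dead time `delta_ref = 2 ms` after every spike.
- Event intensity: exponential link `rho(t) = lambda0 * exp((v_e - theta_e)
  / alpha_e)` with `alpha_e = 2 mV`.
- Burst probability: sigmoid link `p(t) = sigmoid((gamma_b(t) + v0 -
  theta_b) / alpha_b)` with `theta_b = 4.5 mV`, `alpha_b = 1/3 mV`; the
  refractory kernel does not feed this pathway.
- At each event, a Bernoulli(p) draw decides whether the event is a burst;
  if so, exactly `n_ib` intra-burst spikes follow, their ISIs drawn i.i.d.
  from Gamma(shape 1.5, scale 20/3 ms) conditioned on ISI >= `delta_ref`
  (rejection sampling).  Intra-burst spikes never trigger bursts, and the
  event clock is suspended until the burst ends.  A burst running past the
  end of the simulation window is truncated.  `n_ib = 1` (doublets) is the
  default; the burst-length campaign varies it.

Events are sampled by Bernoulli thinning on the 0.1 ms input grid with
per-step probability `1 - exp(-rho dt)`, which is exact in the dt -> 0 limit;
a test verifies that halving dt leaves the long-run event rate unchanged
within Monte-Carlo error.

### Parameter choices that required judgement

- **Intensity gauge.**  Only the combination of `lambda0` and `theta_e`
  matters (`rho = lambda0 * exp((v - theta_e)/alpha_e)`).  We fix
  `lambda0 = 10 Hz` and always set `theta_e` by calibration
  (`calibrate_event_threshold`) so the long-run event rate hits its target —
  10 Hz at `tau_rel = 6 ms` for the canonical operating point, matching the
  1–tens of Hz range of cortical firing.  Calibration is a bisection on a
  common-random-numbers simulation (inputs and thinning stream frozen across
  evaluations, so the rate is a monotone, nearly deterministic function of
  the threshold), validated on an independent substream.
- **Modulator amplitude.**  With the burst threshold 4.5 mV and scale
  1/3 mV, the stationary burst fraction is `E[sigmoid((X - 4.5)/(1/3))]` for
  X the stationary modulator value.  A modulator SD of 6 mV puts this near
  0.22, inside the 0.1–0.2 range measured in layer 2/3 and layer 5
  pyramidal cells, which is the operating point the whole study is built
  around; a 6 mV² *variance* would put it near 0.04 and effectively silence
  the burst channel.  The canonical preset therefore uses variance 36 mV².
- **Refractory amplitude.**  `eta_amp = 10 mV` — a typical spike-response
  reset scale.  The value is bracketed by the modality phenomenology the
  model must produce: with amplitudes of 5–12 mV the population ISI
  distribution is unimodal for `tau_rel <= 7 ms` and bimodal by
  `tau_rel ~ 12 ms`; a unit amplitude (weak against `alpha_e = 2 mV`) never
  produces bimodality at any `tau_rel`, and >= 15 mV is bimodal already at
  7 ms.
- **Intra-burst gamma.**  Scale 20/3 ms and shape 1.5 give a mean IBI of
  10 ms (typical intra-burst rates in the 100–200 Hz band) with the sharp,
  super-exponential ISI peak seen in bursting cells.
- **Seed protocol.**  One `numpy.random.SeedSequence` per experiment trial,
  deterministically split into substreams for the driver, the modulator and
  every neuron; identical config + master seed reproduces results exactly.

Reference generators for the irregularity comparisons: a homogeneous Poisson
process, a (optionally refractory, via a shifted origin) gamma renewal
process with the scale set so the mean ISI matches the requested rate, and a
burst-free SRM (the BSRM with the burst pathway silenced).

## Decoding

Two post-synaptic cells read the population through short-term-plasticity
weights `w in [0, 1]` per spike:

- **STP1 (sharp, renewal):** weight 1 iff the immediately preceding ISI is
  above (depressing / event channel) or below (facilitating / burst channel)
  the ISI threshold `theta_w`.  A spike with no predecessor counts as an
  infinite ISI (depressing 1, facilitating 0).  ISIs exactly at `theta_w`
  (possible because event times are grid-locked) go to the depressing side
  so the two rules partition every spike.
- **STP2 (smooth cascade):** `w = sigmoid(a c + b)` with
  `c = sum_{j<i} kappa(t_i - t_j)` (strictly causal, the weighted spike
  excluded) and `kappa(u) = 1 - sigmoid((u - theta_w)/tau_sigma)`.
  Facilitating gains are `(+40/n_ib, -20)` — the 1/n_ib scaling makes the
  synapse fire only after priming by the burst's n_ib short intervals —
  and depressing gains the mirror `(-40, +20)`.  As `tau_sigma -> 0` the
  rule converges to STP1 away from the threshold (tested).
- **Perfect (oracle):** reads the generative labels; the event channel
  marks singlets and burst-first spikes, the burst channel marks the last
  intra-burst spike of each burst.  Marking the last intra-burst spike
  (rather than the burst onset) keeps the oracle aligned in time with what
  a facilitating synapse can physically report.

Weighted spikes are binned at 1 ms, averaged over neurons (the trace holds
binned delta mass, so it sums to total weight / N), convolved with the
rise/decay synaptic kernel `kappa_syn(t) = g_bar (1 - e^{-t/3}) e^{-t/5}`
(peak at `3 ln(8/3) ~ 2.94 ms`) and offset by the 1 mV resting potential.
The burst-fraction estimate is the lagged quotient
`u_burst(t) / u_event(t - lag)`; the positive resting potential keeps the
division defined.  The lag compensates the intra-burst intervals plus
synaptic rise that delay the facilitating readout; 9 ms for doublets, and
line-searched (0 to 10 n_ib + 10 ms, 1 ms steps) for longer bursts.
`theta_w` is line-searched on 5–35 ms (5–45 ms for the event-rate campaign)
in 1 ms steps to maximise total decoded information, once per cell model
(first trial), with ties broken toward the smaller value.

## Information estimation

Per channel (driver input vs event potential; modulator input vs
burst-fraction estimate) the magnitude-squared coherence is estimated with
Welch's method — Hanning window, 8.192 s windows (4.096 s for the shorter
campaigns), half overlap, per-segment mean removal — and converted to the
Gaussian-channel lower bound on the linearly decodable information rate,

    I_lb = -∫_0^{f_Nyq} log2(1 - Phi(f)) df   [bits/s].

Coherence is clipped at 1 - 1e-6 (the integrand diverges at 1, which only
arises from degenerate estimation), and the full band up to the 500 Hz
Nyquist frequency of the 1 ms decoding grid is integrated.  The total
multiplexed rate is the sum of the two channel rates; for independent
inputs this never exceeds the joint information (verified as a test
property on a synthetic bivariate Gaussian channel against the closed-form
joint rate).

A property of this estimator that matters when reading absolute numbers:
averaged-periodogram coherence has a positive small-sample bias of roughly
1/K (K = number of segments), so each channel carries a noise floor of
about `-log2(1 - 1/K) * f_Nyq` bits/s — with 100 s simulations and 8.192 s
half-overlapping windows (K ~ 23), about 32 bits/s per channel.  The floor
is part of what the estimator reports at these settings (it is *not*
subtracted); it shrinks with longer simulations, and normalized quantities
(channel ratios) largely cancel it.  Estimator consistency on an analytic
flat-coherence channel (500 bits/s at 1 kHz) is tested.

Sweeps report 5-seed trial means with per-seed values stored; normalized
sweeps divide each channel by the maximum of the corresponding
perfect-decoder channel over the sweep (per-channel normalization, matching
the plural reading of the baseline definition).

## Irregularity metrics

CV2 and LV follow their defining sums over adjacent ISI pairs; both are
dimensionless, zero iff all ISIs are equal, and invariant under uniform
time rescaling (property-tested).  For gamma-renewal ISIs with shape kappa,
E[LV] = 3/(2 kappa + 1), used as an analytic oracle.  ISI histograms use
1 ms bins up to 200 ms, optional Gaussian smoothing (SD 1 ms), and a fixed
modality detector — local maxima with prominence >= 5% of the global
maximum, edge bins eligible — replacing by-eye judgements of "visually
unimodal".  The spike autocorrelation is the average product of 1 ms bin
counts at each lag (units spikes²), zero-lag reported separately.

The model-comparison table sweeps target spike rates over 2–20 Hz (the
cortical range; the exact grid is a package choice) and matches the BSRM's
total spike rate to each target by calibrating its event rate to
target / (1 + burst_fraction).

## Problem sizes

Full campaign settings are 100 s simulations, 8.192 s windows and 5 seeds
(50 s / 4.096 s for the smoothness and burst-length campaigns).  The test
suite runs the printed-value checks at exactly these settings and the
trend suite on 5-seed means at 50 s; the irregularity comparison uses
600 s trains and the structural suite a 200-cell, 500 s raster
(~1.2 million labelled spikes).  A `fast` profile (25 s, 2 seeds) exists
for interactive work and is not used for any assertion.

## What the generator does and does not emulate

The synthetic populations reproduce: cortical event rates (1–20 Hz), burst
fractions near 0.2, intra-burst rates of 100–200 Hz, absolute and relative
refractoriness, and the unimodal-to-bimodal ISI transition as the relative
refractory period grows.  They do not include network recurrence,
conductance-based dynamics, dendritic calcium mechanisms, non-stationary
inputs, heterogeneous cell parameters, or correlated spiking noise across
cells (all cells share the inputs but thin independently).  Passing tests
therefore demonstrate properties of this generative model and of the
decoding/estimation pipeline — not that any particular recorded neuron
multiplexes bursts.

## Known limitations

- Absolute information rates depend on the spectral-estimation settings
  through the bias floor discussed above; comparisons across conditions
  (trends, normalized ratios) are the robust quantities.
- The sharp STP1 rule is an idealisation; real synapses are closer to the
  STP2 cascade, which the smoothness campaign covers.
- The burst-fraction quotient is taken directly rather than through an
  explicit divisive-inhibition circuit.
- Calibration targets long-run rates; slow O–U excursions make short-window
  rates fluctuate around the target.
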
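# Methods

This note documents the models, estimators, defaults, and numerical
choices behind `ornspike`, and what the synthetic-data-driven tests do
and do not demonstrate about real recordings.

## Time and label conventions

All times are in milliseconds. t = 0 is odorant arrival at the antenna,
operationalized as the stimulus waveform's 5% crossing; spike times may
be negative (pre-stimulus). Concentration is the log10 of the odorant
dilution. The two receptor types are OR59b (ab2 sensilla; ~23 neurons
converge on glomerulus DM4) and OR22a (ab3; ~8 neurons on DM2); the two
odorants are methyl butyrate and ethyl acetate.

## Synthetic stimulus

`synthdata.make_stimulus` builds a deterministic pulse: zero baseline,
linear rise starting at t = 0, then a plateau whose normalized amplitude
is a logistic function of concentration (half-maximum at dilution 10⁻⁴),
so plateau level grows monotonically with concentration while staying in
(0, 1). The default kernel stretches the ramp so the *measured* 5–95%
span equals the requested rise time (default 3.6 ms, the fast-stimulator
value); a plain `ramp` kernel is available where the argument is the full
0–100% ramp length (5–95% span = 0.9× that). Sampling must satisfy
dt ≤ rise/10 so the rise is resolved.

`metrics.rise_time_5_95` measures the span between the first upward
crossings of 5% and 95% of the plateau (waveform maximum), linearly
interpolated between samples; a sampled step function therefore measures
at most one sample step, not exactly zero.

## Synthetic spike trains

Each trial of one ORN is composed of three segments:

1. **Spontaneous firing** on [−baseline, 0): homogeneous Poisson at
   `spont_rate` (default 5 spikes/s) thinned by a 1 ms refractory floor.
   The effective rate is r/(1 + r·t_ref), about 0.5% below nominal at
   5 Hz. Spontaneous firing is not continued into the response window;
   the evoked renewal process decays toward `spont_rate` instead, which
   keeps the first evoked spike identifiable and is the main idealization
   relative to real trains (a real neuron can emit a spontaneous spike
   between stimulus onset and the first evoked spike).
2. **First evoked spike** at `latency_median + N(0, latency_sd)`,
   clipped below at a 2 ms transduction floor (the fastest observed
   evoked latency is 3 ms, so the floor is essentially never active at
   the calibrated settings).
3. **Subsequent evoked spikes** from a gamma-renewal process (shape 5,
   fairly regular) whose mean interval tracks an instantaneous rate
   decaying exponentially from `peak_rate = 1000 / min_isi` toward
   `spont_rate` with time constant `adapt_tau` (default 15 ms); every
   interval is floored at `min_isi`.

This three-part construction was chosen because it controls the three
summary statistics of interest — latency, jitter, minimum ISI —
independently, so estimator-recovery tests have exact ground truth.

### Concentration calibration

Latency, jitter, and minimum ISI interpolate log-linearly in the value
between anchors at the ends of the calibrated range (log10 dilution −7
to −2):

| quantity          | at 10⁻⁷ | at 10⁻² |
|-------------------|---------|---------|
| latency median    | 55 ms   | 3.5 ms  |
| trial jitter (SD) | 30 ms   | 0.25 ms |
| minimum ISI       | 20 ms   | 2 ms    |

The midpoint value is the geometric mean of the anchors. The anchors sit
inside the observed ranges for these neurons (latencies 18–55 ms at low
and 3–4.4 ms at high concentrations; jitter 4.36–106 ms low,
0.19–0.49 ms high); real data are reported as ranges, not curves, so the
smooth interpolant is a modeling choice, overridable per call.

### Odorant rank structure

Odorant identity enters as additive latency offsets — OR59b leads by
3 ms for ethyl acetate, OR22a leads by 1 ms for methyl butyrate — and as
matching multiplicative factors on the minimum ISI (0.75/1.25 for ethyl
acetate, 0.85/1.15 reversed for methyl butyrate), so the faster type also
fires at a higher rate. The latency offsets are the documented rank
structure; the ISI factors are this package's own (smaller) analogue so
that the interspike-interval classification feature is informative at
all; both are config-overridable.

### Populations and seeding

`generate_population` draws per-neuron median latencies around the
calibrated value with SD `inter_neuron_sd` (default: equal to the
trial-to-trial jitter), which reproduces the observation that
neuron-to-neuron jitter is similar in magnitude to trial-to-trial jitter.
Only the latency varies across neurons; rate parameters are shared.
Every stochastic operation requires an explicit seed; populations fan a
root `SeedSequence` out to one child per neuron, so the same root seed
reproduces the identical RecordingSet regardless of platform.

## Timing estimators

* First-spike latency: first spike with t ≥ 0 inside the response window
  (default (0, 200) ms, configurable); the window is closed on the left.
  Trials without such a spike are "undefined", a value rather than an
  error.
* Trial-to-trial jitter: sample SD (n − 1; trial counts of ~10 make the
  denominator matter) of defined latencies; undefined trials are
  excluded and reported via a warning.
* Neuron-to-neuron jitter: sample SD across neurons of per-neuron
  *median* latencies. No formula is prescribed for this quantity in the
  source material; the median-based definition is robust to single
  aberrant trials.
* Minimum ISI: per-trial first-to-second evoked interval by default
  (`global_min` optional), summarized as the median across trials. The
  reciprocal is the maximum evoked rate.
* Sliding PSTH: fraction of trials with ≥ 1 spike in a 1 ms window slid
  in (default) 0.5 ms steps — a probability, not a rate, bounded by 1.

## Detection analysis

d_a = (μ_e − μ_s)/√((σ²_e + σ²_s)/2) with sample variances. Degenerate
inputs: both samples constant and equal → 0; both constant but different
→ +∞ sentinel, excluded from pool averages with a logged count.

Sampling scheme (the exact scheme used on the original recordings is not
published, so this is declared, not inferred): a pool draws `pool_size`
neurons *with replacement* (recorded sets are smaller than the anatomical
pools of 23/8); each of R trial replicates assigns every pooled neuron
one random trial (R defaults to the available trial count). Evoked
counts: window of length T slid across the response window in 1 ms steps;
the reported statistic is the *peak* d_a over window positions.
Spontaneous counts: non-overlapping tiles of length T across the
pre-stimulus baseline of the same picks, pooled over replicates. The
minimum integration time scans T over 1–40 ms (1 ms grid) and reports,
per repetition (default 50, each with 40 fresh pools), the smallest T
whose mean peak d_a strictly exceeds the threshold (default 5); NaN when
never exceeded, for median/IQR reporting.

`false_positive_rate(d) = Φ(−d/2)` is the miss/false-alarm rate of an
equal-variance Gaussian observer with the criterion midway between the
two means: d = 5 gives 0.62% < 1%.

Numerical caveat, visible in the test suite: with near-zero spontaneous
rates and millisecond windows, both count distributions become almost
deterministic, the RMS-SD denominator collapses, and single-neuron peak
d_a can exceed pooled values. The pool-size monotonicity property is
therefore exercised at a 20 Hz spontaneous rate and 4 ms windows, where
count variance is non-degenerate; the generator's 5 Hz default is
unchanged.

## Latency-difference classifier

Per draw (23 OR59b and 8 OR22a picks, neurons with replacement, one
random trial each), the per-type population latency is the *earliest*
defined first-spike latency in the pool — the first spike a downstream
circuit could see, consistent with the network model; a per-type median
variant is available. The decision feature is Δ = OR22a − OR59b (ms),
for latencies and for per-type median first-to-second ISIs. Δ > θ →
ethyl acetate (OR59b leads), otherwise methyl butyrate; ties at θ go to
the non-leading class; draws where one type never fires abstain and are
scored as errors.

`fit_threshold` maximizes pooled accuracy across all conditions at once
by exhaustive scan — accuracy is piecewise constant in θ with breakpoints
at the observed Δ values, so evaluating one representative per interval
is exact; the midpoint of the widest optimal interval is returned.

Limitation: with the earliest-of-pool statistic the unequal pool sizes
(23 vs 8) bias Δ positive by ~0.63·σ_jitter (extreme-value shift), which
at the lowest calibrated concentrations (jitter ≥ 4 ms) overwhelms the
1 ms methyl-butyrate offset. Concentration-invariant behavior of a
single threshold should therefore be expected over roughly 10⁻⁴–10⁻²
in this synthetic world; the median variant avoids the bias entirely.

## LIF network

Five current-based LIF neurons: PN_X (driven by 8 OR22a trains), PN_Y
(23 OR59b), inhibitory neuron I (driven by both PNs), and KC_X/KC_Y
(each driven strongly by "its" PN, weakly by the other, and inhibited by
I). Membrane equation dV/dt = −(V − v_rest)/τ_m + I_syn; each
presynaptic spike adds, after the synaptic delay, a current of amplitude
equal to the weight (mV/ms) decaying with τ_syn. Constants: v_rest =
v_reset = −60 mV, threshold −45 mV, τ_m = 5 ms (3 ms for I), τ_syn =
2 ms, refractory 2 ms, delays 1 ms per hop except the I→KC synapse
(0.5 ms, see below). No intrinsic noise: all stochasticity enters
through the ORN inputs, so the simulation is deterministic given its
inputs.

Integration: fixed step dt = 0.025 ms, advancing each (synaptic current,
membrane) pair with the exact closed-form solution of the linear cascade
between event arrivals (the degenerate τ_m = τ_syn case uses the t·e^(−t/τ)
limit). Only threshold-crossing times are quantized to the grid; halving
dt moves KC first-spike latencies by less than 0.05 ms (tested). The
subthreshold response to a single event has the closed form
w·(e^(−t/τ_m) − e^(−t/τ_syn))/(1/τ_syn − 1/τ_m), used as an analytic
oracle for the integrator and by the weight calibration. Threshold
crossings are detected at step ends; membrane potential is clamped at
v_reset during the refractory period; there is no lower bound on V
(current-based inhibition may hyperpolarize below reset, which only
deepens the losing KC's silence).

### Weight calibration

The circuit must satisfy a timing inequality: with rank gap Δ between
the two PNs, feedforward inhibition must reach the KCs *after* the
strongly driven KC crosses threshold but *before* the weakly primed KC
does, i.e. t_cross(strong) < t_inhibition < t_cross(strong) + Δ −
(priming advance from the weak synapse). Defaults: ORN→PN weight
14.4/pool-size per synapse (a synchronous volley of roughly half the
pool reaches PN threshold within ~2 ms, so PN timing tracks a mid-order
statistic of the volley rather than the noisy minimum); PN→KC strong 24,
weak 6 (strong alone suprathreshold, crossing ~0.9 ms after arrival);
PN→I 40 (I crosses ~0.5 ms after a PN spike); I→KC −80 (a single
inhibitory event outweighs the concurrent excitatory drive within
~0.1 ms of arrival).

Two constants differ from the obvious symmetric choice, and
deliberately: a 4:1 strong:weak ratio (not ~2.5:1) and a 0.5 ms I→KC
delay (not 1 ms). With the smaller ratio and uniform 1 ms delays, the
1 ms methyl-butyrate rank gap leaves the weakly primed KC_Y crossing
threshold ~0.2 ms before inhibition arrives, breaking exclusivity in a
substantial fraction of runs; weakening the cross synapse and speeding
the inhibitory synapse restores ~0.5 ms of slack on both sides of the
timing window. The calibration targets behavior (classification
exclusivity), not particular constants, and all weights are
config-overridable.

### Classification protocol

A run is scored by KC exclusivity within the decision window
(0–50 ms): KC_X only → methyl butyrate, KC_Y only → ethyl acetate, both
or neither → invalid; only each KC's first spike in the window counts.
`classification_rate` runs 100 fresh synthetic input sets per odorant
(8 + 23 single-trial trains at dilution 10⁻³ by default) and reports
percent correct plus the responding KC's first-spike latencies. The
time-shift sweep translates all OR22a trains by −4…+4 ms in 0.2 ms steps
(OR59b unchanged), reusing the same input sets across shifts so the
curve isolates relative timing; rates fall once the shift reverses the
rank order (≈+1–2 ms for methyl butyrate).

## Problem sizes in the shipped checks

The test suite and the reproduction script use: 10,000 single-neuron
trials for estimator recovery (tolerance 2%); 100 network runs per
odorant; detection sweeps with 8–30 pools and 3–10 repetitions on
populations of ~10 neurons × 6–8 trials. These sizes give comfortably
converged statistics for the quantities asserted; the full-scale
defaults (40 pools × 50 repetitions) remain the library defaults.

## What passing tests do and do not show

The generator reproduces summary statistics (latency, jitter, ISI, rank
offsets) — not biophysics. Real recordings add: spontaneous spikes
inside the response window, bursty non-renewal firing, adaptation
history across trials, correlated noise across simultaneously recorded
neurons, and odorant-specific response dynamics beyond a single offset.
Estimator-recovery results therefore validate the *estimators* and the
*pipeline plumbing*, and the network results demonstrate the
*mechanism's plausibility* under the stated timing statistics; neither
certifies performance on any particular real dataset. Exact per-neuron
values from the original recordings are out of scope (no public
machine-readable archive is parsed; a generic tabular importer is
provided instead).
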
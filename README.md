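# ornspike

Spike-timing analyses for *Drosophila* olfactory receptor neurons (ORNs):
how fast and how precisely the first odorant-evoked spikes occur, what a
downstream decoder could read out of them, and whether a simple
mushroom-body circuit can classify odorants from the *order* in which two
receptor-neuron types respond.

The package is aimed at sensory/olfactory neuroscientists who want a
tested, scriptable implementation of four linked analyses:

1. **Timing statistics** — first-spike latency `L` (relative to odorant
   arrival at the antenna, defined as the stimulus 5% crossing),
   trial-to-trial and neuron-to-neuron jitter (sample SD of `L`), the
   minimum interspike interval (reciprocal of the maximum evoked rate),
   spike probability in a sliding 1 ms window, and the 5–95% stimulus
   rise time.
2. **Pooled onset detection** — detection accuracy

   `d_a = (μ_evoked − μ_spont) / sqrt((σ²_evoked + σ²_spont) / 2)`

   between spike counts pooled over glomerular-scale groups (23 OR59b or
   8 OR22a neurons), swept over integration time and pool size, plus the
   minimum integration time needed to exceed `d_a = 5` — the ideal
   Gaussian observer's criterion-at-midpoint error is `Φ(−d_a/2)`, i.e.
   under 1% at `d_a = 5`.
3. **Latency-difference classification** — the difference
   `Δ = L(OR22a) − L(OR59b)` (or the analogous interspike-interval
   difference) thresholded once across all concentrations:
   concentration-invariant odorant identification by rank order.
4. **LIF network model** — a five-neuron leaky integrate-and-fire circuit
   (PN_X, PN_Y, inhibitory neuron I, KC_X, KC_Y) with feedforward
   inhibition, sensitive to which ORN population fires first; includes
   the time-shift sweep that probes rank-order sensitivity directly.

A synthetic spike-train generator (`ornspike.synthdata`) drives all of
this: it emulates concentration-dependent latency (≈3–55 ms), jitter
(≈0.19–30 ms), minimum ISI, spontaneous firing, and the odorant-specific
rank offsets between the two receptor types, so every stage is testable
without any recordings.

## Worked example

```python
import numpy as np
from ornspike import synthdata, metrics, detection, liflib

# 14 OR59b neurons x 10 trials at dilution 1e-4
rec = synthdata.generate_population(
    "OR59b", "methyl butyrate", -4.0, n_neurons=14, n_trials=10,
    rng_seed=1, baseline=200.0, duration=120.0)

stats = metrics.condition_stats(rec)[0]
print(f"latency median  {stats.latency_median:.2f} ms")
print(f"trial jitter    {stats.latency_trial_jitter:.2f} ms")
print(f"neuron jitter   {stats.latency_neuron_jitter:.2f} ms")
print(f"min ISI         {stats.min_isi:.2f} ms")

mits = detection.min_integration_time(rec, pool_size=23, threshold=5.0,
                                      n_pools=10, n_repetitions=10,
                                      rng_seed=2)
print(f"min integration time (median) {np.nanmedian(mits):.0f} ms")

res = liflib.classification_rate(liflib.default_network(),
                                 liflib.synthetic_orn_factory(-3.0),
                                 n_runs=100, rng_seed=3)
for odorant, d in res.items():
    print(f"{odorant:16s} {d['rate_pct']:.0f}% correct, "
          f"KC latency median {np.median(d['kc_latencies_ms']):.1f} ms")
```

Output:

```
latency median  9.47 ms
trial jitter    1.52 ms
neuron jitter   1.90 ms
min ISI         5.86 ms
min integration time (median) 2 ms
methyl butyrate  99% correct, KC latency median 10.1 ms
ethyl acetate    100% correct, KC latency median 8.0 ms
```

At dilution 10⁻⁴ the generator produces ~10 ms latencies with ~1.5 ms
jitter (neuron-to-neuron jitter of similar size); a pool of 23 such
neurons exceeds `d_a = 5` within a couple of milliseconds of integration;
and at 10⁻³ the rank-order network identifies the odorant from the first
wave of spikes within ~8–11 ms of odorant arrival.

A command-line interface mirrors the library
(`ornspike synth|metrics|detect|classify|simulate-network|shift-sweep`);
each subcommand writes tidy CSV plus a JSON manifest recording the seed,
options, and package versions.

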
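"""Synthetic stimulus waveforms and ORN spike trains.

The generator emulates the statistical structure of odorant responses in
*Drosophila* OR59b and OR22a olfactory receptor neurons: spontaneous
background firing, a fast concentration-dependent first evoked spike with
Gaussian trial-to-trial jitter, a burst of subsequent spikes whose rate
adapts exponentially, and a sharp stimulus pulse with a few-millisecond
5-95% rise time.  Every stochastic operation requires an explicit seed.

Concentration scaling
---------------------
First-spike latency, jitter, and minimum interspike interval are
interpolated log-linearly in the value between anchors at the ends of the
calibrated concentration range (log10 dilution -7 ... -2)::

    value(c) = low * (high / low) ** ((c - c_low) / (c_high - c_low))

so the value at the midpoint concentration is the geometric mean of the
two anchors.  Anchors sit inside the observed ranges for these neurons
(latency 55 -> 3.5 ms, jitter 30 -> 0.25 ms, min ISI 20 -> 2 ms) and can
be overridden per call.

Odorant identity enters as a rank-order structure: OR59b neurons respond
~3 ms earlier than OR22a to ethyl acetate, while OR22a neurons respond
~1 ms earlier to methyl butyrate; evoked spike rates carry a matching
(smaller) odorant-specific modulation of the minimum interspike interval.
"""

from __future__ import annotations

import numpy as np

from .types import (
    ODORANTS,
    RECEPTORS,
    REFRACTORY_FLOOR_MS,
    RecordingSet,
    ResponseParams,
    SpikeTrain,
    StimulusPulse,
)

# --------------------------------------------------------------------------
# Calibrated defaults
# --------------------------------------------------------------------------

#: Calibrated concentration range (log10 dilution).
CONC_LOW, CONC_HIGH = -7.0, -2.0

#: Interpolation anchors (value at CONC_LOW, value at CONC_HIGH), in ms.
LATENCY_ANCHORS_MS = (55.0, 3.5)
JITTER_ANCHORS_MS = (30.0, 0.25)
MIN_ISI_ANCHORS_MS = (20.0, 2.0)

#: Fastest evoked first-spike latency supported by transduction (ms); the
#: shortest latency observed in these neurons is 3 ms, so draws are clipped
#: at a 2 ms floor.
LATENCY_FLOOR_MS = 2.0
MIN_LATENCY_MS = 3.0
#: Smallest trial-to-trial jitter at high concentration (ms).
MIN_HIGH_CONC_JITTER_MS = 0.19

#: Odorant-specific additive latency offsets (ms) applied after the
#: concentration interpolation.  Negative = that receptor leads.
LATENCY_OFFSETS_MS: dict[tuple[str, str], float] = {
    ("ethyl acetate", "OR59b"): -3.0,
    ("ethyl acetate", "OR22a"): 0.0,
    ("methyl butyrate", "OR22a"): -1.0,
    ("methyl butyrate", "OR59b"): 0.0,
}

#: Odorant-specific multiplicative factors on the minimum interspike
#: interval (rate rank order: OR59b fires faster to ethyl acetate, OR22a
#: slightly faster to methyl butyrate).
ISI_FACTORS: dict[tuple[str, str], float] = {
    ("ethyl acetate", "OR59b"): 0.75,
    ("ethyl acetate", "OR22a"): 1.25,
    ("methyl butyrate", "OR22a"): 0.85,
    ("methyl butyrate", "OR59b"): 1.15,
}

#: Spontaneous firing rate (spikes/s).
SPONT_RATE_HZ = 5.0
#: Time constant of evoked-rate adaptation (ms).
ADAPT_TAU_MS = 15.0
#: Shape parameter of the gamma-renewal evoked interval distribution
#: (larger = more regular firing).
RENEWAL_SHAPE = 5.0

#: Default stimulator rise time, 5% to 95% (ms).
DEFAULT_RISE_TIME_MS = 3.6


def _rng(rng_seed) -> np.random.Generator:
    if rng_seed is None:
        raise ValueError(
            "an explicit rng_seed (int, SeedSequence or Generator) is required"
        )
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


# --------------------------------------------------------------------------
# Stimulus
# --------------------------------------------------------------------------

def _plateau_amplitude(concentration: float) -> float:
    """Normalized plateau level, monotone in log10 concentration (0..1)."""
    return 1.0 / (1.0 + 10.0 ** (-(concentration + 4.0)))


def make_stimulus(
    odorant: str,
    concentration: float,
    rise_time_5_95: float = DEFAULT_RISE_TIME_MS,
    duration: float = 500.0,
    dt: float = 0.05,
    pre_ms: float = 20.0,
    kernel: str = "scaled_ramp",
) -> StimulusPulse:
    """Deterministic odorant pulse waveform.

    ``kernel="scaled_ramp"`` (default) produces a linear ramp stretched so
    that the measured 5-95% span equals ``rise_time_5_95`` exactly;
    ``kernel="ramp"`` interprets the argument as the full 0-100% ramp
    length, whose 5-95% span is 0.9x that length.  Onset (t = 0) is the
    start of the rise, so the signal is zero for all t < 0.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if rise_time_5_95 <= 0:
        raise ValueError("rise_time_5_95 must be positive")
    if dt > rise_time_5_95 / 10.0:
        raise ValueError("dt must be <= rise_time_5_95 / 10 to resolve the rise")
    if kernel == "scaled_ramp":
        ramp_len = rise_time_5_95 / 0.9
    elif kernel == "ramp":
        ramp_len = rise_time_5_95
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    amp = _plateau_amplitude(concentration)
    t = np.arange(-pre_ms, duration, dt)
    y = np.clip(t / ramp_len, 0.0, 1.0) * amp
    return StimulusPulse(
        odorant=odorant,
        concentration=concentration,
        t=t,
        y=y,
        onset_time=0.0,
        rise_time_5_95=0.9 * ramp_len,
        duration=duration,
    )


# --------------------------------------------------------------------------
# Response parameters
# --------------------------------------------------------------------------

def _loglinear(c: float, anchors: tuple[float, float]) -> float:
    low, high = anchors
    frac = (c - CONC_LOW) / (CONC_HIGH - CONC_LOW)
    return float(low * (high / low) ** frac)


def response_params(
    receptor: str,
    odorant: str,
    concentration: float,
    spont_rate: float = SPONT_RATE_HZ,
    adapt_tau: float = ADAPT_TAU_MS,
    latency_anchors: tuple[float, float] = LATENCY_ANCHORS_MS,
    jitter_anchors: tuple[float, float] = JITTER_ANCHORS_MS,
    isi_anchors: tuple[float, float] = MIN_ISI_ANCHORS_MS,
    latency_offsets: dict[tuple[str, str], float] | None = None,
    isi_factors: dict[tuple[str, str], float] | None = None,
) -> ResponseParams:
    """Calibrated response parameters for one receptor/odorant/concentration."""
    if receptor not in RECEPTORS:
        raise KeyError(f"unknown receptor {receptor!r}; expected one of {RECEPTORS}")
    if odorant not in ODORANTS:
        raise KeyError(f"unknown odorant {odorant!r}; expected one of {ODORANTS}")
    if not (CONC_LOW <= concentration <= CONC_HIGH):
        raise ValueError(
            f"concentration {concentration} outside calibrated range "
            f"[{CONC_LOW}, {CONC_HIGH}]"
        )
    offsets = LATENCY_OFFSETS_MS if latency_offsets is None else latency_offsets
    factors = ISI_FACTORS if isi_factors is None else isi_factors

    latency = _loglinear(concentration, latency_anchors)
    latency += offsets.get((odorant, receptor), 0.0)
    latency = max(latency, LATENCY_FLOOR_MS)
    jitter = _loglinear(concentration, jitter_anchors)
    jitter = min(jitter, latency)  # generator clips negative latencies anyway
    min_isi = _loglinear(concentration, isi_anchors)
    min_isi *= factors.get((odorant, receptor), 1.0)
    min_isi = max(min_isi, REFRACTORY_FLOOR_MS)

    return ResponseParams(
        receptor=receptor,
        odorant=odorant,
        concentration=concentration,
        latency_median=latency,
        latency_sd=jitter,
        min_isi=min_isi,
        peak_rate=1000.0 / min_isi,
        adapt_tau=adapt_tau,
        spont_rate=spont_rate,
    )


# --------------------------------------------------------------------------
# Spike trains
# --------------------------------------------------------------------------

def _poisson_with_deadtime(
    rng: np.random.Generator, rate_hz: float, t0: float, t1: float, deadtime: float
) -> list[float]:
    """Homogeneous Poisson spikes on [t0, t1), thinned by a dead time."""
    if rate_hz <= 0:
        return []
    rate_per_ms = rate_hz / 1000.0
    out: list[float] = []
    t = t0
    while True:
        t += rng.exponential(1.0 / rate_per_ms)
        if t >= t1:
            return out
        if not out or t - out[-1] >= deadtime:
            out.append(t)


def generate_trial(
    params: ResponseParams,
    baseline: float = 200.0,
    duration: float = 200.0,
    rng_seed=None,
    neuron_id: str = "n0",
    trial: int = 0,
    latency_floor: float = LATENCY_FLOOR_MS,
    refractory_floor: float = REFRACTORY_FLOOR_MS,
) -> SpikeTrain:
    """Simulate one trial of one ORN.

    Pre-stimulus spikes on [-baseline, 0) are homogeneous Poisson at
    ``spont_rate`` thinned by the refractory floor.  The first evoked spike
    falls at ``latency_median + N(0, latency_sd)``, clipped below at the
    transduction floor.  Subsequent evoked spikes form a gamma-renewal
    process whose instantaneous rate decays exponentially from
    ``peak_rate`` toward ``spont_rate`` with time constant ``adapt_tau``;
    every interval is bounded below by ``min_isi``.
    """
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    if duration <= params.latency_median:
        raise ValueError("duration must exceed latency_median")
    rng = _rng(rng_seed)

    spikes = _poisson_with_deadtime(
        rng, params.spont_rate, -baseline, 0.0, refractory_floor
    )

    first = params.latency_median + rng.normal(0.0, params.latency_sd)
    first = max(first, latency_floor)
    if first < duration:
        spikes.append(first)
        t = first
        while True:
            rate_hz = params.spont_rate + (
                params.peak_rate - params.spont_rate
            ) * np.exp(-(t - first) / params.adapt_tau)
            mean_interval = 1000.0 / rate_hz
            raw = rng.gamma(RENEWAL_SHAPE, mean_interval / RENEWAL_SHAPE)
            t += max(raw, params.min_isi, refractory_floor)
            if t >= duration:
                break
            spikes.append(t)

    return SpikeTrain(
        neuron_id=neuron_id,
        trial=trial,
        receptor=params.receptor,
        odorant=params.odorant,
        concentration=params.concentration,
        spikes=np.asarray(spikes, dtype=float),
    )


def generate_population(
    receptor: str,
    odorant: str,
    concentration: float,
    n_neurons: int,
    n_trials: int,
    rng_seed=None,
    baseline: float = 200.0,
    duration: float = 200.0,
    inter_neuron_sd: float | None = None,
    params: ResponseParams | None = None,
    neuron_prefix: str | None = None,
    **param_kwargs,
) -> RecordingSet:
    """Simulate ``n_neurons`` x ``n_trials`` trains of one receptor type.

    Per-neuron median latencies are drawn around the calibrated value with
    SD ``inter_neuron_sd`` (default: equal to the trial-to-trial jitter, so
    neuron-to-neuron jitter is similar to trial-to-trial jitter).  Seeding
    uses a SeedSequence fan-out: the same root seed reproduces the exact
    same RecordingSet.
    """
    if n_neurons < 1 or n_trials < 1:
        raise ValueError("n_neurons and n_trials must be >= 1")
    if rng_seed is None:
        raise ValueError("an explicit rng_seed is required")
    base = params or response_params(receptor, odorant, concentration, **param_kwargs)
    if inter_neuron_sd is None:
        inter_neuron_sd = base.latency_sd
    prefix = neuron_prefix or receptor

    root = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = root.spawn(n_neurons)
    trains: list[SpikeTrain] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        lat = base.latency_median + rng.normal(0.0, inter_neuron_sd)
        lat = max(lat, LATENCY_FLOOR_MS)
        neuron_params = ResponseParams(
            receptor=base.receptor,
            odorant=base.odorant,
            concentration=base.concentration,
            latency_median=lat,
            latency_sd=min(base.latency_sd, lat),
            min_isi=base.min_isi,
            peak_rate=base.peak_rate,
            adapt_tau=base.adapt_tau,
            spont_rate=base.spont_rate,
        )
        for trial in range(n_trials):
            trains.append(
                generate_trial(
                    neuron_params,
                    baseline=baseline,
                    duration=duration,
                    rng_seed=rng,
                    neuron_id=f"{prefix}_{i:02d}",
                    trial=trial,
                )
            )
    return RecordingSet(
        trains,
        baseline_window=(-baseline, 0.0),
        response_window=(0.0, duration),
    )
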
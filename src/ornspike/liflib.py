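"""Rank-order-sensitive leaky integrate-and-fire model of the mushroom body.

Circuit (feedforward, five neurons): 8 OR22a receptor neurons excite
projection neuron PN_X and 23 OR59b neurons excite PN_Y; both PNs excite
an inhibitory neuron I and two Kenyon cells KC_X and KC_Y.  Each PN's
synapse onto "its" KC (PN_X -> KC_X, PN_Y -> KC_Y) is stronger than onto
the other KC, and I provides feedforward inhibition to both KCs.  The KC
driven by the earlier-responding PN reaches threshold before the
inhibition arrives; the inhibition then prevents the other, more weakly
primed KC from firing -- so which KC spikes reports the *order* in which
the two receptor-neuron types responded, independent of absolute latency.

Neuron model: current-based LIF,

    dV/dt = -(V - v_rest) / tau_m + I_syn(t),

where every presynaptic spike adds, after the synaptic delay, an
exponentially decaying current of amplitude equal to the synaptic weight
(in mV/ms) and decay constant tau_syn.  Between increments the (V, I_syn)
pair is advanced with the exact closed-form solution of the linear
cascade, so the fixed step dt only quantizes threshold crossings.

Classification rule: a trial is scored methyl butyrate when KC_X spikes
and KC_Y stays silent within the decision window, ethyl acetate for the
converse, and invalid when both or neither spike.  Only each KC's first
spike in the window counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import synthdata
from .types import SpikeTrain

NEURONS = ("PN_X", "PN_Y", "I", "KC_X", "KC_Y")
MB, EA = "methyl butyrate", "ethyl acetate"
INVALID = "invalid"


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire constants for one cell class."""

    v_rest: float = -60.0  # mV
    v_threshold: float = -45.0  # mV
    v_reset: float = -60.0  # mV
    tau_m: float = 5.0  # ms
    refractory: float = 2.0  # ms
    tau_syn: float = 2.0  # ms, decay of synaptic current
    synaptic_delay: float = 1.0  # ms, delay of this cell's outgoing synapses

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.v_rest < self.v_threshold):
            raise ValueError("require v_reset <= v_rest < v_threshold")
        if min(self.tau_m, self.tau_syn, self.synaptic_delay, self.refractory) <= 0:
            raise ValueError("all time constants must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """Connectivity, weights and per-population constants of the circuit.

    Weights are synaptic current amplitudes in mV/ms; excitatory weights
    are positive, inhibitory negative; within each PN the strong KC weight
    strictly exceeds the weak one.
    """

    orn_pn_weight_x: float  # each OR22a ORN -> PN_X
    orn_pn_weight_y: float  # each OR59b ORN -> PN_Y
    pn_kc_strong: float  # PN_X -> KC_X, PN_Y -> KC_Y
    pn_kc_weak: float  # PN_X -> KC_Y, PN_Y -> KC_X
    pn_i_weight: float  # PN_X/PN_Y -> I
    i_kc_weight: float  # I -> KC_X, KC_Y (negative)
    orn_synaptic_delay: float = 1.0  # ms, ORN -> PN
    pn_params: LIFParams = field(default_factory=LIFParams)
    i_params: LIFParams = field(default_factory=lambda: LIFParams(tau_m=3.0))
    kc_params: LIFParams = field(default_factory=LIFParams)
    decision_window: tuple[float, float] = (0.0, 50.0)

    def __post_init__(self) -> None:
        for w in (
            self.orn_pn_weight_x,
            self.orn_pn_weight_y,
            self.pn_kc_strong,
            self.pn_kc_weak,
            self.pn_i_weight,
        ):
            if w <= 0:
                raise ValueError("excitatory weights must be positive")
        if self.i_kc_weight > 0:
            raise ValueError("inhibitory weight must be <= 0")
        if self.pn_kc_strong <= self.pn_kc_weak:
            raise ValueError("strong PN->KC weight must exceed the weak one")


def default_network(**overrides) -> NetworkSpec:
    """Calibrated default circuit.

    ORN -> PN weights are scaled inversely with the anatomical pool size
    (8 OR22a, 23 OR59b) so that roughly half of a pool's near-synchronous
    first spikes drive one PN spike within ~2 ms of the volley.  The
    strong:weak PN -> KC ratio is 4:1 with the strong weight alone
    suprathreshold, and the inhibitory synapse is fast (0.5 ms delay):
    with the ~1 ms rank gap the odorants impose at intermediate
    concentration, the feedforward inhibition must reach the KCs after
    the strongly driven KC crosses threshold but before the weakly
    primed one does, and this combination leaves ~0.5 ms of slack on
    each side of that window.
    """
    defaults = dict(
        orn_pn_weight_x=14.4 / 8,
        orn_pn_weight_y=14.4 / 23,
        pn_kc_strong=24.0,
        pn_kc_weak=6.0,
        pn_i_weight=40.0,
        i_kc_weight=-80.0,
        i_params=LIFParams(tau_m=3.0, synaptic_delay=0.5),
    )
    defaults.update(overrides)
    return NetworkSpec(**defaults)


@dataclass
class NetworkResult:
    """Spikes, membrane traces and the per-trial classification outcome."""

    spikes: dict[str, np.ndarray]  # ms, per simulated neuron
    trace_times: np.ndarray  # ms
    traces: dict[str, np.ndarray]  # mV
    classification: str
    kc_first_spike_latency: float | None  # ms, responding KC; None if invalid


def _psc_peak_time(tau_m: float, tau_syn: float) -> float:
    a = 1.0 / tau_syn - 1.0 / tau_m
    return float(np.log(tau_m / tau_syn) / a)


def psc_peak_amplitude(weight: float, tau_m: float, tau_syn: float) -> float:
    """Closed-form peak of the membrane response to one synaptic event.

    The cascade g' = -g/tau_syn, v' = -v/tau_m + g with g(0) = weight has

        v(t) = weight * (exp(-t/tau_m) - exp(-t/tau_syn)) / (1/tau_syn - 1/tau_m)

    whose maximum this returns (used as an analytic oracle for the
    integrator and by the weight calibration).
    """
    a = 1.0 / tau_syn - 1.0 / tau_m
    t = _psc_peak_time(tau_m, tau_syn)
    return float(weight * (np.exp(-t / tau_m) - np.exp(-t / tau_syn)) / a)


def simulate(
    spec: NetworkSpec,
    orn22_trains: Sequence[SpikeTrain],
    orn59_trains: Sequence[SpikeTrain],
    dt: float = 0.025,
    span: tuple[float, float] = (-25.0, 70.0),
    record_traces: bool = True,
) -> NetworkResult:
    """Integrate the five-neuron circuit driven by ORN spike trains.

    Deterministic given its inputs: all stochasticity lives in the ORN
    trains.  ``dt`` must be at most 0.05 ms -- sub-millisecond timing is
    the object of study.  Spike times are reported on the dt grid.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms")
    if len(orn22_trains) < 1 or len(orn59_trains) < 1:
        raise ValueError("both ORN populations must be non-empty")
    t0, t1 = span
    for tr in list(orn22_trains) + list(orn59_trains):
        if len(tr) and (tr.spikes[0] < t0 or tr.spikes[-1] > t1):
            raise ValueError("ORN spike outside the simulation span")

    n_steps = int(np.ceil((t1 - t0) / dt))
    params = [spec.pn_params, spec.pn_params, spec.i_params, spec.kc_params, spec.kc_params]
    v_rest = np.array([p.v_rest for p in params])
    v_th = np.array([p.v_threshold for p in params])
    v_reset = np.array([p.v_reset for p in params])
    tau_m = np.array([p.tau_m for p in params])
    tau_s = np.array([p.tau_syn for p in params])
    refr_steps = np.array([int(round(p.refractory / dt)) for p in params])
    em = np.exp(-dt / tau_m)
    es = np.exp(-dt / tau_s)
    a = 1.0 / tau_s - 1.0 / tau_m
    # exact one-step propagator of the (g, v) cascade; degenerate
    # tau_m == tau_syn handled by the t*exp limit
    with np.errstate(divide="ignore", invalid="ignore"):
        gv = np.where(np.abs(a) > 1e-12, (em - es) / a, dt * em)

    # pending synaptic increments per target, indexed by step
    inc = np.zeros((n_steps + 2, 5))

    def schedule(step: int, target: int, weight: float) -> None:
        if step < inc.shape[0]:
            inc[step, target] += weight

    for trains, target, w in ((orn22_trains, 0, spec.orn_pn_weight_x),
                              (orn59_trains, 1, spec.orn_pn_weight_y)):
        for tr in trains:
            steps = np.round((tr.spikes + spec.orn_synaptic_delay - t0) / dt).astype(int)
            for k in steps:
                schedule(k, target, w)

    pn_delay = int(round(spec.pn_params.synaptic_delay / dt))
    i_delay = int(round(spec.i_params.synaptic_delay / dt))

    v = v_rest.copy()
    g = np.zeros(5)
    refr_left = np.zeros(5, dtype=int)
    spikes: list[list[float]] = [[] for _ in range(5)]
    traces = np.empty((n_steps + 1, 5)) if record_traces else None
    if record_traces:
        traces[0] = v

    for k in range(n_steps):
        g = g + inc[k]
        active = refr_left == 0
        v = np.where(active, v_rest + (v - v_rest) * em + g * gv, v_reset)
        g = g * es
        refr_left = np.maximum(refr_left - 1, 0)
        fired = active & (v >= v_th)
        if fired.any():
            t_spike = t0 + (k + 1) * dt
            for n in np.nonzero(fired)[0]:
                spikes[n].append(t_spike)
                if n == 0:  # PN_X
                    schedule(k + 1 + pn_delay, 3, spec.pn_kc_strong)
                    schedule(k + 1 + pn_delay, 4, spec.pn_kc_weak)
                    schedule(k + 1 + pn_delay, 2, spec.pn_i_weight)
                elif n == 1:  # PN_Y
                    schedule(k + 1 + pn_delay, 4, spec.pn_kc_strong)
                    schedule(k + 1 + pn_delay, 3, spec.pn_kc_weak)
                    schedule(k + 1 + pn_delay, 2, spec.pn_i_weight)
                elif n == 2:  # I
                    schedule(k + 1 + i_delay, 3, spec.i_kc_weight)
                    schedule(k + 1 + i_delay, 4, spec.i_kc_weight)
            v = np.where(fired, v_reset, v)
            refr_left = np.where(fired, refr_steps, refr_left)
        if record_traces:
            traces[k + 1] = v
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("non-finite membrane potential")

    spike_arrays = {name: np.asarray(s) for name, s in zip(NEURONS, spikes)}
    result = NetworkResult(
        spikes=spike_arrays,
        trace_times=t0 + dt * np.arange(n_steps + 1) if record_traces else np.empty(0),
        traces={name: traces[:, i] for i, name in enumerate(NEURONS)}
        if record_traces
        else {},
        classification=INVALID,
        kc_first_spike_latency=None,
    )
    label, latency = classify_trial(result, spec.decision_window)
    result.classification = label
    result.kc_first_spike_latency = latency
    return result


def classify_trial(
    result: NetworkResult, decision_window: tuple[float, float] = (0.0, 50.0)
) -> tuple[str, float | None]:
    """KC-exclusivity rule: KC_X only -> methyl butyrate, KC_Y only ->
    ethyl acetate, both or neither -> invalid.

    Returns (label, first spike time of the responding KC or None).
    """
    w0, w1 = decision_window

    def first_in_window(name: str) -> float | None:
        s = result.spikes[name]
        s = s[(s >= w0) & (s < w1)]
        return float(s[0]) if s.size else None

    fx, fy = first_in_window("KC_X"), first_in_window("KC_Y")
    if fx is not None and fy is None:
        return MB, fx
    if fy is not None and fx is None:
        return EA, fy
    return INVALID, None


def synthetic_orn_factory(
    concentration: float = -3.0,
    baseline: float = 20.0,
    duration: float = 60.0,
    n_or22a: int = 8,
    n_or59b: int = 23,
    **param_kwargs,
) -> Callable[[str, np.random.Generator], tuple[list[SpikeTrain], list[SpikeTrain]]]:
    """Factory producing one fresh synthetic ORN input set per call.

    Each call draws independent single-trial populations (8 OR22a and 23
    OR59b by default) at the given concentration, carrying the
    generator's odorant-specific latency rank offsets.
    """

    def factory(odorant: str, rng: np.random.Generator):
        seeds = rng.integers(0, 2**31 - 1, size=2)
        rec22 = synthdata.generate_population(
            "OR22a", odorant, concentration, n_or22a, 1,
            rng_seed=int(seeds[0]), baseline=baseline, duration=duration,
            **param_kwargs,
        )
        rec59 = synthdata.generate_population(
            "OR59b", odorant, concentration, n_or59b, 1,
            rng_seed=int(seeds[1]), baseline=baseline, duration=duration,
            **param_kwargs,
        )
        return list(rec22), list(rec59)

    return factory


def classification_rate(
    spec: NetworkSpec,
    train_factory: Callable,
    odorants: Sequence[str] = (MB, EA),
    n_runs: int = 100,
    rng_seed=None,
    dt: float = 0.025,
    span: tuple[float, float] = (-25.0, 70.0),
) -> dict[str, dict]:
    """Percent correct over repeated simulations, per odorant.

    For each run, ``train_factory(odorant, rng)`` supplies fresh ORN
    inputs; the run is correct when the KC-exclusivity rule returns the
    generating odorant.  Also reports the responding KC's first-spike
    latencies on correct runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if rng_seed is None:
        raise ValueError("an explicit rng_seed is required")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    out: dict[str, dict] = {}
    for odorant in odorants:
        n_correct = 0
        latencies: list[float] = []
        for _ in range(n_runs):
            orn22, orn59 = train_factory(odorant, rng)
            res = simulate(spec, orn22, orn59, dt=dt, span=span, record_traces=False)
            if res.classification == odorant:
                n_correct += 1
                latencies.append(res.kc_first_spike_latency)
        out[odorant] = {
            "rate_pct": 100.0 * n_correct / n_runs,
            "n_runs": n_runs,
            "kc_latencies_ms": np.asarray(latencies),
        }
    return out


def time_shift_sweep(
    spec: NetworkSpec,
    train_factory: Callable,
    odorant: str = MB,
    shifts: np.ndarray | None = None,
    n_runs: int = 20,
    rng_seed=None,
    dt: float = 0.025,
    span: tuple[float, float] = (-30.0, 75.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Classification rate versus an artificial OR22a time shift.

    Every OR22a spike is translated by each shift in the grid (default
    -4 ... +4 ms in 0.2 ms steps) while the OR59b trains stay unchanged;
    the same ``n_runs`` input sets are reused across shifts so the sweep
    isolates the effect of relative timing.  Returns (shifts,
    percent classified as the generating odorant).
    """
    if rng_seed is None:
        raise ValueError("an explicit rng_seed is required")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if shifts is None:
        shifts = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.2), 10)
    shifts = np.asarray(shifts, dtype=float)
    if not np.all(np.isfinite(shifts)):
        raise ValueError("shift grid must be finite")

    inputs = [train_factory(odorant, rng) for _ in range(n_runs)]
    rates = np.zeros(shifts.size)
    for i, shift in enumerate(shifts):
        n_correct = 0
        for orn22, orn59 in inputs:
            shifted = [tr.shifted(shift) for tr in orn22]
            res = simulate(spec, shifted, orn59, dt=dt, span=span, record_traces=False)
            if res.classification == odorant:
                n_correct += 1
        rates[i] = 100.0 * n_correct / n_runs
    return shifts, rates
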
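"""Spike-timing statistics: first-spike latency, jitter, minimum ISI,
sliding-window spike probability, and stimulus rise time.

Estimator conventions: all SDs use the sample denominator (n - 1); latency
is the time of the first spike at or after odorant arrival (t = 0) within
the response window; trials without an evoked spike yield an undefined
(None) latency and are excluded, with a warning, from jitter estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import RecordingSet, SpikeTrain, StimulusPulse

FIRST_TO_SECOND = "first_to_second"
GLOBAL_MIN = "global_min"


@dataclass(frozen=True)
class ResponseStats:
    """Per-condition summary of spike timing across neurons and trials."""

    receptor: str
    odorant: str
    concentration: float
    latency_median: float | None  # ms, median over all defined trial latencies
    latency_trial_jitter: float | None  # ms, mean across neurons of per-neuron SD
    latency_neuron_jitter: float | None  # ms, SD across per-neuron medians
    min_isi: float | None  # ms, median across neurons
    n_trials: int
    n_neurons: int


def first_spike_latency(
    train: SpikeTrain, response_window: tuple[float, float] = (0.0, 200.0)
) -> float | None:
    """Time of the first spike with t >= 0 inside the window, or None.

    The window is closed on the left: a spike exactly at odorant arrival
    has latency 0.
    """
    t0, t1 = response_window
    if t0 != 0:
        raise ValueError("response window must start at 0 (odorant arrival)")
    idx = np.searchsorted(train.spikes, 0.0, side="left")
    if idx >= len(train.spikes):
        return None
    first = float(train.spikes[idx])
    return first if first < t1 else None


def _defined_latencies(
    trains: Iterable[SpikeTrain], response_window: tuple[float, float]
) -> tuple[list[float], int]:
    vals, undefined = [], 0
    for tr in trains:
        lat = first_spike_latency(tr, response_window)
        if lat is None:
            undefined += 1
        else:
            vals.append(lat)
    return vals, undefined


def trial_to_trial_jitter(
    trains: Sequence[SpikeTrain],
    response_window: tuple[float, float] = (0.0, 200.0),
) -> float | None:
    """Sample SD (n-1) of one neuron's first-spike latencies across trials.

    Trials with no evoked spike are excluded (a warning reports how many);
    with fewer than two defined latencies the jitter is undefined (None).
    """
    vals, undefined = _defined_latencies(trains, response_window)
    if undefined:
        warnings.warn(
            f"{undefined} trial(s) without an evoked spike excluded from jitter",
            stacklevel=2,
        )
    if len(vals) < 2:
        return None
    return float(np.std(vals, ddof=1))


def neuron_to_neuron_jitter(
    recordings: RecordingSet,
    response_window: tuple[float, float] | None = None,
) -> float | None:
    """Sample SD across neurons of per-neuron median first-spike latencies."""
    window = response_window or recordings.response_window
    medians = []
    for _, trains in recordings.by_neuron().items():
        vals, _ = _defined_latencies(trains, window)
        if vals:
            medians.append(float(np.median(vals)))
    if len(medians) < 2:
        return None
    return float(np.std(medians, ddof=1))


def min_interspike_interval(
    trains: Sequence[SpikeTrain],
    response_window: tuple[float, float] = (0.0, 200.0),
    mode: str = FIRST_TO_SECOND,
) -> float | None:
    """Median across trials of the per-trial evoked interspike interval.

    ``mode="first_to_second"`` uses the interval between the first two
    evoked spikes; ``mode="global_min"`` the shortest interval between any
    consecutive evoked spikes.  The reciprocal of the result is the
    maximum evoked spike rate.
    """
    if mode not in (FIRST_TO_SECOND, GLOBAL_MIN):
        raise ValueError(f"unknown mode {mode!r}")
    t0, t1 = response_window
    per_trial = []
    for tr in trains:
        s = tr.in_window(t0, t1)
        if len(s) < 2:
            continue
        if mode == FIRST_TO_SECOND:
            per_trial.append(float(s[1] - s[0]))
        else:
            per_trial.append(float(np.diff(s).min()))
    if not per_trial:
        return None
    return float(np.median(per_trial))


def sliding_psth(
    recordings: RecordingSet | Sequence[SpikeTrain],
    window_len: float = 1.0,
    step: float = 0.5,
    t_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of trials with >= 1 spike in a sliding window.

    Returns ``(window_starts, probability)``; probabilities lie in [0, 1]
    and are invariant to the order of trials.
    """
    if window_len <= 0 or step <= 0:
        raise ValueError("window_len and step must be positive")
    trains = list(recordings)
    if not trains:
        raise ValueError("empty recording set")
    if t_range is None:
        if isinstance(recordings, RecordingSet):
            t_range = (recordings.baseline_window[0], recordings.response_window[1])
        else:
            lo = min((tr.spikes[0] for tr in trains if len(tr)), default=0.0)
            hi = max((tr.spikes[-1] for tr in trains if len(tr)), default=window_len)
            t_range = (float(lo), float(hi))
    starts = np.arange(t_range[0], t_range[1] - window_len + 1e-9, step)
    hits = np.zeros(starts.size)
    for tr in trains:
        lo = np.searchsorted(tr.spikes, starts, side="left")
        hi = np.searchsorted(tr.spikes, starts + window_len, side="left")
        hits += hi > lo
    return starts, hits / len(trains)


def rise_time_5_95(waveform: StimulusPulse | tuple[np.ndarray, np.ndarray]) -> float | None:
    """5%-to-95% rise time of a stimulus waveform, in ms.

    Measured between the first upward crossings of 5% and 95% of the
    plateau level (the waveform maximum), with linear interpolation
    between samples.  Returns None with a warning when no plateau exists
    (all-zero signal).
    """
    if isinstance(waveform, StimulusPulse):
        t, y = waveform.t, waveform.y
    else:
        t, y = np.asarray(waveform[0], float), np.asarray(waveform[1], float)
    plateau = float(y.max())
    if plateau <= 0:
        warnings.warn("waveform has no plateau; rise time undefined", stacklevel=2)
        return None

    def first_crossing(level: float) -> float:
        above = np.nonzero(y >= level)[0]
        i = int(above[0])
        if i == 0:
            return float(t[0])
        frac = (level - y[i - 1]) / (y[i] - y[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    return first_crossing(0.95 * plateau) - first_crossing(0.05 * plateau)


def condition_stats(
    recordings: RecordingSet,
    isi_mode: str = FIRST_TO_SECOND,
) -> list[ResponseStats]:
    """ResponseStats for every (receptor, odorant, concentration) present."""
    out = []
    window = recordings.response_window
    for receptor, odorant, conc in recordings.conditions():
        sub = recordings.filter(receptor=receptor, odorant=odorant, concentration=conc)
        groups = sub.by_neuron()
        all_lats: list[float] = []
        trial_jits: list[float] = []
        isis: list[float] = []
        for trains in groups.values():
            vals, _ = _defined_latencies(trains, window)
            all_lats.extend(vals)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                jit = trial_to_trial_jitter(trains, window)
            if jit is not None:
                trial_jits.append(jit)
            isi = min_interspike_interval(trains, window, isi_mode)
            if isi is not None:
                isis.append(isi)
        out.append(
            ResponseStats(
                receptor=receptor,
                odorant=odorant,
                concentration=conc,
                latency_median=float(np.median(all_lats)) if all_lats else None,
                latency_trial_jitter=float(np.mean(trial_jits)) if trial_jits else None,
                latency_neuron_jitter=neuron_to_neuron_jitter(sub, window),
                min_isi=float(np.median(isis)) if isis else None,
                n_trials=len(sub),
                n_neurons=len(groups),
            )
        )
    return out
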
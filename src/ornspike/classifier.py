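"""Concentration-invariant odorant classification from latency differences.

The decoder compares the two receptor-neuron populations' response timing:
for each draw it pools 23 OR59b and 8 OR22a picks (neuron sampled with
replacement, one random trial each) and takes, per type, the earliest
first-spike latency across the pool -- the first spike a downstream
circuit could see.  The decision feature is the difference

    delta = OR22a - OR59b        (ms; positive when OR59b leads)

computed for first-spike latencies and, analogously, for per-type median
first-to-second interspike intervals.  A single threshold applied to
delta across all concentrations separates the odorants: OR59b leads for
ethyl acetate (delta > threshold), OR22a leads slightly for methyl
butyrate (delta <= threshold; ties go to the non-leading class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .types import RecordingSet, SpikeTrain

ABSTAIN = "abstain"
#: Odorant assigned when delta exceeds the threshold (OR59b leads).
POSITIVE_ODORANT = "ethyl acetate"
NEGATIVE_ODORANT = "methyl butyrate"

DEFAULT_POOL_SIZES = {"OR59b": 23, "OR22a": 8}


@dataclass(frozen=True)
class LatencyDifferenceSample:
    """One draw's timing differences between receptor types (OR22a - OR59b)."""

    odorant: str
    concentration: float
    delta_latency: float  # ms; NaN when undefined
    delta_isi: float  # ms; NaN when undefined
    draw: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.delta_latency)


def latency_difference(
    recordings: RecordingSet,
    picks: dict[str, list[tuple[str, int]]],
    draw: int = 0,
    population: str = "earliest",
) -> LatencyDifferenceSample:
    """Timing differences for one explicit draw of (neuron, trial) picks.

    ``picks`` maps receptor type to its pooled picks.  The per-type
    population latency is the earliest defined first-spike latency across
    the pool (``population="median"`` uses the median instead); a type
    with no evoked spike marks the sample undefined (NaN).
    """
    if population not in ("earliest", "median"):
        raise ValueError(f"unknown population statistic {population!r}")
    lookup = {(tr.neuron_id, tr.trial): tr for tr in recordings}
    window = recordings.response_window
    lat: dict[str, float] = {}
    isi: dict[str, float] = {}
    odorant, conc = None, None
    for receptor in ("OR22a", "OR59b"):
        if receptor not in picks or not picks[receptor]:
            raise ValueError(f"no picks for receptor {receptor}")
        trains = [lookup[p] for p in picks[receptor]]
        odorant, conc = trains[0].odorant, trains[0].concentration
        lats = [metrics.first_spike_latency(tr, window) for tr in trains]
        lats = [v for v in lats if v is not None]
        if population == "earliest":
            lat[receptor] = min(lats) if lats else np.nan
        else:
            lat[receptor] = float(np.median(lats)) if lats else np.nan
        isis = [
            metrics.min_interspike_interval([tr], window, metrics.FIRST_TO_SECOND)
            for tr in trains
        ]
        isis = [v for v in isis if v is not None]
        isi[receptor] = float(np.median(isis)) if isis else np.nan
    return LatencyDifferenceSample(
        odorant=odorant,
        concentration=conc,
        delta_latency=lat["OR22a"] - lat["OR59b"],
        delta_isi=isi["OR22a"] - isi["OR59b"],
        draw=draw,
    )


def draw_latency_differences(
    recordings: RecordingSet,
    n_draws: int,
    rng_seed=None,
    pool_sizes: dict[str, int] | None = None,
    population: str = "earliest",
) -> list[LatencyDifferenceSample]:
    """Random pool draws of :func:`latency_difference` for one condition.

    ``recordings`` must contain both receptor types at a single
    odorant/concentration condition.
    """
    if rng_seed is None:
        raise ValueError("an explicit rng_seed is required")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sizes = pool_sizes or DEFAULT_POOL_SIZES
    groups_by_type: dict[str, dict[str, list[SpikeTrain]]] = {}
    for receptor in ("OR59b", "OR22a"):
        sub = recordings.filter(receptor=receptor)
        if not len(sub):
            raise ValueError(f"receptor {receptor} absent from recordings")
        groups_by_type[receptor] = sub.by_neuron()

    samples = []
    for d in range(n_draws):
        picks: dict[str, list[tuple[str, int]]] = {}
        for receptor, groups in groups_by_type.items():
            ids = list(groups)
            chosen = rng.choice(len(ids), size=sizes[receptor], replace=True)
            pk = []
            for m in chosen:
                trials = groups[ids[m]]
                tr = trials[rng.integers(len(trials))]
                pk.append((tr.neuron_id, tr.trial))
            picks[receptor] = pk
        samples.append(latency_difference(recordings, picks, draw=d, population=population))
    return samples


def _feature_value(sample: LatencyDifferenceSample, feature: str) -> float:
    if feature == "latency":
        return sample.delta_latency
    if feature == "isi":
        return sample.delta_isi
    raise ValueError(f"unknown feature {feature!r}")


def classify(
    sample: LatencyDifferenceSample | float,
    threshold: float,
    feature: str = "latency",
) -> str:
    """Threshold the timing difference: delta > threshold -> ethyl acetate.

    The comparison is strict, so a delta exactly at the threshold goes to
    methyl butyrate; an undefined sample yields ``"abstain"``.
    """
    delta = (
        _feature_value(sample, feature)
        if isinstance(sample, LatencyDifferenceSample)
        else float(sample)
    )
    if not np.isfinite(delta):
        return ABSTAIN
    return POSITIVE_ODORANT if delta > threshold else NEGATIVE_ODORANT


def classification_accuracy(
    samples: list[LatencyDifferenceSample],
    threshold: float,
    feature: str = "latency",
) -> pd.DataFrame:
    """Percent of draws labelled with their generating odorant, per condition.

    Abstentions (draws without an evoked spike in one type) count as
    incorrect.  Returns a tidy frame with columns odorant, concentration,
    n_draws, accuracy_pct.
    """
    if not samples:
        raise ValueError("no samples")
    rows: dict[tuple[str, float], list[bool]] = {}
    for s in samples:
        correct = classify(s, threshold, feature) == s.odorant
        rows.setdefault((s.odorant, s.concentration), []).append(correct)
    records = [
        {
            "odorant": od,
            "concentration": conc,
            "n_draws": len(v),
            "accuracy_pct": 100.0 * np.mean(v),
        }
        for (od, conc), v in sorted(rows.items())
    ]
    return pd.DataFrame.from_records(records)


def fit_threshold(
    samples: list[LatencyDifferenceSample],
    feature: str = "latency",
) -> float:
    """Threshold maximizing pooled accuracy across all conditions at once.

    Exhaustive scan: accuracy as a function of the threshold is piecewise
    constant with breakpoints at the observed delta values, so every
    interval between consecutive deltas is evaluated and the midpoint of
    the widest optimal interval is returned.
    """
    deltas, labels = [], []
    for s in samples:
        v = _feature_value(s, feature)
        if np.isfinite(v):
            deltas.append(v)
            labels.append(s.odorant)
    if POSITIVE_ODORANT not in labels or NEGATIVE_ODORANT not in labels:
        raise ValueError("both odorant classes must be represented")
    deltas = np.asarray(deltas)
    pos = np.asarray([lab == POSITIVE_ODORANT for lab in labels])

    uniq = np.unique(deltas)
    # accuracy is constant for theta within [u_i, u_{i+1}) and on the two
    # unbounded flanks, so scanning one representative per interval is
    # exhaustive; ties go to the widest optimal interval's midpoint.
    intervals = [(uniq[0] - 2.0, uniq[0])]
    intervals += [(uniq[i], uniq[i + 1]) for i in range(uniq.size - 1)]
    intervals += [(uniq[-1], uniq[-1] + 2.0)]
    best_acc, best_interval = -1.0, intervals[0]
    for lo, hi in intervals:
        pred_pos = deltas > lo
        acc = float(np.mean(pred_pos == pos))
        if acc > best_acc or (
            acc == best_acc and (hi - lo) > (best_interval[1] - best_interval[0])
        ):
            best_acc, best_interval = acc, (lo, hi)
    return float(np.mean(best_interval))
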
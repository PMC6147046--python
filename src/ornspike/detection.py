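"""Pooled signal-detection analysis of odorant-onset detection.

Detection accuracy d_a is the separation between pooled odorant-evoked and
spontaneous spike-count distributions,

    d_a = (mu_evoked - mu_spont) / sqrt((var_evoked + var_spont) / 2),

i.e. the mean difference normalized by the root-mean-square SD (sample
variances, denominator n - 1).  Pools mimic glomerular convergence: about
23 OR59b neurons project to glomerulus DM4 and about 8 OR22a neurons to
DM2, so a downstream projection neuron effectively counts spikes pooled
over such a group.

Sampling scheme: each pool draws ``pool_size`` neurons with replacement;
for every trial replicate each pooled neuron contributes one randomly
chosen trial.  Evoked counts come from a window of length
``integration_time`` slid across the response window (the peak over window
positions is reported); spontaneous counts come from non-overlapping tiles
of the pre-stimulus baseline of the same picks.

An ideal equal-variance Gaussian observer with its criterion midway
between the two means has false-positive rate Phi(-d_a / 2); d_a = 5 maps
to under 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .types import RecordingSet, SpikeTrain


@dataclass
class CountSample:
    """Pooled evoked and spontaneous spike counts for one window setting."""

    evoked_counts: np.ndarray
    spont_counts: np.ndarray
    integration_time: float
    window_start: float
    pool_size: int

    def __post_init__(self) -> None:
        self.evoked_counts = np.asarray(self.evoked_counts, dtype=float)
        self.spont_counts = np.asarray(self.spont_counts, dtype=float)
        if (self.evoked_counts < 0).any() or (self.spont_counts < 0).any():
            raise ValueError("spike counts must be non-negative")


@dataclass
class PeakAccuracy:
    """Peak d_a of random pools at one (pool size, integration time)."""

    mean: float
    sd: float
    peaks: np.ndarray = field(repr=False)
    n_nonfinite: int = 0


def detection_accuracy(evoked_counts, spont_counts) -> float:
    """d_a between evoked and spontaneous count distributions.

    Degenerate cases: identical all-equal samples give 0; zero variance in
    both samples with different means gives +inf (perfect separation).
    """
    e = np.asarray(evoked_counts, dtype=float)
    s = np.asarray(spont_counts, dtype=float)
    if e.size < 2 or s.size < 2:
        raise ValueError("need at least 2 values in each count list")
    gap = e.mean() - s.mean()
    denom = np.sqrt((e.var(ddof=1) + s.var(ddof=1)) / 2.0)
    if denom == 0.0:
        return 0.0 if gap == 0.0 else float(np.inf) * np.sign(gap)
    return float(gap / denom)


def false_positive_rate(d_a: float) -> float:
    """FPR of an ideal Gaussian observer with the criterion midway between means."""
    if d_a < 0:
        raise ValueError("d_a must be non-negative")
    return float(norm.cdf(-d_a / 2.0))


def _lookup(recordings: RecordingSet) -> dict[tuple[str, int], SpikeTrain]:
    return {(tr.neuron_id, tr.trial): tr for tr in recordings}


def _baseline_tiles(recordings: RecordingSet, integration_time: float) -> np.ndarray:
    b0, b1 = recordings.baseline_window
    n_tiles = int(np.floor((b1 - b0) / integration_time))
    if n_tiles < 1:
        raise ValueError("baseline shorter than the integration time")
    return b0 + integration_time * np.arange(n_tiles)


def pooled_counts(
    recordings: RecordingSet,
    pool: list[tuple[str, int]],
    window_start: float,
    integration_time: float,
) -> CountSample:
    """Counts for one fixed pool of (neuron_id, trial) picks.

    The evoked sample holds the single pooled count in
    [window_start, window_start + integration_time); the spontaneous
    sample holds pooled counts from non-overlapping baseline tiles of the
    same length.
    """
    trains = _lookup(recordings)
    picks = [trains[p] for p in pool]
    evoked = sum(tr.count(window_start, window_start + integration_time) for tr in picks)
    tiles = _baseline_tiles(recordings, integration_time)
    spont = np.zeros(tiles.size)
    for tr in picks:
        lo = np.searchsorted(tr.spikes, tiles, side="left")
        hi = np.searchsorted(tr.spikes, tiles + integration_time, side="left")
        spont += hi - lo
    return CountSample(
        evoked_counts=np.array([evoked], dtype=float),
        spont_counts=spont,
        integration_time=integration_time,
        window_start=window_start,
        pool_size=len(pool),
    )


def _da_vector(evoked: np.ndarray, spont: np.ndarray) -> np.ndarray:
    """d_a for each column of an (replicates x window-starts) evoked matrix."""
    mu_e = evoked.mean(axis=0)
    var_e = evoked.var(axis=0, ddof=1)
    mu_s = spont.mean()
    var_s = spont.var(ddof=1)
    denom = np.sqrt((var_e + var_s) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        da = (mu_e - mu_s) / denom
    zero = denom == 0.0
    if zero.any():
        gap = mu_e[zero] - mu_s
        da[zero] = np.where(gap == 0.0, 0.0, np.sign(gap) * np.inf)
    return da


def peak_detection_accuracy(
    recordings: RecordingSet,
    pool_size: int,
    integration_time: float,
    n_pools: int = 40,
    rng_seed=None,
    window_step: float = 1.0,
    n_trial_draws: int | None = None,
) -> PeakAccuracy:
    """Mean +/- SD over random pools of the peak d_a across window positions.

    Neurons are sampled with replacement (recorded sets are smaller than
    the anatomical pools); each trial replicate assigns every pooled
    neuron one random trial.  Pools whose peak d_a is non-finite (both
    variances zero) are excluded from the mean, with their number
    reported.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if rng_seed is None:
        raise ValueError("an explicit rng_seed is required")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    groups = recordings.by_neuron()
    if not groups:
        raise ValueError("empty recording set")
    neuron_ids = list(groups)
    n_draws = n_trial_draws or max(len(v) for v in groups.values())
    r0, r1 = recordings.response_window
    starts = np.arange(r0, r1 - integration_time + 1e-9, window_step)
    tiles = _baseline_tiles(recordings, integration_time)

    # per-(neuron, trial) evoked counts for every window start, cached
    evoked_cache: dict[tuple[str, int], np.ndarray] = {}
    spont_cache: dict[tuple[str, int], np.ndarray] = {}

    def counts_for(tr: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
        key = (tr.neuron_id, tr.trial)
        if key not in evoked_cache:
            lo = np.searchsorted(tr.spikes, starts, side="left")
            hi = np.searchsorted(tr.spikes, starts + integration_time, side="left")
            evoked_cache[key] = (hi - lo).astype(float)
            lo = np.searchsorted(tr.spikes, tiles, side="left")
            hi = np.searchsorted(tr.spikes, tiles + integration_time, side="left")
            spont_cache[key] = (hi - lo).astype(float)
        return evoked_cache[key], spont_cache[key]

    peaks = np.empty(n_pools)
    for p in range(n_pools):
        members = rng.choice(len(neuron_ids), size=pool_size, replace=True)
        evoked = np.zeros((n_draws, starts.size))
        spont_rows = []
        for r in range(n_draws):
            spont_row = np.zeros(tiles.size)
            for m in members:
                trials = groups[neuron_ids[m]]
                tr = trials[rng.integers(len(trials))]
                ev, sp = counts_for(tr)
                evoked[r] += ev
                spont_row += sp
            spont_rows.append(spont_row)
        spont = np.concatenate(spont_rows)
        da = _da_vector(evoked, spont)
        finite = da[np.isfinite(da)]
        peaks[p] = finite.max() if finite.size else np.inf

    finite_peaks = peaks[np.isfinite(peaks)]
    n_bad = int(peaks.size - finite_peaks.size)
    if finite_peaks.size == 0:
        return PeakAccuracy(mean=float(np.inf), sd=float("nan"), peaks=peaks, n_nonfinite=n_bad)
    return PeakAccuracy(
        mean=float(finite_peaks.mean()),
        sd=float(finite_peaks.std(ddof=1)) if finite_peaks.size > 1 else 0.0,
        peaks=peaks,
        n_nonfinite=n_bad,
    )


def min_integration_time(
    recordings: RecordingSet,
    pool_size: int,
    threshold: float = 5.0,
    grid: np.ndarray | None = None,
    n_pools: int = 40,
    n_repetitions: int = 50,
    rng_seed=None,
    window_step: float = 1.0,
) -> np.ndarray:
    """Per-repetition minimum integration time to exceed a d_a threshold.

    For each repetition the smallest grid value whose mean peak d_a (over
    ``n_pools`` random pools) is strictly greater than ``threshold`` is
    recorded; NaN marks repetitions where the threshold is never exceeded
    within the grid (capped at 40 ms by default).  Report the median/IQR
    of the returned values.
    """
    if rng_seed is None:
        raise ValueError("an explicit rng_seed is required")
    grid = np.arange(1.0, 41.0) if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and sorted ascending")
    root = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    out = np.full(n_repetitions, np.nan)
    for rep, child in enumerate(root.spawn(n_repetitions)):
        rng = np.random.default_rng(child)
        for T in grid:
            pa = peak_detection_accuracy(
                recordings,
                pool_size,
                float(T),
                n_pools=n_pools,
                rng_seed=rng,
                window_step=window_step,
            )
            if pa.mean > threshold:
                out[rep] = T
                break
    return out
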
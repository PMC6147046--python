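"""Core containers for stimuli and spike-train data.

Conventions used throughout the package:

* time is in milliseconds;
* t = 0 is odorant arrival at the antenna, defined as the stimulus
  waveform's 5% crossing -- spike times may be negative (pre-stimulus);
* concentration is the log10 of the odorant dilution (e.g. -6 ... -2);
* receptor labels are ``"OR59b"`` (ab2 sensilla, ~23 neurons converging
  on glomerulus DM4) and ``"OR22a"`` (ab3, ~8 neurons onto DM2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

RECEPTORS = ("OR59b", "OR22a")
ODORANTS = ("methyl butyrate", "ethyl acetate")

#: Hard lower bound on interspike intervals enforced by the generator (ms).
REFRACTORY_FLOOR_MS = 1.0


@dataclass(frozen=True)
class StimulusPulse:
    """A single odorant pulse as seen by a fast photoionization detector.

    ``t`` and ``y`` sample the normalized stimulus time course; ``onset_time``
    marks the start of the concentration rise and ``rise_time_5_95`` is the
    time the signal takes to climb from 5% to 95% of its plateau.
    """

    odorant: str
    concentration: float
    t: np.ndarray
    y: np.ndarray
    onset_time: float
    rise_time_5_95: float
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if y.min() < -1e-12 or y.max() > 1.05:
            raise ValueError("stimulus signal must stay within [0, 1.05]")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class ResponseParams:
    """Summary parameters of one ORN's odorant response.

    ``latency_median`` / ``latency_sd`` describe the first evoked spike
    (median latency and trial-to-trial jitter), ``min_isi`` the shortest
    evoked interspike interval (reciprocal of the maximum spike rate),
    ``peak_rate`` and ``adapt_tau`` the decaying evoked firing rate, and
    ``spont_rate`` the spontaneous background rate.
    """

    receptor: str
    odorant: str
    concentration: float
    latency_median: float  # ms
    latency_sd: float  # ms
    min_isi: float  # ms
    peak_rate: float  # spikes/s
    adapt_tau: float  # ms
    spont_rate: float  # spikes/s

    def __post_init__(self) -> None:
        for name in ("latency_median", "latency_sd", "min_isi", "adapt_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.latency_median <= 0 or self.min_isi <= 0 or self.adapt_tau <= 0:
            raise ValueError("latency_median, min_isi and adapt_tau must be > 0")
        if self.latency_sd > self.latency_median:
            raise ValueError("latency_sd must not exceed latency_median")
        if self.peak_rate < self.spont_rate:
            raise ValueError("peak_rate must be >= spont_rate")


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one neuron on one trial, labelled by condition."""

    neuron_id: str
    trial: int
    receptor: str
    odorant: str
    concentration: float
    spikes: np.ndarray  # sorted, strictly increasing, ms

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes, dtype=float)
        if spikes.ndim != 1:
            raise ValueError("spikes must be a 1-D array")
        if spikes.size > 1 and not np.all(np.diff(spikes) > 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "spikes", spikes)

    def __len__(self) -> int:
        return int(self.spikes.size)

    def count(self, t0: float, t1: float) -> int:
        """Number of spikes in the half-open window [t0, t1)."""
        lo, hi = np.searchsorted(self.spikes, [t0, t1], side="left")
        return int(hi - lo)

    def in_window(self, t0: float, t1: float) -> np.ndarray:
        """Spike times in the half-open window [t0, t1)."""
        lo, hi = np.searchsorted(self.spikes, [t0, t1], side="left")
        return self.spikes[lo:hi]

    def shifted(self, delta: float) -> "SpikeTrain":
        return replace(self, spikes=self.spikes + delta)

    def min_gap(self) -> float:
        if len(self) < 2:
            return np.inf
        return float(np.diff(self.spikes).min())


@dataclass
class RecordingSet:
    """A collection of spike trains plus analysis windows.

    ``baseline_window`` is the pre-stimulus span used for spontaneous-count
    sampling (ends at or before 0); ``response_window`` starts at odorant
    arrival (0).
    """

    trains: list[SpikeTrain] = field(default_factory=list)
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    response_window: tuple[float, float] = (0.0, 200.0)

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        r0, r1 = self.response_window
        if b1 > 0:
            raise ValueError("baseline window must end at or before 0")
        if r0 != 0:
            raise ValueError("response window must start at 0 (odorant arrival)")
        if b0 >= b1 or r0 >= r1:
            raise ValueError("windows must be non-empty intervals")

    def __len__(self) -> int:
        return len(self.trains)

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains)

    def filter(
        self,
        receptor: str | None = None,
        odorant: str | None = None,
        concentration: float | None = None,
        neuron_id: str | None = None,
    ) -> "RecordingSet":
        """New RecordingSet holding only the trains that match all given labels."""
        out = []
        for tr in self.trains:
            if receptor is not None and tr.receptor != receptor:
                continue
            if odorant is not None and tr.odorant != odorant:
                continue
            if concentration is not None and not np.isclose(
                tr.concentration, concentration
            ):
                continue
            if neuron_id is not None and tr.neuron_id != neuron_id:
                continue
            out.append(tr)
        return RecordingSet(out, self.baseline_window, self.response_window)

    @property
    def neuron_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trains:
            seen.setdefault(tr.neuron_id, None)
        return list(seen)

    def by_neuron(self) -> dict[str, list[SpikeTrain]]:
        """Trains grouped by neuron id, trials sorted."""
        groups: dict[str, list[SpikeTrain]] = {}
        for tr in self.trains:
            groups.setdefault(tr.neuron_id, []).append(tr)
        for trs in groups.values():
            trs.sort(key=lambda t: t.trial)
        return groups

    def conditions(self) -> list[tuple[str, str, float]]:
        """Distinct (receptor, odorant, concentration) labels, in first-seen order."""
        seen: dict[tuple[str, str, float], None] = {}
        for tr in self.trains:
            seen.setdefault((tr.receptor, tr.odorant, tr.concentration), None)
        return list(seen)

    def extend(self, trains: Iterable[SpikeTrain]) -> None:
        self.trains.extend(trains)
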
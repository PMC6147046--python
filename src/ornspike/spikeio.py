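"""Tabular I/O for spike trains, stimulus traces, and run manifests.

Interchange dialect: plain CSV with one row per spike and the header
``neuron_id,receptor,odorant,concentration,trial,spike_time_ms``.  Extra
columns are ignored on read; rows are written sorted by (neuron, trial,
time) so repeated runs are byte-identical.  Stimulus traces are two-column
CSV (``time_ms,signal``); manifests are JSON.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .types import RecordingSet, SpikeTrain, StimulusPulse

SPIKE_COLUMNS = [
    "neuron_id",
    "receptor",
    "odorant",
    "concentration",
    "trial",
    "spike_time_ms",
]


class FormatError(ValueError):
    """A required column is missing or a value cannot be parsed."""


def read_spikes(
    path,
    baseline_window: tuple[float, float] = (-200.0, 0.0),
    response_window: tuple[float, float] = (0.0, 200.0),
) -> RecordingSet:
    """Load a spike CSV into a RecordingSet.

    Rows are grouped by (neuron_id, trial, odorant, concentration); spike
    times are sorted on load, so unsorted input is tolerated.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if not np.isfinite(df["spike_time_ms"]).all():
        raise FormatError("spike_time_ms contains non-finite values")
    if not np.isfinite(df["concentration"]).all():
        raise FormatError("concentration contains non-finite values")

    trains = []
    keys = ["neuron_id", "trial", "receptor", "odorant", "concentration"]
    for (neuron_id, trial, receptor, odorant, conc), grp in df.groupby(
        keys, sort=True
    ):
        trains.append(
            SpikeTrain(
                neuron_id=str(neuron_id),
                trial=int(trial),
                receptor=str(receptor),
                odorant=str(odorant),
                concentration=float(conc),
                spikes=np.sort(grp["spike_time_ms"].to_numpy(dtype=float)),
            )
        )
    return RecordingSet(trains, baseline_window, response_window)


def spikes_frame(recordings: RecordingSet) -> pd.DataFrame:
    """One row per spike, sorted by (neuron, trial, time)."""
    rows = []
    for tr in recordings:
        for s in tr.spikes:
            rows.append(
                (tr.neuron_id, tr.receptor, tr.odorant, tr.concentration, tr.trial, s)
            )
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    return df.sort_values(["neuron_id", "trial", "spike_time_ms"]).reset_index(
        drop=True
    )


def write_spikes(recordings: RecordingSet, path) -> None:
    """Write a RecordingSet as a spike CSV (inverse of :func:`read_spikes`).

    Trains without any spike leave no row; an empty set yields a
    header-only file.
    """
    spikes_frame(recordings).to_csv(path, index=False)


def write_stimulus(pulse: StimulusPulse, path) -> None:
    pd.DataFrame({"time_ms": pulse.t, "signal": pulse.y}).to_csv(path, index=False)


def read_stimulus(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("time_ms", "signal"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    return df["time_ms"].to_numpy(float), df["signal"].to_numpy(float)


def write_manifest(path, seed: int | None, config: dict[str, Any], **extra) -> None:
    """Machine-readable run provenance: seed, configuration, versions."""
    from . import __version__

    manifest = {
        "package": "ornspike",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def load_config(path=None, defaults: dict[str, Any] | None = None) -> dict[str, Any]:
    """Merge a YAML config file over the given defaults (shallow)."""
    merged = dict(defaults or {})
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise FormatError("config file must contain a mapping")
        merged.update(loaded)
    return merged
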
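"""Delimited-text I/O for event tables, traces and analysis artifacts.

Event tables are UTF-8 delimited text with a required header and columns
``pair_id, cell_id, trial, time_s``.  Traces are two-column delimited text
(``time_s`` plus a value column) with an optional JSON sidecar carrying
sampling metadata.  Correlograms, spectrograms and ridge tables export as
plain delimited text so artifacts remain diff-able.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_events import EventTrain, PairRecording, ProtocolConfig, TrialSet

EVENT_COLUMNS = ["pair_id", "cell_id", "trial", "time_s"]


def write_event_table(pairs, path, sep="\t") -> None:
    """Write a list of PairRecording objects as one long event table."""
    rows = []
    for pair in pairs:
        for cell_name, ts in (("a", pair.cell_a), ("b", pair.cell_b)):
            for k, tr in enumerate(ts.trains):
                for t in tr.times:
                    rows.append((pair.pair_id, f"{pair.pair_id}:{cell_name}",
                                 k, t))
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep=sep, index=False)


def read_event_table(path, duration: float,
                     protocol: ProtocolConfig | None = None, sep="\t") -> list:
    """Read an event table back into PairRecording objects.

    ``duration`` (and optionally the protocol) are supplied by the caller
    or a config sidecar; the table itself holds only event times.
    Malformed rows raise with the offending row index.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    bad = df.index[df["time_s"].isna() | (df["time_s"] < 0)]
    if len(bad):
        raise ValueError(f"malformed event table row {bad[0]}")
    protocol = protocol or ProtocolConfig()
    pairs = []
    for pair_id, g in df.groupby("pair_id", sort=True):
        cells = sorted(g["cell_id"].unique())
        if len(cells) != 2:
            raise ValueError(f"pair {pair_id!r} must have exactly two cells")
        n_trials = int(g["trial"].max()) + 1
        sets = []
        for cell in cells:
            gc = g[g["cell_id"] == cell]
            trains = []
            for k in range(n_trials):
                t = np.sort(gc.loc[gc["trial"] == k, "time_s"].to_numpy(float))
                t = t[np.concatenate(([True], np.diff(t) > 0))] if t.size else t
                trains.append(EventTrain(t, duration, label=str(cell)))
            sets.append(TrialSet(tuple(trains), protocol, label=str(cell)))
        pairs.append(PairRecording(sets[0], sets[1], pair_id=str(pair_id)))
    return pairs


def write_trace(path, values: np.ndarray, fs: float, units: str = "pA",
                baseline_window=None, sep="\t") -> None:
    """Two-column delimited trace with a JSON metadata sidecar."""
    t = np.arange(values.size) / fs
    pd.DataFrame({"time_s": t, units: values}).to_csv(path, sep=sep,
                                                      index=False)
    meta = {"fs": fs, "units": units, "baseline_window": baseline_window}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_trace(path, sep="\t") -> tuple:
    """Read a trace and its sidecar; returns (values, fs, metadata)."""
    df = pd.read_csv(path, sep=sep)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    value_col = [c for c in df.columns if c != "time_s"][0]
    values = df[value_col].to_numpy(float)
    fs = meta.get("fs")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy(float))))
    return values, float(fs), meta


def write_correlogram(path, correlogram, sep="\t") -> None:
    pd.DataFrame({"lag_s": correlogram.lags,
                  "value": correlogram.values}).to_csv(path, sep=sep,
                                                       index=False)


def write_spectrogram(path, sg, sep="\t") -> None:
    """Delimited matrix: first column freq_hz, remaining columns times."""
    df = pd.DataFrame(sg.power, index=sg.freqs,
                      columns=[f"{t:.6f}" for t in sg.times])
    df.index.name = "freq_hz"
    df.to_csv(path, sep=sep)


def write_ridges(path, ridge_sets, pair_ids, sep="\t") -> None:
    rows = []
    for pid, ridges in zip(pair_ids, ridge_sets):
        for rid, r in enumerate(ridges):
            for t, f, p in zip(r.times, r.freqs, r.powers):
                rows.append((pid, rid, t, f, p))
    pd.DataFrame(rows, columns=["pair_id", "ridge_id", "time_s", "freq_hz",
                                "power"]).to_csv(path, sep=sep, index=False)
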
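#!/usr/bin/env python
"""IPSC detection, kinetics and synchrony decomposition.

Detects IPSCs in the simulated current traces with the sliding
template-matching fit, measures 20-80% rise times and the median-waveform
decay constant, and decomposes paired IPSC trains into synchronous
(|dt| <= 1 ms) and asynchronous classes with the F_synch(w) curve.
Writes per-cell event tables and a kinetics/synchrony summary to
results/ipsc/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from obsync.io import read_trace
from obsync.ipsc_detect import detect_ipscs, f_synch_curve, ipsc_kinetics, synchrony_decomposition

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "ipsc"
OUT.mkdir(parents=True, exist_ok=True)

cells = {}
for path in sorted((ROOT / "synthetic").glob("ipsc_cell*.tsv")):
    trace, fs, meta = read_trace(path)
    events = detect_ipscs(trace, fs,
                          baseline_window=tuple(meta["baseline_window"]))
    kin = ipsc_kinetics(events, trace, fs)
    cells[path.stem] = {"events": events, "kin": kin}

rows = [(name, e.time, e.amplitude, e.criterion)
        for name, d in cells.items() for e in d["events"]]
pd.DataFrame(rows, columns=["cell_id", "time_s", "amplitude_pA",
                            "criterion"]).to_csv(OUT / "events.tsv",
                                                 sep="\t", index=False)

summary = {name: {
    "n_events": len(d["events"]),
    "rate_hz": len(d["events"]) / 5.0,
    "rise_20_80_ms_median": float(np.nanmedian(d["kin"]["rise_20_80_ms"])),
    "decay_tau_ms": d["kin"]["decay_tau_s"] * 1000.0,
} for name, d in cells.items()}

# pairwise synchrony of the first two cells (independently generated, so
# F_synch should track the chance curve 1 - exp(-2 r w))
names = sorted(cells)
ta = np.array([e.time for e in cells[names[0]]["events"]])
tb = np.array([e.time for e in cells[names[1]]["events"]])
decomp = synchrony_decomposition(ta, tb, w_ms=1.0)
curve = f_synch_curve(ta, tb)
r_mean = 0.5 * (ta.size + tb.size) / 5.0
summary["pair_0_1"] = {
    "sync_fraction_at_1ms": decomp["sync_fraction"],
    "chance_at_1ms": float(1 - np.exp(-2 * r_mean * 0.001)),
    "f_synch": dict(zip(map(float, curve.w_grid_ms),
                        map(float, curve.f_synch))),
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=2))

for name in names:
    s = summary[name]
    print(f"{name}: {s['n_events']} IPSCs ({s['rate_hz']:.1f} Hz), "
          f"rise {s['rise_20_80_ms_median']:.2f} ms, "
          f"tau {s['decay_tau_ms']:.2f} ms")
p = summary["pair_0_1"]
print(f"independent pair: F_synch(1 ms) = {p['sync_fraction_at_1ms']:.3f} "
      f"vs chance {p['chance_at_1ms']:.3f}")
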
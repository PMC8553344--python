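#!/usr/bin/env python
"""Spike-time synchrony and periodicity analysis of the simulated dataset.

Runs the full per-pair pipeline on the event tables written by
01_simulate_dataset.py: surrogate-corrected cross-correlograms, CPSD/APSD
spectrograms, dataset-pooled ridge thresholds (xi, lambda), ridge
detection, ridge summaries and rate-vs-ridge coupling.  Writes per-pair
ridge tables and a dataset summary to results/spikes/.
"""

import json
from pathlib import Path

import numpy as np

from obsync.config import AnalysisConfig
from obsync.io import read_event_table, write_ridges
from obsync.pipeline import run_spike_analysis

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "spikes"
OUT.mkdir(parents=True, exist_ok=True)

pairs = read_event_table(ROOT / "synthetic" / "spike_events.tsv",
                         duration=1.2)
tc = [p for p in pairs if p.pair_id.startswith("TC")]
mc = [p for p in pairs if p.pair_id.startswith("MC")]

cfg = AnalysisConfig(seed=11)
bundle = run_spike_analysis(pairs, cfg)

write_ridges(OUT / "cpsd_ridges.tsv",
             [bundle["pairs"][p.pair_id]["cpsd_ridges"] for p in pairs],
             [p.pair_id for p in pairs])

summary = {}
for name, group in (("TC", tc), ("MC", mc)):
    with_ridge = [p.pair_id for p in group
                  if bundle["pairs"][p.pair_id]["cpsd_ridges"]]
    peaks = [bundle["pairs"][p.pair_id]["corrected_peak"] for p in group]
    freqs = np.concatenate(
        [r.freqs for p in group
         for r in bundle["pairs"][p.pair_id]["cpsd_ridges"]]
        or [np.array([])])
    ratios = [bundle["pairs"][p.pair_id]["rate_vs_ridge"][c]["mean_ratio"]
              for p in group for c in ("cell_a", "cell_b")]
    ratios = [r for r in ratios if np.isfinite(r)]
    summary[name] = {
        "n_pairs": len(group),
        "n_with_cpsd_ridge": len(with_ridge),
        "mean_corrected_peak": float(np.mean(peaks)),
        "median_ridge_freq_hz": float(np.median(freqs)) if freqs.size else None,
        "mean_rate_ridge_ratio": float(np.mean(ratios)) if ratios else None,
    }
summary["xi_threshold"] = bundle["xi"].value
summary["config_hash"] = bundle["config"]["config_hash"]
(OUT / "summary.json").write_text(json.dumps(summary, indent=2))

for name in ("TC", "MC"):
    s = summary[name]
    print(f"{name}: {s['n_with_cpsd_ridge']}/{s['n_pairs']} pairs with >=1 "
          f"CPSD ridge; median ridge frequency "
          f"{s['median_ridge_freq_hz']} Hz; mean null-corrected peak "
          f"{s['mean_corrected_peak']:.0f}")
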
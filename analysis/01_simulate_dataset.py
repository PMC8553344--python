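#!/usr/bin/env python
"""Simulate the study's paired-recording dataset.

Generates two groups of gamma-synchronized cell pairs under the 5 x 10 ms
/ 200 ms photostimulation protocol:

* a TC-like group (densely synchronized, decelerating 90->50 Hz gamma
  chirps, high per-cycle participation), and
* an MC-like group (mostly independent phasic firing; a minority of pairs
  weakly synchronized),

plus IPSC current traces (biexponential events over noise) and
step-current voltage traces containing subthreshold oscillations for the
resonance analysis.  Event tables, traces and the ground-truth sidecar
land in results/synthetic/.
"""

import json
from pathlib import Path

import numpy as np

from obsync.io import write_event_table, write_trace
from obsync.pipeline import substream
from obsync.synth import (
    SyncPairSpec,
    ipsc_trace,
    phasic_poisson_pair,
    sto_trace,
    synchronous_pair,
)

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

# --- spike-time dataset ---------------------------------------------------
tc_pairs = []
for k in range(12):
    p = synchronous_pair(SyncPairSpec(
        seed=substream(SEED, f"tc-{k}"), f_start=90.0, f_end=50.0,
        phase_jitter=0.001, participation=0.8, n_trials=10))
    object.__setattr__(p, "pair_id", f"TC{k:02d}")
    tc_pairs.append(p)

mc_pairs = []
for k in range(10):
    if k < 3:  # minority of MC pairs carry weak synchrony
        p = synchronous_pair(SyncPairSpec(
            seed=substream(SEED, f"mc-sync-{k}"), f_start=55.0, f_end=45.0,
            phase_jitter=0.002, participation=0.4, n_trials=10,
            baseline_rate=5.0))
    else:
        p = phasic_poisson_pair(seed=substream(SEED, f"mc-null-{k}"))
    object.__setattr__(p, "pair_id", f"MC{k:02d}")
    mc_pairs.append(p)

write_event_table(tc_pairs + mc_pairs, OUT / "spike_events.tsv")
gt = {p.pair_id: p.metadata.get("ground_truth", {"independent": True})
      for p in tc_pairs + mc_pairs}

# --- IPSC traces ----------------------------------------------------------
ipsc_gt = {}
for k in range(4):
    rng = np.random.default_rng(substream(SEED, f"ipsc-{k}"))
    times = np.sort(rng.uniform(0.1, 4.9, 60))
    times = times[np.concatenate(([True], np.diff(times) > 0.002))]
    amps = rng.uniform(20, 80, times.size)
    trace, g = ipsc_trace(times, amps, noise_sd=5.0, duration=5.0,
                          seed=substream(SEED, f"ipsc-noise-{k}"))
    write_trace(OUT / f"ipsc_cell{k}.tsv", trace, fs=10_000.0, units="pA",
                baseline_window=[0.0, 0.05])
    ipsc_gt[f"ipsc_cell{k}"] = {"n_events": int(times.size)}

# --- STO step responses ---------------------------------------------------
sto_gt = {}
for cell, n_steps_with_sto in (("TCcell", 10), ("MCcell", 5)):
    for step in range(10):
        has = step < n_steps_with_sto
        vm, g = sto_trace(
            sto_freq=45.0, sto_amp=1.0,
            sto_epochs=((0.8, None),) if has else (),
            n_periods=4, noise_sd=1 / 3,
            seed=substream(SEED, f"sto-{cell}-{step}"))
        write_trace(OUT / f"sto_{cell}_step{step}.tsv", vm, fs=10_000.0,
                    units="mV")
        sto_gt[f"{cell}_step{step}"] = {"has_sto": has, "freq": 45.0}

(OUT / "ground_truth.json").write_text(json.dumps(
    {"seed": SEED, "spike_pairs": gt, "ipsc": ipsc_gt, "sto": sto_gt},
    indent=2, default=float))

print(f"wrote {len(tc_pairs)} TC-like and {len(mc_pairs)} MC-like pairs, "
      f"{len(ipsc_gt)} IPSC traces and {len(sto_gt)} STO step responses "
      f"to {OUT}")
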
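# obsync

Spike-time synchrony, network-oscillation and subthreshold-resonance
analysis for paired recordings of olfactory-bulb principal neurons
(mitral and tufted cells), with synthetic-data generators that stand in
for the raw recordings.

Mitral cells (MCs) and tufted cells (TCs) are the two excitatory output
channels of the main olfactory bulb. During sniff-paced (5 Hz) optogenetic
input, pairs of these cells synchronize their spikes at gamma frequencies
(40–100 Hz), and the two cell types do so differently: TC pairs
synchronize densely (a spike on most oscillation cycles, tracking a
decelerating intra-sniff frequency chirp), MC pairs sparsely. This
package implements the full analysis chain used to quantify that
difference, for anyone who has paired event-time or trace data (or wants
a tested reference implementation of the methods):

- **Event-train model and firing statistics** (`obsync.core_events`) —
  spike/IPSC trains convolved with a unit-area 1 ms Gaussian kernel,
  sequential rates (1/inter-event interval), PSTHs, and the CV2
  statistic, CV2ᵢ = 2·|ISIᵢ₊₁ − ISIᵢ| / (ISIᵢ₊₁ + ISIᵢ).
- **Surrogate-corrected cross-correlograms** (`obsync.correlogram`) —
  trial-averaged C(τ) of convolved trains; chance synchrony removed by
  subtracting the mean correlogram of rate-matched inhomogeneous-Poisson
  surrogates (Lewis–Shedler thinning against the PSTH); central peak
  within |Δt| ≤ 5 ms.
- **CPSD/APSD spectrograms** (`obsync.spectral`) — Welch cross- and
  auto-power spectral densities (100 ms Hamming window, 95% overlap,
  10 Hz × 5 ms resolution), magnitude before trial averaging so
  within-trial synchrony survives cross-trial phase variability; a 500 ms
  window variant for theta (2–12 Hz).
- **Ridge detection** (`obsync.ridge`) — continuous supra-threshold
  epochs in a spectrogram (threshold ξ/λ/ζ = dataset-pooled 95th
  percentile of 40–200 Hz power; continuity ΔHz/ms < 150), greedy
  maximal tracking, slope fits (deceleration in Hz/ms), prevalence,
  occupancy, and the instantaneous-rate : ridge-frequency ratio.
- **IPSC analysis** (`obsync.ipsc_detect`) — sliding template-matching
  detection (abridged biexponential template: 4 ms total, 1 ms baseline,
  τ_rise 0.4 ms, τ_decay 3 ms; Clements–Bekkers criterion plus the
  2.5 × baseline-SD amplitude rule), 20–80% rise times, median-waveform
  decay fits, and synchronous/asynchronous decomposition with
  F_synch(w_IPSC).
- **Subthreshold oscillations** (`obsync.sto`) — spike interpolation,
  Morlet (ω₀ = 6) scalograms over 10–150 Hz, iterative ridge extraction
  (ΔHz/ms ≤ 30, ≥ 2 periods, < 20% frequency deviation), constrained
  sinusoid fits (amplitude = segment SD, phase by least squares), the
  ≥ 10-event resonance rule, and post-STO spike phases.
- **Inferential statistics** (`obsync.stats_infer`) — 2×2 chi-squared
  without continuity correction, Rayleigh and Watson–Williams circular
  tests, Benjamini–Hochberg adjustment.
- **Synthetic data** (`obsync.synth`) — generators for every input:
  gamma-synchronized pairs (chirps, jitter, per-cycle participation),
  phasic independent-Poisson pairs, IPSC current traces, and
  step-current voltage responses with programmed STOs.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
simulated data:

```sh
python analysis/01_simulate_dataset.py
python analysis/02_spike_synchrony.py
python analysis/03_ipsc_analysis.py
python analysis/04_sto_resonance.py
python analysis/05_group_statistics.py
```

which prints (abridged):

```
TC: 12/12 pairs with >=1 CPSD ridge; median ridge frequency 80.0 Hz; mean null-corrected peak 3300
MC: 0/10 pairs with >=1 CPSD ridge; ... mean null-corrected peak 168
ipsc_cell0: 60 IPSCs (12.0 Hz), rise 0.56 ms, tau 2.85 ms
independent pair: F_synch(1 ms) = 0.034 vs chance 0.023
TCcell: 10 confirmed STOs -> resonant
MCcell: 5 confirmed STOs -> non-resonant
simulated dataset: ridge prevalence 12/12 vs 0/10, chi2 = 22.00, p = 2.73e-06
cpsd_prevalence: chi2 = 17.28 (p = 3.23e-05)
```

Reading this: every densely synchronized (TC-like) pair shows at least
one epoch of robust periodic synchrony (a CPSD ridge) and no
independent-firing (MC-like) pair does; IPSC kinetics are recovered near
the generating template (τ ≈ 3 ms); the synchronous-IPSC fraction of an
independent pair sits at its chance level 1 − e^(−2rw); the cell with
STOs on all ten current steps is classified resonant; and the
reconstructed worked-example table reproduces χ² = 17.3.

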
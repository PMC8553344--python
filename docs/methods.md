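# Methods

This note documents the models, conventions, and numerical choices behind
`obsync`, the way the package itself would explain them to a maintainer.
Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not compute.

## Signal model and conventions

All times are in seconds; the canonical sampling rate is 10 kHz
(configurable). Event trains (spike or IPSC times) are converted to
continuous signals by summing unit-area Gaussians (σ = 1 ms, truncated at
±5σ, no boundary renormalisation — analysis windows are expected to be
padded by ≥ 5σ). The unit-area kernel makes the signal mean equal the
firing rate, so products of convolved trains have rate-squared units and
an independent pair's correlogram baseline is r₁·r₂.

Cross-correlograms are computed per trial over the analysis window,
C(τ) = (1/T)∫ s_a(t)·s_b(t+τ) dt, then averaged across trials (positive τ
means cell b follows cell a). Mean subtraction is applied within the
window. Sequential rates (1/IEI) are stamped at the later event of each
interval so they can be paired with time-resolved spectrogram bins. CV2
uses the pairwise formulation 2|ΔISI|/(ISI sum), bounded in [0, 2] and
invariant to time rescaling.

## Welch spectrograms

CPSD/APSD spectrograms use 100 ms Hamming windows at 95% overlap: one
Welch segment per time bin (the window is both the segment and the time
resolution unit), 10 Hz frequency spacing, 5 ms hop, times referenced to
photostimulation onset. The magnitude of the per-window cross-spectrum is
taken **before** trial averaging: network gamma is coherent within a
trial but not phase-locked to the stimulus, so averaging complex spectra
across trials would cancel exactly the synchrony of interest. Stored
power is |S₁₂| (for the auto case |S₁₁| = |F|², a true power); every
threshold-based result is invariant to monotone rescalings of this
choice. Theta-band (2–12 Hz) analyses cannot be resolved by a 100 ms
window; a 500 ms window at the same overlap fraction is used there
(2 Hz resolution). The protocol-averaged spectrum is the time mean of the
spectrogram, which coincides with Welch's segment-averaged estimate.

## Surrogate null

Chance synchrony is estimated from independent inhomogeneous-Poisson
surrogates rate-matched to each cell: λ(t) is the trial-pooled PSTH,
events are drawn by Lewis–Shedler thinning (exact for bounded λ), and 10
surrogate datasets are averaged for the null correlogram (the count is a
package default; more datasets only tighten the null).

The PSTH smoothing used for *rate matching* is σ = 1 ms (the general
`psth()` default remains 10 ms for display/rate purposes). This choice is
deliberate: the 5 Hz stimulus envelope has sharp edges, and heavier
smoothing attenuates the envelope's harmonics in the surrogates but not
in the data, leaving the null-corrected correlogram with a positive
envelope-covariance residual at small lags (measured at ≈ 0.25 × the
corrected-value SD for σ = 10 ms on independent phasic pairs, and
≈ 0.03 × SD at σ = 1 ms). Estimation noise at small σ is independent
between the two cells and therefore unbiased in the product. Note that
with stimulus-locked oscillations a fine-resolution PSTH transfers the
locked modulation into the surrogates — which is correct behaviour for a
*rate-matched* null: stimulus-locked structure is a rate pattern, not
trial-to-trial synchrony.

## Ridge analysis

A ridge is a temporally contiguous supra-threshold track of band-limited
(40–200 Hz) local spectral maxima. The threshold (ξ for spike CPSD, λ for
APSD, ζ for IPSC CPSD) is the 95th percentile of band power pooled over
all time bins of all trial-averaged spectrograms in the dataset — it is a
*dataset-level* quantity computed before any per-pair detection, so
prevalence comparisons between groups analysed together are meaningful.
Tracking is greedy and maximal: seed at the global supra-threshold local
maximum, extend bidirectionally to the nearest supra-threshold local
maximum per time step subject to the 150 Hz/ms continuity limit (at a
5 ms hop this allows 750 Hz jumps, so segmentation is in practice
threshold-driven), remove claimed bins, repeat. Ties between equidistant
candidates break toward the lower frequency (the decelerating-gamma
prior); minimum ridge length is 2 bins (10 ms), the smallest span that is
"continuous".

Ridge slope (Hz/ms; negative = deceleration) is a least-squares fit of
ridge frequency against time. For summary statistics the fit drops bins
within half a Welch window (50 ms) of either ridge end: windows that
straddle an epoch boundary average a truncated chirp, so the ridge
plateaus there and an untrimmed fit systematically understates the
deceleration (with a 150 ms chirp and 100 ms windows, by roughly a
third).

The rate:frequency ratio pairs each ISI whose later spike falls inside a
ridge with the ridge frequency at the nearest bin; mean(rate/frequency)
approaches 1 under dense (one spike per cycle) synchrony and 0.5 under
strict every-other-cycle firing. (Bernoulli participation at p = 0.5 is
*not* every-other-cycle firing: the ISI mixture gives a mean ratio of
ln 2 ≈ 0.69.)

## IPSC detection and kinetics

Detection slides the abridged biexponential template
g(t) = (1 − e^(−t/τ_r))·e^(−t/τ_d) (τ_r = 0.4 ms, τ_d = 3 ms, 4 ms total
with a 1 ms baseline, unit peak) across the outward-positive current,
fitting scale and offset by least squares at every offset with rolling
sums. A candidate needs both the Clements–Bekkers criterion
(scale / SE ≥ 3.0, a package default — only the amplitude rule is
prescribed) and a fitted amplitude ≥ 2.5 × the baseline-noise SD (noise
estimated from first differences of the designated baseline segment, so
slow drift does not inflate it). Candidates closer than 0.5 ms merge,
keeping the larger criterion; the event time is the template-window
onset (a consistent cross-cell convention is what matters for |Δt|
classification).

The 20–80% rise time of the unit-peak template itself is 0.308 ms by
root finding on g (the rising exponential alone would suggest ≈ 0.55 ms,
but the decay factor shifts both crossings). Because temporal summation
precludes per-event decay fits at realistic rates, the decay constant is
a single-exponential fit (with free offset) to the peak-aligned *median*
waveform over all detected events (≥ 5 required), starting 4·τ_r past
the peak — earlier the biexponential's rise term has not saturated and
inflates the fitted constant — and extending 5·τ_d.

Synchrony decomposition classifies each event independently: synchronous
iff a partner event in the other cell lies within ±w (default 1 ms),
which is symmetric under swapping the pair; F_synch(w) is this fraction
over the grid {0.5, 1, 2, 3, 4, 5} ms and tracks 1 − e^(−2rw) for
independent Poisson trains.

## STO pipeline

Spikes are removed by linear interpolation from 1 ms before each spike
to the first return within 1 mV of the pre-spike level (capped at
+10 ms; overlapping spans merge). The Morlet transform (centre-frequency
parameter ω₀ = 6) runs on a 1 Hz-step pseudo-frequency grid over
10–150 Hz after decimating the trace to 1 kHz (the band tops out at
150 Hz; decimation only removes out-of-band noise and makes the
transform cheap). Two numerical corrections to the PyWavelets backend
matter: the scalogram uses L1-normalised magnitude (the default
√scale L2 factor biases a pure tone's ridge maximum low by ~2.5%
relative), and the scale→frequency map uses the analytic centre
frequency ω₀/2π (the library's numerical estimate is quantised by its
FFT grid).

Candidate extraction is iterative with a relaxed (amplitude-free)
threshold: find the global scalogram maximum among usable bins, track
the per-column maximum outward under the 30 Hz/ms continuity limit, and
take as the candidate epoch the contiguous span around the maximum where
the instantaneous frequency stays within 20% of the ridge-maximum
frequency **and** the magnitude stays above half the ridge maximum. The
half-maximum rule, together with the ≥ 2-period rule and the fit-quality
gate below, is the package's automated stand-in for the original
semi-automated visual confirmation: without it, wavelet temporal
smearing extends candidate durations about one period beyond each true
epoch edge. Usability is masked by a frequency-dependent
cone-of-influence guard (2/f seconds from trace and analysis-window
boundaries) so broadband step-onset transients cannot seed ridges; each
claimed temporal epoch is excluded from later iterations (at most one
confirmed STO per epoch).

Each surviving candidate is fit with a sinusoid of fixed amplitude
(= segment SD), offset (= segment mean) and frequency (= ridge maximum);
only the phase is free and has a closed form. Fixing the amplitude at
the SD caps r² at 1 − (1 − 1/√2)² ≈ 0.914 even for a perfect sinusoid.
The confirmation gate is r² ≥ 0.70 — a free parameter of the automated
stand-in, placed between the measured distributions of programmed STOs
at SNR ≥ 3 (r² 0.84–0.87) and of band-limited noise candidates
(r² ≤ 0.60); the shipped default is surfaced in `AnalysisConfig`.

Phase convention: cosine with 0 at the STO peak, reported in (−π, π], so
spikes "just before the peak" map to small negative phases. Post-STO
spikes (within 2 periods of the STO end) receive phases extrapolated
from the last fitted peak; their instantaneous rates over the STO
frequency give the per-cell rate:STO ratio. A cell is resonant iff ≥ 10
confirmed STOs accumulate across the ten-step (50–500 pA) protocol.

## Statistics

Prevalence comparisons use Pearson's chi-squared on 2×2 tables without
continuity correction (required to match the worked examples; expected
counts must be positive). The Rayleigh test uses the standard
small-sample-corrected p approximation
exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)); Watson–Williams uses the
circular one-way F with the 1 + 3/(8κ̂) correction and flags pooled mean
resultant lengths below 0.45. BH adjustment is the step-up procedure
with enforced monotonicity (delegated to statsmodels; note it is *not*
idempotent on arbitrary monotone inputs — only all-equal sets are fixed
points). Standard group tests (rank-sum, KS, t, ANOVA) are deliberately
left to scipy/statsmodels.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes:
5 Hz phasic envelopes gating gamma oscillators with per-cycle Bernoulli
participation and Gaussian spike jitter; decelerating frequency chirps
(90→50 Hz over the 150 ms active span, −0.267 Hz/ms); per-cycle random
oscillator phase shared by both cells (network gamma is coherent within
trials but not stimulus-locked — stimulus-locked phase would put gamma
into the PSTH and hence into the rate-matched surrogates); IPSC barrages
as amplitude-scaled biexponentials plus white noise (rendered with their
full ~19 ms decay tail, not the abridged 4 ms detection template); and
step responses with cosine STO epochs (one-period cosine edge ramps) and
2 ms triangular spikes.

They do **not** emulate bursting, adaptation, cross-frequency coupling,
correlated (non-white) noise, electrode artifacts, or biophysical
phase-resetting dynamics. Passing tests therefore demonstrate that the
*analysis chain* recovers programmed structure and stays calibrated on
its own null — not that real recordings satisfy the generators'
assumptions.

Default problem sizes for the validation battery (10-trial pairs, 1.2 s
records, 50-seed sweeps, 2000-simulation calibrations) were chosen so
that sampling error sits well inside each check's tolerance while the
whole battery remains a couple of minutes of compute.

## Known limitations

- The frequency grid of the spike-CPSD analysis is 10 Hz; ridge
  frequencies inherit that quantisation.
- Short-epoch scalogram maxima have a small upward frequency tilt that
  grows with frequency (constant-Q kernels widen with f); at the 45 Hz
  validation condition it is within one 1 Hz grid step, at 120 Hz it can
  reach a few Hz.
- The IPSC criterion threshold (3.0) and the STO r² gate (0.70) are
  calibrated on the synthetic conditions; new preparations should check
  them against their own noise (both are exposed in `AnalysisConfig`).
- `read_event_table` requires durations/protocols from the caller or a
  sidecar; the event table format itself carries only times.
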
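"""Welch auto-/cross-power spectral density spectrograms.

Convolved event trains (or mean-subtracted current traces) are analysed in
sliding 100 ms Hamming windows with 95% overlap (5 ms hop), giving 10 Hz
frequency resolution at 5 ms time resolution.  Per trial and window the
cross-spectrum S12(f) = F{w*s_a} * conj(F{w*s_b}) is formed and its
magnitude averaged across trials; magnitude is taken before trial
averaging so within-trial synchrony survives cross-trial phase
variability.  The auto-spectrogram (APSD) is the same computation with a
train against itself, |S11| = |F{w*s}|^2.

The protocol-averaged spectrum (time-independent analyses) is the time
mean of the spectrogram, which coincides with Welch's segment-averaged
estimate.  Theta-band (2-12 Hz) analyses need finer frequency resolution
than a 100 ms window allows; ``theta=True`` switches to a 500 ms window
(2 Hz resolution) at the same overlap fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hamming

from .core_events import DEFAULT_FS, PairRecording, ProtocolConfig, TrialSet, convolve_events

__all__ = ["Spectrogram", "cpsd_spectrogram", "apsd_spectrogram",
           "band_average", "cycle_average", "trace_cpsd_spectrogram"]

THETA_WINDOW = 0.500
GAMMA_BAND = (40.0, 200.0)
THETA_BAND = (2.0, 12.0)


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency power matrix from sliding-window cross/auto spectra."""

    times: np.ndarray  # window centers, s (0 = photostimulation onset)
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_freqs, n_times), >= 0
    kind: str = "CPSD"  # CPSD | APSD
    n_trials: int = 1

    def __post_init__(self):
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power must be (n_freqs, n_times)")

    @property
    def hop(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan

    def band(self, f_lo: float, f_hi: float) -> "Spectrogram":
        """Restrict to an inclusive frequency band."""
        m = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not m.any():
            raise ValueError("band does not intersect the frequency grid")
        return replace(self, freqs=self.freqs[m], power=self.power[m])

    def time_mean(self) -> np.ndarray:
        """Protocol-averaged spectrum (Welch estimate): mean over windows."""
        return self.power.mean(axis=1)


def _windowed_ffts(x: np.ndarray, fs: float, window: float, overlap: float):
    """Sliding-window Hamming-tapered rFFTs: (frames x freqs), centers, freqs."""
    n_win = int(round(window * fs))
    if n_win > x.size:
        raise ValueError("window longer than the record")
    hop = max(int(round(n_win * (1.0 - overlap))), 1)
    taper = hamming(n_win, sym=False)
    frames = sliding_window_view(x, n_win)[::hop]
    spec = np.fft.rfft(frames * taper, axis=1)
    # Welch density scaling; a constant factor, irrelevant to thresholds
    spec = spec / np.sqrt(fs * (taper ** 2).sum())
    centers = (np.arange(frames.shape[0]) * hop + (n_win - 1) / 2.0) / fs
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    return spec, centers, freqs


def _pair_spectrogram(sig_pairs, fs, window, overlap, t_offset, kind, n_trials):
    power = None
    for sa, sb in sig_pairs:
        fa, centers, freqs = _windowed_ffts(sa, fs, window, overlap)
        fb = fa if sb is sa else _windowed_ffts(sb, fs, window, overlap)[0]
        cross = np.abs(fa * np.conj(fb)).T  # (freqs, times)
        power = cross if power is None else power + cross
    return Spectrogram(centers + t_offset, freqs, power / n_trials,
                       kind=kind, n_trials=n_trials)


def cpsd_spectrogram(
    pair: PairRecording,
    window: float = 0.100,
    overlap: float = 0.95,
    fs: float = DEFAULT_FS,
    sigma: float = 0.001,
    t_reference: float | None = None,
    theta: bool = False,
) -> Spectrogram:
    """Trial-averaged spike-time CPSD spectrogram of a pair.

    Times are window centers relative to photostimulation onset
    (``t_reference``; defaults to the protocol's first pulse).
    """
    if theta:
        window = THETA_WINDOW
    if t_reference is None:
        t_reference = pair.protocol.stim_onsets[0]

    def gen():
        for tr_a, tr_b in zip(pair.cell_a.trains, pair.cell_b.trains):
            sa = convolve_events(tr_a, fs=fs, sigma=sigma, mean_subtract=True)
            sb = convolve_events(tr_b, fs=fs, sigma=sigma, mean_subtract=True)
            yield sa.samples, sb.samples

    return _pair_spectrogram(gen(), fs, window, overlap, -t_reference,
                             "CPSD", pair.n_trials)


def apsd_spectrogram(
    trials: TrialSet,
    window: float = 0.100,
    overlap: float = 0.95,
    fs: float = DEFAULT_FS,
    sigma: float = 0.001,
    t_reference: float | None = None,
    theta: bool = False,
) -> Spectrogram:
    """Trial-averaged spike-time APSD spectrogram (periodic firing measure)."""
    if theta:
        window = THETA_WINDOW
    if t_reference is None:
        t_reference = trials.protocol.stim_onsets[0]

    def gen():
        for tr in trials.trains:
            s = convolve_events(tr, fs=fs, sigma=sigma, mean_subtract=True).samples
            yield s, s

    sg = _pair_spectrogram(gen(), fs, window, overlap, -t_reference,
                           "APSD", trials.n_trials)
    return sg


def trace_cpsd_spectrogram(
    traces_a, traces_b, fs: float,
    window: float = 0.100, overlap: float = 0.95,
    t_reference: float = 0.0, kind: str = "CPSD",
) -> Spectrogram:
    """CPSD spectrogram of raw sampled traces (e.g. currents), mean-subtracted.

    Reuses the spike-time machinery with traces in place of convolved
    trains; used e.g. to show excitatory input devoid of gamma patterning.
    """
    traces_a = [np.asarray(t, dtype=float) for t in traces_a]
    traces_b = [np.asarray(t, dtype=float) for t in traces_b]

    def gen():
        for a, b in zip(traces_a, traces_b):
            yield a - a.mean(), b - b.mean()

    return _pair_spectrogram(gen(), fs, window, overlap, -t_reference,
                             kind, len(traces_a))


def band_average(sg: Spectrogram, f_lo: float, f_hi: float,
                 t_window=None) -> float:
    """Mean power over an inclusive frequency band and time window."""
    sub = sg.band(f_lo, f_hi)
    if t_window is None:
        m = np.ones(sub.times.size, dtype=bool)
    else:
        m = (sub.times >= t_window[0]) & (sub.times <= t_window[1])
        if not m.any():
            raise ValueError("time window does not intersect the spectrogram")
    return float(sub.power[:, m].mean())


def cycle_average(sg: Spectrogram, protocol: ProtocolConfig) -> Spectrogram:
    """Average the spectrogram across aligned photostimulation cycles.

    Output time axis spans [0, cycle_period) relative to cycle onset.
    Requires at least two complete cycles inside the spectrogram.
    """
    hop = sg.hop
    period = protocol.cycle_period
    n_bins = int(round(period / hop))
    onsets = [t - protocol.stim_onsets[0] for t in protocol.stim_onsets]
    acc = np.zeros((sg.freqs.size, n_bins))
    count = np.zeros(n_bins)
    complete = 0
    for onset in onsets:
        i0 = int(np.searchsorted(sg.times, onset - hop / 2))
        if i0 + n_bins > sg.times.size:
            continue
        acc += sg.power[:, i0:i0 + n_bins]
        count += 1
        complete += 1
    if complete < 2:
        raise ValueError("need >= 2 complete cycles to average")
    times = np.arange(n_bins) * hop
    return Spectrogram(times, sg.freqs, acc / count, kind=sg.kind,
                       n_trials=sg.n_trials)
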
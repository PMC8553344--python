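"""Detection and summarisation of spectrogram ridges.

A *ridge* is a temporally continuous supra-threshold track in a CPSD or
APSD spectrogram, interpreted as an epoch of robust periodic synchrony
(CPSD) or periodic firing (APSD).  The detection threshold is the 95th
percentile of 40-200 Hz power values pooled over the whole
photostimulation protocol across all pairs/cells of a dataset (symbols in
the analysis: xi for spike CPSD, lambda for APSD, zeta for IPSC CPSD).

Tracking is greedy and maximal: per time bin the band-limited
supra-threshold local maxima are located; a ridge is seeded at the global
maximum and extended bidirectionally, following the nearest
supra-threshold local maximum while the per-step frequency jump stays
below the continuity limit (150 Hz/ms, permissive at a 5 ms hop, so
segmentation is primarily threshold-driven); claimed bins are removed and
the procedure repeats.  Ridges shorter than ``min_bins`` are discarded.
Ties between equidistant candidate maxima are broken toward the lower
frequency (gamma-deceleration prior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_events import PairRecording, ProtocolConfig, sequential_rates
from .spectral import GAMMA_BAND, Spectrogram

__all__ = ["RidgeThreshold", "Ridge", "ridge_threshold", "detect_ridges",
           "ridge_summary", "rate_vs_ridge"]

CONTINUITY_HZ_PER_MS = 150.0
MIN_BINS = 2


@dataclass(frozen=True)
class RidgeThreshold:
    """Dataset-pooled percentile threshold for ridge detection."""

    value: float
    percentile: float = 95.0
    band: tuple = GAMMA_BAND
    scope: str = ""
    symbol: str = "xi"  # xi: spike CPSD, lambda: APSD, zeta: IPSC CPSD


@dataclass(frozen=True)
class Ridge:
    """A contiguous time-frequency track of supra-threshold power."""

    times: np.ndarray
    freqs: np.ndarray
    powers: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def mean_freq(self) -> float:
        return float(self.freqs.mean())

    @property
    def mean_power(self) -> float:
        return float(self.powers.mean())

    @property
    def slope_hz_per_ms(self) -> float:
        """Least-squares slope of frequency vs time; negative = deceleration."""
        return self.slope()

    def slope(self, edge_trim: float = 0.0) -> float:
        """Least-squares frequency-vs-time slope in Hz/ms.

        ``edge_trim`` (seconds) drops bins within that span of either ridge
        end before fitting.  Spectrogram windows that straddle an epoch
        boundary average a truncated chirp, so the ridge plateaus over
        roughly half a Welch window at each end; trimming half a window
        restricts the fit to bins whose estimate reflects the full local
        chirp.  Falls back to the untrimmed fit when fewer than 4 bins
        survive.
        """
        if self.times.size < 2:
            return 0.0
        t, f = self.times, self.freqs
        if edge_trim > 0:
            m = (t >= t[0] + edge_trim) & (t <= t[-1] - edge_trim)
            if m.sum() >= 4:
                t, f = t[m], f[m]
        slope = np.polyfit(t, f, 1)[0]
        return float(slope / 1000.0)


def ridge_threshold(
    spectrograms,
    band: tuple = GAMMA_BAND,
    percentile: float = 95.0,
    scope: str = "",
    symbol: str = "xi",
) -> RidgeThreshold:
    """Pooled percentile of band-limited power across a dataset.

    All time bins of all (trial-averaged) spectrograms contribute; by
    construction ~ (100 - percentile)% of pooled band values exceed the
    returned threshold.
    """
    pool = []
    for sg in spectrograms:
        pool.append(sg.band(*band).power.ravel())
    if not pool:
        raise ValueError("empty spectrogram collection")
    value = float(np.percentile(np.concatenate(pool), percentile))
    return RidgeThreshold(value, percentile, band, scope, symbol)


def _local_maxima_by_time(power: np.ndarray, thr: float):
    """Per time bin, row indices of supra-threshold local maxima in frequency."""
    n_f, n_t = power.shape
    out = []
    for j in range(n_t):
        col = power[:, j]
        idx = [i for i in range(n_f)
               if col[i] >= thr
               and (i == 0 or col[i] >= col[i - 1])
               and (i == n_f - 1 or col[i] > col[i + 1])]
        out.append(idx)
    return out


def detect_ridges(
    sg: Spectrogram,
    thr: RidgeThreshold,
    continuity: float = CONTINUITY_HZ_PER_MS,
    band: tuple = GAMMA_BAND,
    min_bins: int = MIN_BINS,
) -> list:
    """Greedy maximal-ridge tracking on a band-limited spectrogram.

    Returns ridges sorted by descending peak power.  An empty list is a
    valid result (all power sub-threshold).
    """
    sub = sg.band(*band)
    power = sub.power.copy()
    freqs, times = sub.freqs, sub.times
    hop_ms = (times[1] - times[0]) * 1000.0 if times.size > 1 else np.inf
    max_jump = continuity * hop_ms  # Hz allowed per consecutive-bin step

    maxima = _local_maxima_by_time(power, thr.value)
    claimed = np.zeros_like(power, dtype=bool)
    ridges = []

    def _available(j):
        return [i for i in maxima[j] if not claimed[i, j]]

    while True:
        # seed: global maximum among unclaimed supra-threshold local maxima
        best = None
        for j in range(times.size):
            for i in _available(j):
                if best is None or power[i, j] > power[best[0], best[1]]:
                    best = (i, j)
        if best is None:
            break
        i0, j0 = best
        track = {j0: i0}
        for step in (+1, -1):  # extend forward then backward
            i_prev, j = i0, j0
            while 0 <= j + step < times.size:
                j += step
                cands = [i for i in _available(j)
                         if abs(freqs[i] - freqs[i_prev]) <= max_jump]
                if not cands:
                    break
                # nearest in frequency; ties toward the lower frequency
                i_next = min(cands, key=lambda i: (abs(freqs[i] - freqs[i_prev]),
                                                   freqs[i]))
                track[j] = i_next
                i_prev = i_next
        cols = sorted(track)
        for j in cols:
            claimed[track[j], j] = True
        if len(cols) >= min_bins:
            ridges.append(Ridge(
                times=np.array([times[j] for j in cols]),
                freqs=np.array([freqs[track[j]] for j in cols]),
                powers=np.array([power[track[j], j] for j in cols]),
            ))
    ridges.sort(key=lambda r: -r.powers.max())
    return ridges


def ridge_summary(ridge_sets, protocol: ProtocolConfig,
                  sub_window: float = 0.050,
                  slope_edge_trim: float = 0.050) -> dict:
    """Dataset-level ridge distributions and cycle occupancy.

    Parameters
    ----------
    ridge_sets : list of list of Ridge
        One ridge list per pair (or cell).

    Returns pooled per-bin frequency and power values (for CDFs), per-ridge
    least-squares slopes (Hz/ms), the fraction of pairs with >= 1 ridge,
    and occupancy: the fraction of pairs with >= 1 ridge bin inside each
    ``sub_window`` (default 50 ms) sub-window of the average cycle.
    """
    freqs, powers, slopes = [], [], []
    n_with = 0
    n_sub = int(round(protocol.cycle_period / sub_window))
    occupancy_counts = np.zeros(n_sub)
    for ridges in ridge_sets:
        if ridges:
            n_with += 1
        occupied = np.zeros(n_sub, dtype=bool)
        for r in ridges:
            freqs.append(r.freqs)
            powers.append(r.powers)
            slopes.append(r.slope(slope_edge_trim))
            # spectrogram times are relative to photostimulation onset
            phase = np.mod(r.times, protocol.cycle_period)
            for w in (phase // sub_window).astype(int):
                if 0 <= w < n_sub:
                    occupied[w] = True
        occupancy_counts += occupied
    n_pairs = max(len(ridge_sets), 1)
    return {
        "freqs": np.concatenate(freqs) if freqs else np.array([]),
        "powers": np.concatenate(powers) if powers else np.array([]),
        "slopes_hz_per_ms": np.asarray(slopes),
        "fraction_with_ridge": n_with / n_pairs,
        "occupancy": occupancy_counts / n_pairs,
        "n_pairs": len(ridge_sets),
        "n_with_ridge": n_with,
    }


def rate_vs_ridge(pair: PairRecording, ridges, hop_tol: float | None = None) -> dict:
    """Instantaneous firing rate against simultaneous ridge frequency.

    For each ISI whose later spike falls inside a ridge's time span, the
    rate 1/ISI is paired with the ridge frequency at the nearest time bin.
    The per-cell ratio mean(rate / frequency) approaches 1 for dense
    (one-spike-per-cycle) synchrony and 0.5 when cells fire every other
    oscillation cycle.
    """
    out = {}
    for name, trials in (("cell_a", pair.cell_a), ("cell_b", pair.cell_b)):
        rates, freqs = [], []
        for tr in trials.trains:
            ts, rs = sequential_rates(tr)
            for t, rate in zip(ts, rs):
                for r in ridges:
                    if r.times[0] <= t <= r.times[-1]:
                        k = int(np.argmin(np.abs(r.times - t)))
                        rates.append(rate)
                        freqs.append(r.freqs[k])
                        break
        rates, freqs = np.asarray(rates), np.asarray(freqs)
        ratios = rates / freqs if rates.size else np.array([])
        out[name] = {
            "rates": rates,
            "ridge_freqs": freqs,
            "ratios": ratios,
            "mean_ratio": float(ratios.mean()) if ratios.size else float("nan"),
        }
    return out
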
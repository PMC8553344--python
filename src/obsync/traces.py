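"""Scalar analytics on current/voltage traces.

Input latency, charge transfer, unitary (spike-triggered) response
amplitude and electrical coupling coefficients.  All operations are
invariant to constant offsets of the input traces and, where meaningful,
linear in trace scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["TraceWindowSpec", "onset_latency", "charge_transfer",
           "unitary_amplitude", "coupling_coefficient"]


@dataclass(frozen=True)
class TraceWindowSpec:
    """Baseline and response windows (seconds) with a polarity convention."""

    baseline: tuple
    response: tuple
    polarity: str = "inward"  # inward | outward | depolarizing | hyperpolarizing

    def __post_init__(self):
        if self.baseline[1] > self.response[0]:
            raise ValueError("baseline must precede (not overlap) the response")


def _win(trace, fs, window):
    i0, i1 = (int(round(b * fs)) for b in window)
    return trace[i0:i1]


def onset_latency(
    traces,
    fs: float,
    spec: TraceWindowSpec,
    k_sd: float = 2.0,
) -> float | None:
    """Latency to input onset after photostimulation.

    The first time in the response window at which the trial-mean
    baseline-subtracted current deviates below -k_sd x baseline SD
    (inward-negative convention).  Returns None when the threshold is
    never crossed.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    mean_trace = traces.mean(axis=0)
    base = _win(mean_trace, fs, spec.baseline)
    if base.size / fs < 0.020 - 1e-9:
        raise ValueError("baseline must span at least 20 ms")
    # noise scale of a single sweep: trial-mean of per-trial baseline SDs
    # (the SD of the averaged trace shrinks with trial count and would let
    # chance fluctuations of the mean cross the threshold)
    sd = float(np.mean([_win(tr, fs, spec.baseline).std() for tr in traces]))
    if sd == 0:
        raise ValueError("zero baseline SD")
    centered = mean_trace - base.mean()
    i0, i1 = (int(round(b * fs)) for b in spec.response)
    below = np.flatnonzero(centered[i0:i1] < -k_sd * sd)
    if below.size == 0:
        return None
    return (i0 + below[0]) / fs


def charge_transfer(trace, fs: float, spec: TraceWindowSpec) -> float:
    """Integral of the baseline-subtracted current over the response window.

    With current in amperes the result is coulombs; sign follows the
    recorded polarity (no rectification).
    """
    trace = np.asarray(trace, dtype=float)
    base_mean = _win(trace, fs, spec.baseline).mean()
    resp = _win(trace, fs, spec.response)
    return float((resp - base_mean).sum() / fs)


def _spike_crossing_time(trace, fs, threshold=-0.040, upsample_fs=1e6):
    """First upward threshold crossing, localised on a cubic 1 MHz upsample."""
    trace = np.asarray(trace, dtype=float)
    above = trace >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return None
    i = idx[0]
    lo, hi = max(i - 3, 0), min(i + 5, trace.size)
    t = np.arange(lo, hi) / fs
    cs = CubicSpline(t, trace[lo:hi])
    tt = np.arange(t[0], t[-1], 1.0 / upsample_fs)
    vv = cs(tt)
    j = np.flatnonzero(vv >= threshold)
    return float(tt[j[0]]) if j.size else i / fs


def unitary_amplitude(
    post_traces,
    pre_traces,
    fs: float,
    window: float = 0.015,
    baseline: float = 0.005,
    spike_threshold: float = -0.040,
) -> float:
    """Unitary postsynaptic response amplitude (same units as the traces).

    Trials are aligned on presynaptic spike times localised as -40 mV
    crossings on a cubic-interpolated 1 MHz upsample; the amplitude is the
    maximum of the trial-mean baseline-subtracted postsynaptic potential
    within (0, window] after the spike.  Trials without a detectable
    presynaptic spike are excluded.
    """
    aligned = []
    n_pre = int(round(baseline * fs))
    n_post = int(round(window * fs))
    for pre, post in zip(pre_traces, post_traces):
        t_spike = _spike_crossing_time(pre, fs, spike_threshold)
        if t_spike is None:
            continue
        i = int(round(t_spike * fs))
        if i - n_pre < 0 or i + n_post + 1 > len(post):
            continue
        post = np.asarray(post, dtype=float)
        snippet = post[i - n_pre: i + n_post + 1]
        aligned.append(snippet - snippet[:n_pre].mean())
    if not aligned:
        raise ValueError("no trial contained a detectable presynaptic spike")
    mean = np.mean(aligned, axis=0)
    return float(mean[n_pre + 1:].max())


def coupling_coefficient(
    pre_traces,
    post_traces,
    fs: float,
    step_window: tuple,
    baseline_window: tuple | None = None,
    noise_floor: float = 1e-4,
) -> float:
    """Electrical coupling coefficient dV_post / dV_pre.

    Each deflection is the steady-state mean (last 20% of the
    hyperpolarizing step) minus the pre-step baseline mean, trial-averaged
    before the ratio.  Raises when the presynaptic deflection is below the
    noise floor.
    """
    t0, t1 = step_window
    ss_window = (t1 - 0.2 * (t1 - t0), t1)
    if baseline_window is None:
        baseline_window = (max(t0 - 0.05, 0.0), t0)

    def _delta(traces):
        traces = np.atleast_2d(np.asarray(traces, dtype=float))
        deltas = [_win(tr, fs, ss_window).mean() - _win(tr, fs, baseline_window).mean()
                  for tr in traces]
        return float(np.mean(deltas))

    dv_pre = _delta(pre_traces)
    if abs(dv_pre) < noise_floor:
        raise ValueError("presynaptic deflection below the noise floor")
    return _delta(post_traces) / dv_pre
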
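"""IPSC template matching, kinetics and synchrony decomposition."""

import numpy as np
import pytest
from scipy.optimize import brentq

from obsync.ipsc_detect import (
    IpscTemplate,
    detect_ipscs,
    f_synch_curve,
    ipsc_kinetics,
    synchrony_decomposition,
)
from obsync.synth import ipsc_trace

FS = 10_000.0


def analytic_rise_20_80_ms(tpl: IpscTemplate) -> float:
    """Root-finding oracle for the 20-80% rise of the biexponential."""
    peak = tpl.peak_value()
    f = lambda t: ((1 - np.exp(-t / tpl.tau_rise))
                   * np.exp(-t / tpl.tau_decay) / peak)
    t_peak = tpl.time_to_peak - tpl.baseline
    t20 = brentq(lambda t: f(t) - 0.2, 1e-9, t_peak)
    t80 = brentq(lambda t: f(t) - 0.8, 1e-9, t_peak)
    return (t80 - t20) * 1000.0


def make_events(seed, n, duration, min_sep=0.01):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.1, duration - 0.1, n))
    return t[np.concatenate(([True], np.diff(t) > min_sep))]


class TestDetectIpscs:
    def test_high_snr_recall_precision(self):
        """20 events at 10x noise SD: recall/precision >= 0.95, |dt|<=0.5 ms."""
        hits = fps = tot = 0
        for seed in range(5):
            times = make_events(seed, 20, 5.0)
            tr, _ = ipsc_trace(times, 50.0, noise_sd=5.0, fs=FS,
                               duration=5.0, seed=100 + seed)
            det = np.array([e.time for e in
                            detect_ipscs(tr, FS, baseline_window=(0, 0.05))])
            tol = 0.0005
            hits += sum(det.size and np.min(np.abs(det - t)) <= tol
                        for t in times)
            fps += sum(np.min(np.abs(times - d)) > tol for d in det)
            tot += times.size
        assert hits / tot >= 0.95
        assert hits / (hits + fps) >= 0.95

    def test_pure_noise_false_positive_rate(self):
        """<= 1 false positive per 10 s of pure noise at default criterion."""
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tr = rng.normal(0, 5.0, int(10 * FS))
            counts.append(len(detect_ipscs(tr, FS,
                                           baseline_window=(0, 0.05))))
        assert np.mean(counts) <= 1.0

    def test_min_separation_merges(self):
        tr, _ = ipsc_trace([0.05, 0.0503], 50.0, noise_sd=0.0, fs=FS,
                           duration=0.2)
        ev = detect_ipscs(tr, FS, noise_sd=1.0)
        assert len(ev) == 1

    def test_amplitude_recovery(self):
        """Fitted scale within 5% of truth at SNR >= 5."""
        times = make_events(3, 15, 4.0)
        tr, _ = ipsc_trace(times, 40.0, noise_sd=4.0, fs=FS, duration=4.0,
                           seed=9)
        ev = detect_ipscs(tr, FS, baseline_window=(0, 0.05))
        amps = np.array([e.amplitude for e in ev])
        assert abs(np.median(amps) - 40.0) / 40.0 < 0.05

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_ipscs(np.zeros(10), FS)


class TestIpscKinetics:
    def test_noiseless_rise_matches_oracle(self):
        times = np.arange(0.05, 0.5, 0.05)
        tr, _ = ipsc_trace(times, 50.0, noise_sd=0.0, fs=FS, duration=0.6)
        ev = detect_ipscs(tr, FS, noise_sd=1.0)
        kin = ipsc_kinetics(ev, tr, FS)
        expected = analytic_rise_20_80_ms(IpscTemplate())
        assert expected == pytest.approx(0.308, abs=0.002)  # frozen oracle
        assert np.median(kin["rise_20_80_ms"]) == pytest.approx(expected,
                                                                abs=0.1)

    def test_decay_tau_round_trip(self):
        """Median-waveform single-exponential fit recovers tau = 3 ms +/-5%."""
        times = make_events(1, 40, 8.0, min_sep=0.03)
        tr, _ = ipsc_trace(times, 60.0, noise_sd=3.0, fs=FS, duration=8.0,
                           seed=4)
        ev = detect_ipscs(tr, FS, baseline_window=(0, 0.05))
        kin = ipsc_kinetics(ev, tr, FS)
        assert kin["decay_tau_s"] == pytest.approx(0.003, rel=0.05)

    def test_too_few_events_flagged(self):
        tr, _ = ipsc_trace([0.05, 0.15], 50.0, noise_sd=0.0, fs=FS,
                           duration=0.3)
        ev = detect_ipscs(tr, FS, noise_sd=1.0)
        kin = ipsc_kinetics(ev, tr, FS)
        assert np.isnan(kin["decay_tau_s"])


class TestSynchronyDecomposition:
    def test_identical_lists_all_synchronous(self):
        t = np.linspace(0.1, 0.9, 20)
        out = synchrony_decomposition(t, t, w_ms=1.0)
        assert out["sync_fraction"] == 1.0
        assert out["rates_a"]["asynchronous"].size == 0

    def test_offset_lists_all_asynchronous(self):
        t = np.linspace(0.1, 0.9, 20)
        out = synchrony_decomposition(t, t + 0.005, w_ms=1.0)
        assert out["sync_fraction"] == 0.0

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(0, 1, 50))
        b = np.sort(rng.uniform(0, 1, 60))
        ab = synchrony_decomposition(a, b, 1.0)
        ba = synchrony_decomposition(b, a, 1.0)
        np.testing.assert_array_equal(ab["sync_mask_a"], ba["sync_mask_b"])
        assert ab["sync_fraction"] == ba["sync_fraction"]

    def test_independent_poisson_matches_analytic(self):
        """Independent 50 Hz trains: P(partner within +/-1 ms) ~ 1-e^(-2rw)."""
        rng = np.random.default_rng(8)
        r, w = 50.0, 0.001
        a = np.cumsum(rng.exponential(1 / r, 20_000))
        b = np.cumsum(rng.exponential(1 / r, 20_000))
        out = synchrony_decomposition(a[a < 300], b[b < 300], w_ms=1.0)
        expected = 1 - np.exp(-2 * r * w)
        assert out["sync_fraction"] == pytest.approx(expected, abs=0.01)


class TestFSynchCurve:
    def test_identical_lists_unity(self):
        t = np.linspace(0.1, 0.9, 15)
        curve = f_synch_curve(t, t)
        np.testing.assert_allclose(curve.f_synch, 1.0)

    def test_monotone_in_window(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.uniform(0, 2, 200))
        b = np.sort(rng.uniform(0, 2, 180))
        curve = f_synch_curve(a, b)
        assert np.all(np.diff(curve.f_synch) >= 0)

    def test_poisson_tracks_analytic_within_ci(self):
        rng = np.random.default_rng(5)
        r = 40.0
        a = np.cumsum(rng.exponential(1 / r, 8000))
        b = np.cumsum(rng.exponential(1 / r, 8000))
        T = min(a[-1], b[-1])
        curve = f_synch_curve(a[a < T], b[b < T])
        n = 2 * 8000
        for w_ms, f in zip(curve.w_grid_ms, curve.f_synch):
            p = 1 - np.exp(-2 * r * w_ms / 1000.0)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(f - p) < 4 * se + 0.005
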
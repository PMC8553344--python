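"""Subthreshold-oscillation pipeline: interpolation, CWT, detection, phases."""

import numpy as np
import pytest

from obsync.sto import (
    SubthresholdTrace,
    classify_resonant,
    detect_stos,
    fit_sto_sinusoid,
    interpolate_spikes,
    morlet_cwt,
    sto_spike_metrics,
)
from obsync.synth import sto_trace

FS = 10_000.0
STEP_WINDOW = (0.2, 1.8)


def detect(vm, **kw):
    kw.setdefault("analysis_window", STEP_WINDOW)
    return detect_stos(SubthresholdTrace(vm, FS), **kw)


class TestInterpolateSpikes:
    def test_no_spikes_unchanged(self):
        vm = np.full(1000, -55.0)
        out = interpolate_spikes(vm, FS, [])
        np.testing.assert_array_equal(out.vm, vm)

    def test_spike_on_flat_baseline_removed(self):
        vm, _ = sto_trace(sto_epochs=(), spike_times=[1.0], noise_sd=0.0)
        out = interpolate_spikes(vm, FS, [1.0])
        seg = out.vm[int(0.9 * FS): int(1.1 * FS)]
        assert np.ptp(seg) < 0.01

    def test_cwt_peak_preserved_after_interpolation(self):
        """Spike riding a 40 Hz oscillation: CWT peak still at 40 +/- 2 Hz."""
        vm, _ = sto_trace(sto_freq=40.0, sto_amp=1.5,
                          sto_epochs=((0.8, 1.3),), spike_times=[1.05],
                          noise_sd=0.0)
        out = interpolate_spikes(vm, FS, [1.05])
        assert not np.any(out.vm > 0)  # spike excursion gone
        times, freqs, mag = morlet_cwt(out)
        sel = (times > 0.9) & (times < 1.2)
        prof = mag[:, sel].mean(axis=1)
        assert abs(freqs[np.argmax(prof)] - 40.0) <= 2.0

    def test_overlapping_spans_merged(self):
        vm, _ = sto_trace(sto_epochs=(), spike_times=[1.0, 1.0015],
                          noise_sd=0.0)
        out = interpolate_spikes(vm, FS, [1.0, 1.0015])
        assert len(out.interpolated_spans) == 1


class TestMorletCwt:
    def test_pure_tone_peak(self):
        t = np.arange(int(4 * FS)) / FS
        trace = SubthresholdTrace(np.cos(2 * np.pi * 40.0 * t), FS)
        times, freqs, mag = morlet_cwt(trace)
        prof = mag[:, mag.shape[1] // 4: -mag.shape[1] // 4].mean(axis=1)
        assert abs(freqs[np.argmax(prof)] - 40.0) <= 1.0

    def test_linearity_in_amplitude(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.cos(2 * np.pi * 60.0 * t)
        _, _, m1 = morlet_cwt(SubthresholdTrace(x, FS))
        _, _, m2 = morlet_cwt(SubthresholdTrace(2 * x, FS))
        mid = m1.shape[1] // 2
        assert m2[:, mid] == pytest.approx(2 * m1[:, mid], rel=1e-6)

    def test_white_noise_argmax_unstable(self):
        """White noise has no persistently dominant frequency bin: the
        longest single-bin winning streak of the scalogram argmax stays a
        small fraction of the record (20 seeds)."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trace = SubthresholdTrace(rng.normal(0, 1, int(1.0 * FS)), FS)
            times, freqs, mag = morlet_cwt(trace)
            guard = 150
            win = np.argmax(mag[:, guard:-guard], axis=0)
            longest, cur, prev = 0, 0, -1
            for w in win:
                cur = cur + 1 if w == prev else 1
                prev = w
                longest = max(longest, cur)
            assert longest < 0.3 * win.size

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            morlet_cwt(SubthresholdTrace(np.zeros(int(0.1 * FS)), FS))


class TestFitStoSinusoid:
    @pytest.mark.parametrize("phi0", [-2.0, -0.5, 0.0, 1.0, 2.5])
    def test_phase_round_trip(self, phi0):
        fs, f = 1000.0, 37.0
        t = np.arange(200) / fs
        seg = -52.0 + 1.3 * np.cos(2 * np.pi * f * t + phi0)
        phase, amp, offset, r2 = fit_sto_sinusoid(seg, fs, f)
        err = np.degrees(np.angle(np.exp(1j * (phase - phi0))))
        assert abs(err) < 5.0
        assert offset == pytest.approx(-52.0, abs=0.05)

    def test_phase_offset_invariant(self):
        fs, f = 1000.0, 50.0
        t = np.arange(100) / fs
        seg = np.cos(2 * np.pi * f * t + 0.7)
        p1 = fit_sto_sinusoid(seg, fs, f)[0]
        p2 = fit_sto_sinusoid(seg + 40.0, fs, f)[0]
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_amplitude_is_sd_systematic(self):
        """The recipe fixes amplitude = SD = A/sqrt(2) for a pure sinusoid."""
        fs, f, A = 1000.0, 40.0, 2.0
        t = np.arange(500) / fs
        seg = A * np.cos(2 * np.pi * f * t)
        _, amp, _, r2 = fit_sto_sinusoid(seg, fs, f)
        assert amp == pytest.approx(A / np.sqrt(2), rel=0.01)
        # consequent r2 ceiling: 1 - (1 - 1/sqrt(2))^2 ~ 0.914
        assert r2 == pytest.approx(1 - (1 - 2 ** -0.5) ** 2, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_sto_sinusoid(np.zeros(100), 1000.0, 40.0)


class TestDetectStos:
    def test_round_trip_45hz(self):
        vm, _ = sto_trace(sto_freq=45.0, sto_amp=1.0,
                          sto_epochs=((0.8, None),), n_periods=4,
                          noise_sd=1 / 3, seed=1)
        events = detect(vm)
        assert len(events) == 1
        assert events[0].frequency == pytest.approx(45.0, abs=2.0)
        assert events[0].n_periods >= 2.0

    def test_one_period_blip_rejected(self):
        vm, _ = sto_trace(sto_freq=45.0, sto_amp=1.0,
                          sto_epochs=((0.8, None),), n_periods=1,
                          noise_sd=0.0, seed=2)
        events = detect(vm)
        assert all(abs(e.frequency - 45.0) > 9.0 for e in events) \
            or not events

    def test_two_separated_stos(self):
        vm, _ = sto_trace(sto_freq=30.0, sto_amp=1.0,
                          sto_epochs=((0.5, 0.75),), noise_sd=0.0, seed=3)
        vm2, _ = sto_trace(sto_freq=80.0, sto_amp=1.0,
                           sto_epochs=((1.2, 1.35),), noise_sd=0.0, seed=3,
                           step_amp_mv=0.0)
        vm = vm + (vm2 - vm2.mean()) - vm2[0] + vm2.mean()  # superpose epochs
        events = detect(vm)
        freqs = sorted(round(e.frequency) for e in events)
        assert len(events) == 2
        assert abs(freqs[0] - 30) <= 3 and abs(freqs[1] - 80) <= 4
        assert events[0].t_end < events[1].t_start

    def test_noise_only_no_confirmed_stos(self):
        """Fit-quality gate keeps pure-noise responses STO-free (10 seeds)."""
        n_events = 0
        for seed in range(10):
            vm, _ = sto_trace(sto_epochs=(), noise_sd=0.5, seed=seed)
            n_events += len(detect(vm))
        assert n_events <= 1  # chance-level residue at most

    def test_count_non_increasing_in_r2_gate(self):
        vm, _ = sto_trace(sto_freq=45.0, sto_amp=0.8,
                          sto_epochs=((0.5, None), (1.2, None)),
                          n_periods=5, noise_sd=0.4, seed=5)
        counts = [len(detect(vm, r2_gate=g)) for g in (0.0, 0.4, 0.8, 0.99)]
        assert counts == sorted(counts, reverse=True)


class TestClassifyResonant:
    @pytest.mark.parametrize("n,label", [(10, "resonant"), (9, "non-resonant"),
                                         (0, "non-resonant")])
    def test_rule_boundary(self, n, label):
        assert classify_resonant([object()] * n) == label


class TestStoSpikeMetrics:
    def _sto_event(self, f=50.0, t_start=1.0, n_periods=4.0, phase=0.0):
        from obsync.sto import STOEvent
        return STOEvent(t_start=t_start, t_end=t_start + n_periods / f,
                        frequency=f, phase=phase, amplitude=1.0,
                        offset=-50.0, fit_r2=0.9)

    def test_spikes_at_extrapolated_peaks_phase_zero(self):
        ev = self._sto_event()
        peaks = ev.peak_times()
        t_ref = peaks[-1]
        spikes = [t_ref + 1 / 50.0, t_ref + 2 / 50.0]
        out = sto_spike_metrics([ev], spikes)
        angles = out["phases"].angles
        wrapped = np.angle(np.exp(1j * angles))
        assert np.all(np.abs(np.degrees(wrapped)) < 1.0)

    def test_one_spike_per_period_unity_ratio(self):
        ev = self._sto_event()
        t_ref = ev.peak_times()[-1]
        spikes = t_ref + np.array([1, 2]) / 50.0
        out = sto_spike_metrics([ev], spikes)
        assert out["mean_rate_freq_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_every_other_period_half_ratio(self):
        # a ~2-period ISI just fits inside the 2-period post-STO horizon
        ev = self._sto_event(f=60.0)
        spikes = ev.t_end + np.array([0.02, 1.98]) / 60.0
        out = sto_spike_metrics([ev], spikes)
        assert out["mean_rate_freq_ratio"] == pytest.approx(0.5, abs=0.02)

    def test_no_qualifying_spikes_empty(self):
        ev = self._sto_event()
        out = sto_spike_metrics([ev], [ev.t_end + 1.0])  # beyond 2 periods
        assert out["phases"] is None
        assert np.isnan(out["mean_rate_freq_ratio"])


class TestEndToEnd:
    def test_resonance_classification_round_trip(self):
        """A cell with one confirmed STO per step across 10 steps is
        resonant; a cell with STOs on only 5 steps is not."""
        def cell_events(n_steps_with_sto, seed0):
            events = []
            for k in range(n_steps_with_sto):
                vm, _ = sto_trace(sto_freq=45.0, sto_amp=1.0,
                                  sto_epochs=((0.8, None),), n_periods=4,
                                  noise_sd=1 / 3, seed=seed0 + k)
                events.extend(detect(vm))
            return events

        resonant = cell_events(10, seed0=100)
        non_resonant = cell_events(5, seed0=200)
        assert classify_resonant(resonant) == "resonant"
        assert classify_resonant(non_resonant) == "non-resonant"
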
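"""Synthetic-data generators: determinism, rate matching, ground truth."""

import numpy as np
import pytest

from obsync.core_events import EventTrain, TrialSet, convolve_events
from obsync.correlogram import cross_correlogram
from obsync.ipsc_detect import IpscTemplate
from obsync.synth import (
    SurrogateSpec,
    SyncPairSpec,
    ipsc_trace,
    phasic_poisson_pair,
    poisson_surrogate,
    sto_trace,
    synchronous_pair,
)
from tests.conftest import make_trialset


class TestPoissonSurrogate:
    def test_rate_matching(self):
        rng = np.random.default_rng(0)
        trials = []
        for _ in range(20):
            t = np.cumsum(rng.exponential(1 / 30.0, 200))
            trials.append(t[t < 2.0])
        ts = make_trialset(trials, 2.0)
        surr = poisson_surrogate(ts, SurrogateSpec(seed=1, n_repeats=10))
        expt_rate = ts.total_events / (ts.n_trials * 2.0)
        surr_rate = np.mean([s.total_events / (s.n_trials * 2.0)
                             for s in surr])
        assert surr_rate == pytest.approx(expt_rate, rel=0.05)

    def test_deterministic_given_seed(self):
        ts = make_trialset([np.linspace(0.1, 0.9, 20)] * 3, 1.0)
        a = poisson_surrogate(ts, SurrogateSpec(seed=9, n_repeats=2))
        b = poisson_surrogate(ts, SurrogateSpec(seed=9, n_repeats=2))
        for sa, sb in zip(a, b):
            for ta, tb in zip(sa.trains, sb.trains):
                np.testing.assert_array_equal(ta.times, tb.times)

    def test_trial_count_preserved(self):
        ts = make_trialset([np.linspace(0.1, 0.9, 10)] * 7, 1.0)
        surr = poisson_surrogate(ts, SurrogateSpec(seed=2, n_repeats=3))
        assert all(s.n_trials == 7 for s in surr)

    def test_surrogates_break_fast_synchrony(self, sync_pair):
        """Surrogates of a gamma pair show a flat central correlogram."""
        from obsync.core_events import PairRecording
        sa = poisson_surrogate(sync_pair.cell_a, SurrogateSpec(seed=5))[0]
        sb = poisson_surrogate(sync_pair.cell_b, SurrogateSpec(seed=6))[0]
        surr_pair = PairRecording(sa, sb, pair_id="surr")
        c_sync = cross_correlogram(sync_pair, max_lag=0.02)
        c_surr = cross_correlogram(surr_pair, max_lag=0.02)

        def prominence(c):
            center = c.values[c.lags.size // 2]
            flank = c.values[np.abs(c.lags) > 0.015].mean()
            return center - flank
        # synchronized pair has a sharp central peak above its flanks; the
        # surrogate pair keeps only the slow envelope (flat at small lags)
        assert prominence(c_sync) > 5 * abs(prominence(c_surr))


class TestSynchronousPair:
    def test_full_participation_no_jitter_coincident(self):
        spec = SyncPairSpec(seed=0, f_start=50, f_end=50, phase_jitter=0.0,
                            participation=1.0, n_trials=2,
                            phase_locked=True)
        pair = synchronous_pair(spec)
        for ta, tb in zip(pair.cell_a.trains, pair.cell_b.trains):
            np.testing.assert_allclose(ta.times, tb.times)
            # exactly periodic within each stimulation cycle
            isis = np.diff(ta.times)
            assert np.all(np.abs(isis[isis < 0.03] - 0.02) < 1e-9)

    def test_zero_participation_empty(self):
        spec = SyncPairSpec(seed=0, participation=0.0, n_trials=3)
        pair = synchronous_pair(spec)
        assert pair.cell_a.total_events == 0
        assert pair.cell_b.total_events == 0

    def test_side_peaks_at_oscillation_period(self):
        """Jittered 50 Hz pair: correlogram peaks at 0 and +/-20 ms."""
        spec = SyncPairSpec(seed=1, f_start=50, f_end=50, phase_jitter=0.001,
                            participation=0.8, n_trials=10)
        c = cross_correlogram(synchronous_pair(spec), max_lag=0.03)
        center = c.lags.size // 2
        side = np.abs(np.abs(c.lags) - 0.02) < 0.002
        trough = np.abs(np.abs(c.lags) - 0.01) < 0.002
        assert abs(c.lags[np.argmax(c.values)]) < 0.001  # peak at ~0 lag
        assert c.values[side].max() > 2 * c.values[trough].max()

    def test_ground_truth_recorded(self):
        pair = synchronous_pair(SyncPairSpec(seed=3, f_start=90, f_end=50))
        gt = pair.metadata["ground_truth"]
        assert gt["f_start"] == 90 and gt["f_end"] == 50
        assert gt["chirp_slope_hz_per_ms"] == pytest.approx(-0.267, abs=0.001)

    def test_seed_determinism(self):
        a = synchronous_pair(SyncPairSpec(seed=4))
        b = synchronous_pair(SyncPairSpec(seed=4))
        np.testing.assert_array_equal(a.cell_a.trains[0].times,
                                      b.cell_a.trains[0].times)


class TestPhasicPoissonPair:
    def test_cells_independent(self):
        pair = phasic_poisson_pair(seed=0, n_trials=10)
        c = cross_correlogram(pair, max_lag=0.01)
        # no sharp central structure: center value within noise of flanks
        center = c.values[c.lags.size // 2]
        assert abs(center) < 5 * c.values.std() + 1e-9

    def test_phasic_envelope(self):
        pair = phasic_poisson_pair(rate_hz=40, off_rate_hz=0, seed=1,
                                   n_trials=20)
        counts_on = sum(np.count_nonzero((tr.times % 0.2) < 0.15)
                        for tr in pair.cell_a.trains)
        counts_off = sum(np.count_nonzero((tr.times % 0.2) >= 0.15)
                         for tr in pair.cell_a.trains)
        assert counts_off <= 0.02 * counts_on


class TestIpscTrace:
    def test_single_event_peak_equals_amplitude(self):
        tr, _ = ipsc_trace([0.01], 40.0, noise_sd=0.0, fs=10_000,
                           duration=0.1)
        assert tr.max() == pytest.approx(40.0, rel=0.01)

    def test_noise_only_sd(self):
        tr, _ = ipsc_trace([], [], noise_sd=3.0, fs=10_000, duration=1.0,
                           seed=2)
        assert tr.std() == pytest.approx(3.0, rel=0.1)

    def test_overlapping_events_sum(self):
        tr1, _ = ipsc_trace([0.01], 40.0, noise_sd=0.0, duration=0.1)
        tr2, _ = ipsc_trace([0.01, 0.012], 40.0, noise_sd=0.0, duration=0.1)
        assert tr2.max() > tr1.max()

    def test_rejects_nonpositive_amplitude(self):
        with pytest.raises(ValueError):
            ipsc_trace([0.01], -5.0, duration=0.1)

    def test_full_decay_tail_rendered(self):
        """Simulated events decay with tau ~3 ms, beyond the abridged 4 ms."""
        tpl = IpscTemplate()
        tr, _ = ipsc_trace([0.01], 100.0, noise_sd=0.0, fs=10_000,
                           duration=0.1)
        i_peak = tr.argmax()
        i_5ms = i_peak + 50
        assert tr[i_5ms] > 1.0  # abridged template would be exactly zero


class TestStoTrace:
    def test_epoch_and_step_layout(self):
        vm, gt = sto_trace(sto_freq=45, sto_amp=1.0, noise_sd=0.0, seed=0)
        t = np.arange(vm.size) / 1e4
        base = vm[t < 0.15]
        step = vm[(t > 0.3) & (t < 0.45)]
        assert base.mean() == pytest.approx(-55.0, abs=0.1)
        assert step.mean() == pytest.approx(-47.0, abs=0.5)

    def test_spikes_reach_excursion(self):
        vm, _ = sto_trace(spike_times=[1.0], noise_sd=0.0, seed=0)
        assert vm.max() == pytest.approx(30.0, abs=0.5)

    def test_determinism(self):
        a, _ = sto_trace(noise_sd=0.5, seed=8)
        b, _ = sto_trace(noise_sd=0.5, seed=8)
        np.testing.assert_array_equal(a, b)
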
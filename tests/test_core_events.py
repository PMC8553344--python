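"""Event-train model, convolution, rates, PSTH and CV2."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obsync.core_events import (
    EventTrain,
    TrialSet,
    convolve_events,
    cv2_series,
    psth,
    relative_rate_difference,
    sequential_rates,
)
from tests.conftest import make_pair, make_trialset

GAUSS_PEAK = 1.0 / (0.001 * np.sqrt(2 * np.pi))  # unit-area kernel, sigma 1 ms


class TestEventTrain:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            EventTrain(np.array([0.2, 0.1]), 1.0)
        with pytest.raises(ValueError):
            EventTrain(np.array([0.5]), -1.0)
        with pytest.raises(ValueError):
            EventTrain(np.array([1.5]), 1.0)

    def test_empty_train_valid(self):
        t = EventTrain(np.array([]), 1.0)
        assert t.n_events == 0 and t.mean_rate == 0.0


class TestConvolveEvents:
    def test_single_event_unit_area(self):
        ct = convolve_events(EventTrain(np.array([0.5]), 1.0),
                             mean_subtract=False)
        assert ct.samples.sum() / ct.fs == pytest.approx(1.0, abs=1e-6)

    def test_single_event_gaussian_peak(self):
        ct = convolve_events(EventTrain(np.array([0.5]), 1.0),
                             mean_subtract=False)
        assert ct.samples.max() == pytest.approx(GAUSS_PEAK, rel=1e-3)

    def test_empty_train_all_zero(self):
        ct = convolve_events(EventTrain(np.array([]), 1.0),
                             mean_subtract=False)
        assert not ct.samples.any()

    def test_integral_equals_event_count(self):
        train = EventTrain(np.arange(0.1, 0.95, 0.05), 1.0)
        ct = convolve_events(train, mean_subtract=False)
        assert ct.samples.sum() / ct.fs == pytest.approx(train.n_events,
                                                         rel=1e-4)

    def test_mean_subtraction(self):
        ct = convolve_events(EventTrain(np.arange(0.1, 0.9, 0.01), 1.0),
                             mean_subtract=True)
        assert abs(ct.samples.mean()) < 1e-9 * np.abs(ct.samples).max()

    def test_linear_in_superposition(self):
        a = EventTrain(np.array([0.2, 0.4]), 1.0)
        b = EventTrain(np.array([0.3, 0.7]), 1.0)
        ab = EventTrain(np.array([0.2, 0.3, 0.4, 0.7]), 1.0)
        sa = convolve_events(a, mean_subtract=False).samples
        sb = convolve_events(b, mean_subtract=False).samples
        sab = convolve_events(ab, mean_subtract=False).samples
        np.testing.assert_allclose(sab, sa + sb, atol=1e-9)

    def test_unresolvable_kernel_rejected(self):
        with pytest.raises(ValueError):
            convolve_events(EventTrain(np.array([0.5]), 1.0), fs=100.0,
                            sigma=0.001)


class TestSequentialRates:
    def test_inverse_interval(self):
        t, r = sequential_rates(EventTrain(np.array([0.1, 0.2, 0.4]), 1.0))
        np.testing.assert_allclose(r, [10.0, 5.0])
        np.testing.assert_allclose(t, [0.2, 0.4])  # later event of each IEI

    def test_periodic_train_constant(self, periodic_train):
        _, r = sequential_rates(periodic_train)
        np.testing.assert_allclose(r, 50.0)

    def test_short_train_empty(self):
        t, r = sequential_rates(EventTrain(np.array([0.5]), 1.0))
        assert t.size == 0 and r.size == 0

    def test_poisson_mean_inverse_isi_exceeds_rate(self):
        # Jensen: E[1/ISI] > 1/E[ISI]; Monte-Carlo oracle at rate 20 Hz
        rng = np.random.default_rng(7)
        isis = rng.exponential(1 / 20.0, 200_000)
        t = np.cumsum(isis)
        _, r = sequential_rates(EventTrain(t, t[-1] + 1))
        assert r.mean() > 20.0 * 2  # heavy-tailed 1/ISI mean far above rate


class TestPsth:
    def test_count_conservation(self):
        ts = make_trialset([[0.05]] * 10, 1.0)
        centers, lam = psth(ts, 0.001, 0.010)
        assert np.trapezoid(lam, centers) == pytest.approx(1.0, abs=1e-2)

    def test_homogeneous_poisson_level(self):
        rng = np.random.default_rng(3)
        trials = []
        for _ in range(20):
            t = np.cumsum(rng.exponential(1 / 20.0, 100))
            trials.append(t[t < 1.0])
        centers, lam = psth(make_trialset(trials, 1.0), 0.001, 0.010)
        # pointwise within sampling error of 20 Hz (generous 3-sigma-ish)
        inner = lam[(centers > 0.05) & (centers < 0.95)]
        assert abs(inner.mean() - 20.0) < 3.0
        assert inner.max() < 20.0 + 40.0

    def test_empty_trials_zero(self):
        _, lam = psth(make_trialset([[], []], 1.0))
        assert not lam.any()


class TestCv2:
    def test_constant_isis_zero(self, periodic_train):
        s = cv2_series(periodic_train)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)
        assert s.median == pytest.approx(0.0, abs=1e-12)

    def test_known_pair(self):
        # ISIs 10 then 30 ms: CV2 = 2*20/40 = 1
        s = cv2_series(EventTrain(np.array([0.0, 0.010, 0.040]), 1.0))
        np.testing.assert_allclose(s.values, [1.0])

    def test_too_few_events_flagged(self):
        s = cv2_series(EventTrain(np.array([0.1, 0.2]), 1.0))
        assert s.values.size == 0 and np.isnan(s.median)

    def test_poisson_mean_near_one(self):
        rng = np.random.default_rng(11)
        t = np.cumsum(rng.exponential(0.01, 10_000))
        s = cv2_series(EventTrain(t, t[-1] + 1))
        assert s.values.mean() == pytest.approx(1.0, abs=0.05)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_time_rescaling(self, scale):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 1, 50))
        t = t[np.concatenate(([True], np.diff(t) > 0))]
        base = cv2_series(EventTrain(t, 1.0)).values
        scaled = cv2_series(EventTrain(t * scale, scale)).values
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_bounded(self):
        rng = np.random.default_rng(9)
        t = np.cumsum(rng.lognormal(-4, 1.5, 500))
        s = cv2_series(EventTrain(t, t[-1] + 1))
        assert np.all((s.values >= 0) & (s.values <= 2))


class TestRelativeRateDifference:
    def test_equal_rates_zero(self):
        pair = make_pair([[0.1, 0.2, 0.3]], [[0.15, 0.25, 0.35]], 1.0)
        assert relative_rate_difference(pair, (0.0, 0.5)) == 0.0

    def test_three_to_one(self):
        pair = make_pair([np.linspace(0.01, 0.99, 30)],
                         [np.linspace(0.01, 0.99, 10)], 1.0)
        assert relative_rate_difference(pair, (0.0, 1.0)) == pytest.approx(1.0)

    def test_one_silent_cell_boundary(self):
        pair = make_pair([[0.1, 0.2]], [[]], 1.0)
        assert relative_rate_difference(pair, (0.0, 1.0)) == pytest.approx(2.0)

    def test_both_silent_flagged(self):
        pair = make_pair([[0.9]], [[0.95]], 1.0)
        assert np.isnan(relative_rate_difference(pair, (0.0, 0.5)))
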
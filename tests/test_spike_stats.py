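"""Rate/CV/serial-correlation estimators and power-spectrum estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifspec import (InsufficientDataError, SpikeTrain, isi_statistics,
                     renewal_spectrum, spike_spectrum)

from conftest import poisson_trains


def train_from_intervals(intervals, trial_id=0):
    times = np.cumsum(intervals)
    return SpikeTrain(times=times, duration=times[-1] + 1.0, trial_id=trial_id)


class TestISIStatistics:
    def test_periodic_train_has_zero_cv(self):
        stats = isi_statistics([train_from_intervals(np.full(500, 12.5))])
        assert stats.cv == pytest.approx(0.0, abs=1e-12)
        assert stats.rate == pytest.approx(80.0)

    def test_poisson_limit_cv_one_rho_zero(self, rng):
        intervals = rng.exponential(10.0, 120_000)
        stats = isi_statistics([train_from_intervals(intervals)], max_lag=3)
        se = 1.0 / np.sqrt(stats.n_intervals)
        assert stats.cv == pytest.approx(1.0, abs=3 * 2 * se)
        assert np.all(np.abs(stats.rho) < 3 * se)

    def test_alternating_intervals(self):
        # 10,20,10,20,... ms: mean 15, cv 1/3, rho_1 -> -1
        stats = isi_statistics(
            [train_from_intervals(np.tile([10.0, 20.0], 5000))], max_lag=2)
        assert stats.rate == pytest.approx(1000.0 / 15.0, rel=1e-4)
        assert stats.cv == pytest.approx(1.0 / 3.0, rel=1e-3)
        assert stats.rho[0] == pytest.approx(-1.0, abs=1e-3)
        assert stats.rho[1] == pytest.approx(1.0, abs=1e-3)

    def test_intervals_never_span_trial_boundaries(self):
        # two trials of periodic trains with different phases: pooling the
        # per-trial ISIs keeps CV at 0; a cross-boundary interval would not
        t1 = train_from_intervals(np.full(100, 10.0), trial_id=0)
        t2 = SpikeTrain(times=np.cumsum(np.full(100, 10.0)) + 3.0,
                        duration=1005.0, trial_id=1)
        stats = isi_statistics([t1, t2])
        assert stats.cv == pytest.approx(0.0, abs=1e-12)
        assert stats.n_intervals == 198

    def test_insufficient_data(self):
        lone = SpikeTrain(times=np.array([5.0]), duration=10.0)
        with pytest.raises(InsufficientDataError):
            isi_statistics([lone])

    def test_infeasible_lags_truncated(self):
        stats = isi_statistics([train_from_intervals(np.array([9.0, 11.0, 10.0]))],
                               max_lag=10)
        assert stats.rho.size < 10
        assert np.all(stats.rho_low_confidence)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_estimator_invariants(self, seed):
        r = np.random.default_rng(seed)
        intervals = r.gamma(r.uniform(0.5, 6.0), r.uniform(2.0, 30.0), 400)
        stats = isi_statistics([train_from_intervals(intervals)], max_lag=3)
        # internal consistency: rate is the inverse pooled mean interval
        assert stats.rate * stats.isi_sample.mean() == pytest.approx(1000.0,
                                                                     rel=1e-9)
        assert stats.cv >= 0
        assert np.all(np.abs(stats.rho) <= 1.0)


class TestSpikeSpectrum:
    def test_poisson_spectrum_is_flat_at_rate(self, rng):
        nu = 71.0
        trains = poisson_trains(nu, 1638.4 * 4, 40, rng)
        ps = spike_spectrum(trains)
        n_spk = sum(t.n_spikes for t in trains)
        rate = 1000.0 * n_spk / sum(t.duration for t in trains)
        rel_se = 1.0 / np.sqrt(ps.n_windows)
        assert ps.values.mean() == pytest.approx(rate, rel=3 * rel_se / np.sqrt(ps.freq.size) + 0.01)
        # no systematic slope: low and high halves agree
        half = ps.freq.size // 2
        assert ps.values[:half].mean() == pytest.approx(
            ps.values[half:].mean(), rel=4 * rel_se / np.sqrt(half))

    def test_periodic_train_concentrates_at_harmonics(self):
        # period dividing the window exactly: all mass sits on multiples of
        # the firing rate (here 78.125 Hz = 128 spectral bins)
        period = 12.8
        times = np.arange(period, 1638.4 * 2, period)
        train = SpikeTrain(times=times, duration=1638.4 * 2)
        ps = spike_spectrum([train])
        f0 = 1000.0 / period
        harmonics = np.isclose(ps.freq % f0, 0.0, atol=ps.delta_f / 4) | \
            np.isclose(ps.freq % f0, f0, atol=ps.delta_f / 4)
        assert ps.values[harmonics].mean() > 100 * ps.values[~harmonics].mean()

    def test_high_frequency_tail_equals_rate(self, rng):
        trains = poisson_trains(50.0, 1638.4 * 3, 30, rng)
        ps = spike_spectrum(trains)
        rate = 1000.0 * sum(t.n_spikes for t in trains) / sum(
            t.duration for t in trains)
        top_decade = ps.freq > ps.freq[-1] / 10
        assert ps.values[top_decade].mean() == pytest.approx(rate, rel=0.05)

    def test_window_longer_than_data_rejected(self):
        short = SpikeTrain(times=np.array([1.0, 2.0]), duration=100.0)
        with pytest.raises(ValueError, match="window"):
            spike_spectrum([short], window_length=1638.4)

    def test_grid_and_metadata(self, rng):
        trains = poisson_trains(40.0, 1638.4 * 2, 3, rng)
        ps = spike_spectrum(trains)
        assert ps.delta_f == pytest.approx(1000.0 / 1638.4)
        assert ps.freq[0] == pytest.approx(ps.delta_f)
        assert ps.n_windows == 6
        assert np.all(ps.values >= 0)


class TestRenewalSpectrum:
    def test_exponential_isi_gives_flat_spectrum(self, rng):
        nu = 80.0
        sample = rng.exponential(1000.0 / nu, 200_000)
        freq = np.linspace(2.0, 400.0, 120)
        ps = renewal_spectrum(sample, nu, freq)
        np.testing.assert_allclose(ps.values, nu, rtol=0.04)

    def test_low_frequency_limit_is_nu_cv_squared(self, rng):
        sample = rng.gamma(4.0, 5.0, 300_000)  # cv = 0.5
        nu = 1000.0 / sample.mean()
        cv2 = sample.var(ddof=1) / sample.mean() ** 2
        ps = renewal_spectrum(sample, nu, np.array([0.05, 0.1, 0.2]))
        np.testing.assert_allclose(ps.values, nu * cv2, rtol=0.05)

    def test_gamma_renewal_matches_simulated_spectrum(self, rng):
        # Eq-by-construction cross-check: analytic renewal formula on the
        # empirical sample vs the averaged periodogram of simulated trains
        shape, scale = 2.0, 7.0
        sample = rng.gamma(shape, scale, 100_000)
        nu = 1000.0 / sample.mean()
        trains = []
        for i in range(60):
            iv = rng.gamma(shape, scale, 2000)
            t = np.cumsum(iv)
            trains.append(SpikeTrain(times=t[t < 1638.4 * 4], duration=1638.4 * 4,
                                     trial_id=i))
        measured = spike_spectrum(trains)
        test_freq = np.linspace(5.0, 300.0, 10)
        analytic = renewal_spectrum(sample, nu, test_freq)
        interp = np.interp(test_freq, measured.freq, measured.values)
        rel_se = 3.0 / np.sqrt(measured.n_windows)
        np.testing.assert_allclose(interp, analytic.values,
                                   rtol=rel_se + 0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            renewal_spectrum(np.array([1.0, 2.0]), 0.0, np.array([1.0]))
        with pytest.raises(ValueError):
            renewal_spectrum(np.array([-1.0, 2.0]), 10.0, np.array([1.0]))
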
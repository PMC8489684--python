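import numpy as np
import pytest

from ringbind import analysis as an
from ringbind.engine import SpikeRecord


def make_record(times, neurons, n_exc=64, duration=1000.0):
    times = np.asarray(times, dtype=float)
    order = np.argsort(times)
    return SpikeRecord(
        times=times[order],
        neurons=np.asarray(neurons, dtype=np.int64)[order],
        populations=np.full(len(times), "E", dtype="U1"),
        network="color",
        duration=duration,
        dt=0.05,
        seed=0,
        n_exc=n_exc,
        n_inh=16,
    )


class TestBumpSpikeCounts:
    def test_empty_record(self):
        rec = make_record([], [])
        counts = an.bump_spike_counts(rec, an.BumpWindow(10, 5), 5.0)
        assert counts.counts.sum() == 0

    def test_single_spike_binning(self):
        rec = make_record([7.0], [10], duration=20.0)
        counts = an.bump_spike_counts(rec, an.BumpWindow(10, 5), 5.0)
        assert counts.counts.tolist() == [0, 1, 0, 0]

    def test_window_wraps_around_zero(self):
        n = 64
        rec = make_record([1.0, 2.0, 3.0], [n - 5, 5, 31], n_exc=n, duration=10.0)
        counts = an.bump_spike_counts(rec, an.BumpWindow(0, 10), 10.0)
        # brute-force circular distance oracle
        def circ(i):
            return min(i % n, n - i % n)
        expected = sum(1 for i in (n - 5, 5, 31) if circ(i) <= 10)
        assert counts.counts.sum() == expected == 2


class TestCrossCorrelogram:
    def test_autocorrelation_at_zero_is_one(self, rng):
        c = an.BinnedCounts(5.0, 0.0, rng.poisson(3.0, 200))
        corr = an.cross_correlogram(c, c, 50.0)
        assert corr.values[corr.lags == 0][0] == pytest.approx(1.0)

    def test_antiphase_zero_lag_negative(self):
        t = np.arange(400) * 5.0
        a = an.BinnedCounts(5.0, 0.0, np.round(10 + 8 * np.cos(2 * np.pi * 0.03 * t)))
        b = an.BinnedCounts(5.0, 0.0, np.round(10 + 8 * np.cos(2 * np.pi * 0.03 * t + np.pi)))
        corr = an.cross_correlogram(a, b, 100.0)
        assert corr.values[corr.lags == 0][0] < -0.5

    def test_symmetry_identity(self, rng):
        a = an.BinnedCounts(5.0, 0.0, rng.poisson(4.0, 300))
        b = an.BinnedCounts(5.0, 0.0, rng.poisson(4.0, 300))
        ab = an.cross_correlogram(a, b, 50.0)
        ba = an.cross_correlogram(b, a, 50.0)
        assert np.allclose(ab.values, ba.values[::-1], atol=1e-12)

    def test_values_bounded(self, rng):
        a = an.BinnedCounts(5.0, 0.0, rng.poisson(4.0, 300))
        b = an.BinnedCounts(5.0, 0.0, rng.poisson(4.0, 300))
        corr = an.cross_correlogram(a, b, 100.0)
        ok = ~np.isnan(corr.values)
        assert np.all(corr.values[ok] <= 1.0 + 1e-12)
        assert np.all(corr.values[ok] >= -1.0 - 1e-12)

    def test_zero_variance_flagged(self):
        a = an.BinnedCounts(5.0, 0.0, np.ones(100, dtype=int))
        b = an.BinnedCounts(5.0, 0.0, np.ones(100, dtype=int))
        corr = an.cross_correlogram(a, b, 20.0)
        assert np.all(np.isnan(corr.values))


class TestSlidingCorrelation:
    def test_identical_series(self, rng):
        counts = rng.poisson(5.0, 200)
        a = an.BinnedCounts(5.0, 0.0, counts)
        centers, vals = an.sliding_count_correlation(a, a, 100.0)
        ok = ~np.isnan(vals)
        assert ok.any()
        assert np.allclose(vals[ok], 1.0)

    def test_window_not_multiple_rejected(self):
        a = an.BinnedCounts(5.0, 0.0, np.arange(100))
        with pytest.raises(ValueError):
            an.sliding_count_correlation(a, a, 98.0)

    def test_programmed_reversal_detected(self):
        from ringbind.fixtures import correlated_pair_fixture

        rec_a, rec_b = correlated_pair_fixture(
            f=30.0, relative_phase=0.0, reversal_time=1500.0, seed=5, duration=3000.0
        )
        ca = an.bump_spike_counts(rec_a, an.BumpWindow(0, 20), 5.0)
        cb = an.bump_spike_counts(rec_b, an.BumpWindow(0, 20), 5.0)
        centers, vals = an.sliding_count_correlation(ca, cb, 100.0)
        before = vals[(centers > 500) & (centers < 1350)]
        after = vals[(centers > 1650) & (centers < 2900)]
        assert np.nanmean(before) > 0.2
        assert np.nanmean(after) < -0.2
        # sign change within +-150 ms of the programmed reversal
        sign = np.sign(vals)
        flips = centers[np.flatnonzero(np.diff(sign) != 0)]
        assert np.any(np.abs(flips - 1500.0) <= 150.0)


class TestCorrelationSpectrum:
    @pytest.mark.parametrize("f", [20.0, 30.0, 40.0, 60.0])
    def test_recovers_programmed_frequency(self, f):
        lags = np.arange(-100, 101) * 5.0
        corr = an.CorrelationFunction(lags, np.cos(2 * np.pi * f * lags / 1000.0))
        spec = an.correlation_spectrum(corr)
        assert spec.peak_frequency == pytest.approx(f, abs=2.0)

    def test_white_noise_flat(self):
        lags = np.arange(-50, 51) * 5.0
        values = np.zeros(lags.size)
        values[lags == 0] = 1.0
        spec = an.correlation_spectrum(an.CorrelationFunction(lags, values))
        assert spec.peak_frequency is None

    def test_antiphase_fixture_30hz(self):
        from ringbind.fixtures import correlated_pair_fixture

        rec_a, rec_b = correlated_pair_fixture(f=30.0, relative_phase=np.pi, seed=2)
        ca = an.bump_spike_counts(rec_a, an.BumpWindow(0, 20), 5.0)
        cb = an.bump_spike_counts(rec_b, an.BumpWindow(0, 20), 5.0)
        corr = an.cross_correlogram(ca, cb, 500.0)
        spec = an.correlation_spectrum(corr)
        assert spec.peak_frequency == pytest.approx(30.0, abs=2.0)

    def test_all_missing_rejected(self):
        corr = an.CorrelationFunction(np.arange(-5, 6) * 5.0, np.full(11, np.nan))
        with pytest.raises(ValueError):
            an.correlation_spectrum(corr)


class TestLfp:
    def test_single_spike_peak(self):
        lfp = an.lfp_from_spikes([0.0], duration=100.0, dt=0.1, tau=5.0)
        peak_idx = np.argmax(lfp.samples)
        assert lfp.times[peak_idx] == pytest.approx(5.0, abs=0.1)
        assert lfp.samples[peak_idx] == pytest.approx(np.exp(-1), abs=1e-3)

    def test_empty_spike_list(self):
        lfp = an.lfp_from_spikes([], duration=50.0, dt=1.0)
        assert not lfp.samples.any()

    def test_integral_per_spike_is_tau(self):
        # analytic: integral of (t/tau) exp(-t/tau) dt over [0, inf) = tau
        tau, dt = 5.0, 0.05
        lfp = an.lfp_from_spikes([10.0], duration=200.0, dt=dt, tau=tau)
        assert np.sum(lfp.samples) * dt == pytest.approx(tau, rel=1e-2)

    def test_linearity(self):
        a = an.lfp_from_spikes([5.0, 20.0], duration=100.0, dt=0.5)
        b = an.lfp_from_spikes([12.0], duration=100.0, dt=0.5)
        both = an.lfp_from_spikes([5.0, 12.0, 20.0], duration=100.0, dt=0.5)
        assert np.allclose(both.samples, a.samples + b.samples, atol=1e-9)

    def test_nonnegative(self, rng):
        lfp = an.lfp_from_spikes(rng.uniform(0, 500, 200), duration=500.0, dt=1.0)
        assert np.all(lfp.samples >= -1e-12)


class TestPowerPeak:
    def test_pure_30hz(self):
        t = np.arange(0, 3000.0, 1.0)
        trace = an.LfpTrace(10 + np.sin(2 * np.pi * 30 * t / 1000.0), dt=1.0)
        spec = an.power_peak(trace)
        assert spec.peak_frequency == pytest.approx(30.0, abs=1.0)

    def test_constant_trace_no_peak(self):
        trace = an.LfpTrace(np.full(2000, 3.0), dt=1.0)
        spec = an.power_peak(trace)
        assert spec.peak_frequency is None

    def test_two_component_picks_larger(self):
        t = np.arange(0, 4000.0, 1.0)
        sig = 3.0 * np.sin(2 * np.pi * 25 * t / 1000.0) + 1.0 * np.sin(2 * np.pi * 50 * t / 1000.0)
        spec = an.power_peak(an.LfpTrace(sig, dt=1.0))
        assert spec.peak_frequency == pytest.approx(25.0, abs=1.0)

    def test_short_window_rejected(self):
        trace = an.LfpTrace(np.ones(100), dt=1.0)
        with pytest.raises(ValueError):
            an.power_peak(trace, window=(0.0, 100.0))


class TestLoadFrequencyRatio:
    def test_constant_network_frequency(self):
        out = an.load_frequency_ratio({1: 40.0, 2: 40.0, 3: 40.0})
        assert out["ratios"] == {1: 1.0, 2: 1.0, 3: 1.0}

    def test_halving_is_scenario2(self):
        out = an.load_frequency_ratio({1: 40.0, 2: 20.0})
        assert out["ratios"][2] == pytest.approx(0.5)
        assert out["scenario2"][2] == pytest.approx(0.5)

    def test_linear_is_scenario1(self):
        out = an.load_frequency_ratio({1: 40.0, 2: 80.0, 3: 120.0})
        assert [out["ratios"][k] for k in (1, 2, 3)] == pytest.approx([1.0, 2.0, 3.0])
        assert out["scenario1"] == {1: 1.0, 2: 2.0, 3: 3.0}

    def test_missing_load1_rejected(self):
        with pytest.raises(ValueError):
            an.load_frequency_ratio({2: 20.0})


class TestWaveletPhase:
    def test_linear_phase_advance(self):
        f0, dt = 30.0, 1.0
        t = np.arange(0, 2000.0, dt)
        trace = an.LfpTrace(np.cos(2 * np.pi * f0 * t / 1000.0), dt=dt)
        ph = an.wavelet_phase(trace, f0=f0)
        inner = slice(200, -200)  # avoid edge effects
        unwrapped = np.unwrap(ph.phases[0][inner])
        slope = np.polyfit(t[inner], unwrapped, 1)[0]  # rad/ms
        expected = 2 * np.pi * f0 / 1000.0
        assert abs(slope - expected) / expected < 0.01

    def test_constant_phase_shift_recovered(self):
        f0, dt, delta = 30.0, 1.0, 0.9
        t = np.arange(0, 2000.0, dt)
        a = an.wavelet_phase(an.LfpTrace(np.cos(2 * np.pi * f0 * t / 1000.0), dt=dt), f0)
        b = an.wavelet_phase(
            an.LfpTrace(np.cos(2 * np.pi * f0 * t / 1000.0 - delta), dt=dt), f0
        )
        diff = np.angle(np.exp(1j * (a.phases[0] - b.phases[0])))[300:-300]
        assert np.allclose(diff, delta, atol=0.02)

    def test_sign_flip_is_pi_shift(self):
        f0, dt = 30.0, 1.0
        t = np.arange(0, 2000.0, dt)
        sig = np.cos(2 * np.pi * f0 * t / 1000.0)
        a = an.wavelet_phase(an.LfpTrace(sig, dt=dt), f0)
        b = an.wavelet_phase(an.LfpTrace(-sig, dt=dt), f0)
        diff = np.abs(np.angle(np.exp(1j * (a.phases[0] - b.phases[0]))))[300:-300]
        assert np.allclose(diff, np.pi, atol=0.02)

    def test_unresolvable_f0_rejected(self):
        trace = an.LfpTrace(np.ones(100), dt=10.0)
        with pytest.raises(ValueError):
            an.wavelet_phase(trace, f0=80.0)


class TestPpi:
    def test_locked_ensemble_is_one(self):
        from ringbind.fixtures import phase_trial_ensemble

        ph = phase_trial_ensemble(20, drift_model="locked", seed=3)
        curve = an.phase_preservation_index(ph, t_ref=0.0)
        assert np.all(np.abs(curve.values - 1.0) < 1e-9)

    def test_reference_time_exactly_one(self):
        from ringbind.fixtures import phase_trial_ensemble

        ph = phase_trial_ensemble(10, drift_model="random_walk", seed=4)
        curve = an.phase_preservation_index(ph, t_ref=1500.0)
        ref_idx = np.argmin(np.abs(curve.times - 1500.0))
        assert curve.values[ref_idx] == pytest.approx(1.0, abs=1e-12)

    def test_common_offset_cancels(self, rng):
        times = np.arange(0.0, 1000.0, 5.0)
        base = rng.uniform(-np.pi, np.pi, size=(8, 1))
        delta = rng.uniform(-np.pi, np.pi, size=(1, times.size))
        phases = np.angle(np.exp(1j * (base + delta)))
        ph = an.PhaseSeries(phases=phases, times=times, f0=30.0)
        curve = an.phase_preservation_index(ph, t_ref=0.0)
        assert np.all(np.abs(curve.values - 1.0) < 1e-9)

    def test_independent_phases_match_rayleigh_oracle(self, rng):
        # oracle: mean resultant length of N uniform phasors ~ sqrt(pi)/(2 sqrt(N))
        n = 100
        n_rep = 200
        times = np.arange(0.0, 500.0, 5.0)
        vals = []
        for rep in range(n_rep):
            phases = rng.uniform(-np.pi, np.pi, size=(n, times.size))
            phases[:, 0] = 0.0  # reference column
            ph = an.PhaseSeries(phases=phases, times=times, f0=30.0)
            curve = an.phase_preservation_index(ph, t_ref=0.0)
            vals.append(curve.values[1:].mean())
        expected = np.sqrt(np.pi) / (2.0 * np.sqrt(n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_bounds_always_hold(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(13, 50))
        ph = an.PhaseSeries(phases=phases, times=np.arange(50.0), f0=30.0)
        curve = an.phase_preservation_index(ph, t_ref=10.0)
        assert np.all((curve.values >= 0.0) & (curve.values <= 1.0))

    def test_fewer_than_two_trials_rejected(self):
        ph = an.PhaseSeries(phases=np.zeros((1, 10)), times=np.arange(10.0), f0=30.0)
        with pytest.raises(ValueError):
            an.phase_preservation_index(ph, t_ref=0.0)


class TestBumpStrength:
    def test_uniform_counts_zero(self):
        n = 32
        times = np.tile(np.arange(10.0), n)
        neurons = np.repeat(np.arange(n), 10)
        rec = make_record(times, neurons, n_exc=n, duration=20.0)
        assert an.bump_strength(rec, (0.0, 20.0)) == 0.0

    def test_concentrated_is_maximal(self):
        n = 32
        total = 64
        conc = make_record(np.linspace(0, 9, total), [3] * total, n_exc=n, duration=10.0)
        spread = make_record(
            np.linspace(0, 9, total), list(range(n)) * 2, n_exc=n, duration=10.0
        )
        assert an.bump_strength(conc, (0.0, 10.0)) > an.bump_strength(spread, (0.0, 10.0))

    def test_matches_direct_recount(self, rng):
        n = 64
        neurons = rng.integers(0, n, 500)
        times = rng.uniform(0, 100, 500)
        rec = make_record(times, neurons, n_exc=n, duration=100.0)
        window = (20.0, 80.0)
        mask = (rec.times >= window[0]) & (rec.times < window[1])
        counts = np.bincount(rec.neurons[mask], minlength=n)
        assert an.bump_strength(rec, window) == pytest.approx(counts.std())
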
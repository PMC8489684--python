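import numpy as np
import pytest

from ringbind import decoder as dc
from ringbind import fixtures as fx
from tests.test_analysis import make_record


def profile_from(rates, window=(0.0, 500.0)):
    return dc.RateProfile(rates=np.asarray(rates, dtype=float), window=window)


def gaussian_profile(n, center, sigma, mass):
    x = np.arange(n)
    return mass * np.exp(-((x - center) ** 2) / (2 * sigma**2))


class TestDelayRateProfile:
    def test_empty_record(self):
        rec = make_record([], [], n_exc=32)
        profile = dc.delay_rate_profile(rec, (0.0, 500.0))
        assert not profile.rates.any()

    def test_rate_arithmetic(self):
        rec = make_record([10.0 + i for i in range(10)], [4] * 10, n_exc=32)
        profile = dc.delay_rate_profile(rec, (0.0, 500.0))
        assert profile.rates[4] == pytest.approx(20.0)  # 10 spikes / 0.5 s

    def test_conservation(self, rng):
        n = 64
        times = rng.uniform(0, 1000, 400)
        neurons = rng.integers(0, n, 400)
        rec = make_record(times, neurons, n_exc=n)
        window = (100.0, 900.0)
        profile = dc.delay_rate_profile(rec, window)
        in_window = np.sum((rec.times >= window[0]) & (rec.times < window[1]))
        assert profile.rates.sum() * 0.8 == pytest.approx(in_window)

    def test_zero_length_window_rejected(self):
        rec = make_record([], [], n_exc=32)
        with pytest.raises(ValueError):
            dc.delay_rate_profile(rec, (100.0, 100.0))


class TestFitTwoGaussians:
    def test_two_rectangular_bumps(self):
        # moment-matching oracle: each rectangle's mean is its center
        n = 2048
        rates = np.zeros(n)
        rates[520 - 40 : 520 + 40] = 10.0
        rates[1480 - 40 : 1480 + 40] = 10.0
        fit = dc.fit_two_gaussians(profile_from(rates), (520, 1480))
        centers = np.sort(fit.centers)
        assert abs(centers[0] - 520) <= 10
        assert abs(centers[1] - 1480) <= 10
        assert fit.weights[0] == pytest.approx(0.5, abs=0.05)

    def test_single_bump_dominant_component(self):
        n = 2048
        rates = gaussian_profile(n, 520, 30.0, 10.0)
        fit = dc.fit_two_gaussians(profile_from(rates), (520, 1480))
        k = int(np.argmax(fit.weights))
        assert fit.weights[k] >= 0.9
        assert abs(fit.centers[k] - 520) <= 10

    def test_mass_ratio_two_to_one(self):
        n = 2048
        rates = gaussian_profile(n, 520, 30.0, 10.0) + gaussian_profile(n, 1480, 30.0, 5.0)
        fit = dc.fit_two_gaussians(profile_from(rates), (520, 1480))
        order = np.argsort(fit.centers)
        w_520, w_1480 = fit.weights[order]
        assert w_520 / w_1480 == pytest.approx(2.0, rel=0.1)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            dc.fit_two_gaussians(profile_from(np.zeros(100)), (20, 80))

    def test_deterministic(self):
        rates = gaussian_profile(256, 65, 8.0, 5.0) + gaussian_profile(256, 185, 8.0, 4.0)
        a = dc.fit_two_gaussians(profile_from(rates), (65, 185))
        b = dc.fit_two_gaussians(profile_from(rates), (65, 185))
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.weights, b.weights)


class TestReadout:
    def _fit(self, w1, w2, c1=520.0, c2=1480.0):
        return dc.MixtureFit(
            centers=np.array([c1, c2]), widths=np.array([30.0, 30.0]),
            weights=np.array([w1, w2]), converged=True, n_iter=1, log_likelihood=0.0,
        )

    def test_larger_weight_wins(self):
        pos, comp, tie = dc.readout_color(self._fit(0.7, 0.3))
        assert pos == 520.0 and comp == 1 and not tie

    def test_swapped_weights(self):
        pos, comp, tie = dc.readout_color(self._fit(0.3, 0.7))
        assert pos == 1480.0 and comp == 2

    def test_exact_tie_flagged(self):
        pos, comp, tie = dc.readout_color(self._fit(0.5, 0.5), target=1480)
        assert tie
        assert pos == 1480.0  # tie broken toward target


class TestClassifyResponse:
    def test_near_target(self):
        assert dc.classify_response(530, 520, 1480, 2048) == "on_target"

    def test_near_nontarget(self):
        assert dc.classify_response(1450, 520, 1480, 2048) == "swap"

    def test_midpoint_convention(self):
        assert dc.classify_response(1000, 520, 1480, 2048) == "on_target"

    def test_label_symmetry(self, rng):
        for _ in range(50):
            readout = int(rng.integers(0, 2048))
            a = dc.classify_response(readout, 520, 1480, 2048)
            b = dc.classify_response(readout, 1480, 520, 2048)
            if a == "on_target" and b == "on_target":
                # both equidistant conventions fire only at exact midpoints
                d_t = min(abs(readout - 520), 2048 - abs(readout - 520))
                d_nt = min(abs(readout - 1480), 2048 - abs(readout - 1480))
                assert d_t == d_nt
            else:
                assert {a, b} == {"on_target", "swap"}

    def test_identical_items_rejected(self):
        with pytest.raises(ValueError):
            dc.classify_response(100, 5, 5, 2048)


def fake_swap_decode():
    return dc.DecodeResult(readout_position=185.0, chosen_component=2, label="swap")


class TestDiagnoseSwap:
    @pytest.mark.parametrize("category", ["memory", "attentional", "decoding"])
    def test_programmed_category_recovered(self, category):
        sim, proto, expected = fx.swap_scenario_fixture(category, seed=5)
        diag = dc.diagnose_swap(sim, proto, fake_swap_decode())
        assert diag.category == expected

    def test_memory_reversal_time_located(self):
        sim, proto, _ = fx.swap_scenario_fixture("memory", seed=8, delay_ms=3000.0)
        t_rev = proto.delay_window[0] + 1500.0
        diag = dc.diagnose_swap(sim, proto, fake_swap_decode())
        assert diag.category == "memory"
        assert diag.reversal_time is not None
        assert abs(diag.reversal_time - t_rev) <= 150.0

    def test_requires_swap_label(self):
        sim, proto, _ = fx.swap_scenario_fixture("memory", seed=2)
        good = dc.DecodeResult(readout_position=65.0, chosen_component=1, label="on_target")
        with pytest.raises(ValueError):
            dc.diagnose_swap(sim, proto, good)

    def test_categories_exhaustive_and_exclusive(self):
        # every (early, late) sign combination maps to exactly one category
        for seed in range(10):
            for category in ("memory", "attentional", "decoding"):
                sim, proto, _ = fx.swap_scenario_fixture(category, seed=seed)
                diag = dc.diagnose_swap(sim, proto, fake_swap_decode())
                assert diag.category in ("memory", "attentional", "decoding")


class TestDecoderRecoveryProperty:
    def test_heavier_bump_wins(self, rng):
        n = 1024
        wins = 0
        trials = 300
        for _ in range(trials):
            c1, c2 = 260, 770
            m1 = rng.uniform(1.0, 5.0)
            ratio = rng.uniform(1.2, 3.0)
            heavier_first = rng.random() < 0.5
            masses = (m1 * ratio, m1) if heavier_first else (m1, m1 * ratio)
            rates = (
                gaussian_profile(n, c1, 20.0, masses[0])
                + gaussian_profile(n, c2, 20.0, masses[1])
                + rng.uniform(0, 0.02, n)
            )
            fit = dc.fit_two_gaussians(profile_from(rates), (c1, c2))
            pos, _, _ = dc.readout_color(fit)
            heavy_center = c1 if heavier_first else c2
            if abs(pos - heavy_center) < 50:
                wins += 1
        assert wins / trials >= 0.99
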
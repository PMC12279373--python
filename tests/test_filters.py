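"""Linear-filter estimation, behavior prediction, autocorrelation."""

import numpy as np
import pytest

from steerlab import filters as F
from steerlab.synthetic import SimConfig, biphasic_kernel, simulate_steering_session

from conftest import make_ts


def _kernel_as_filter(kernel, rate):
    """Wrap a causal kernel as a two-sided LinearFilter (zeros at negative lags)."""
    lags = np.concatenate([-np.arange(1, kernel.size + 1)[::-1], np.arange(kernel.size)]) / rate
    values = np.concatenate([np.zeros(kernel.size), kernel])
    return F.LinearFilter(lags=lags, values=values, rate=rate)


def _lstsq_kernel(x, y, n_lags):
    """Time-domain least-squares filter on lagged input copies (oracle)."""
    rows = [np.roll(x, lag) for lag in range(n_lags)]
    design = np.vstack(rows).T[n_lags:-1]
    coef, *_ = np.linalg.lstsq(design, y[n_lags:-1], rcond=None)
    return coef


class TestEstimateFilter:
    def test_identity_system_gives_pulse_at_zero_lag(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40_000)
        filt = F.estimate_filter(make_ts(x), make_ts(x.copy()))
        peak_lag = filt.lags[np.argmax(filt.values)]
        assert abs(peak_lag) < 1e-9
        # mass concentrates at 0 (Slepian smoothing spreads the pulse)
        near = np.abs(filt.lags) <= 0.05
        assert filt.values[near].sum() == pytest.approx(1.0, abs=0.1)

    def test_recovers_known_kernel_against_lstsq_oracle(self):
        rng = np.random.default_rng(1)
        rate = 100.0
        x = rng.standard_normal(60_000)
        k = biphasic_kernel(rate)
        clean = np.convolve(x, k)[: x.size]
        noise = rng.standard_normal(x.size) * (clean.std() / 5.0)  # SNR 5
        y = clean + noise
        filt = F.estimate_filter(make_ts(x), make_ts(y))
        est = filt.values[(filt.lags >= 0) & (filt.lags < k.size / rate)]
        m = min(est.size, k.size)
        assert np.corrcoef(est[:m], k[:m])[0, 1] >= 0.95
        oracle = _lstsq_kernel(x, y, k.size)
        assert np.corrcoef(est[:m], oracle[:m])[0, 1] >= 0.95

    def test_independent_output_stays_at_noise_floor(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50_000)
        y = rng.standard_normal(50_000)
        filt = F.estimate_filter(make_ts(x), make_ts(y))
        # noise floor from acausal far lags (the true filter is zero anyway;
        # compare peak to the spread of the lag-reversed surrogate)
        surrogate = F.estimate_filter(make_ts(x), make_ts(y[::-1].copy()))
        floor = np.std(surrogate.values)
        assert np.max(np.abs(filt.values)) < 5.0 * floor

    def test_linearity_in_input_scale(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20_000)
        y = np.convolve(x, biphasic_kernel(100.0))[: x.size]
        f1 = F.estimate_filter(make_ts(x), make_ts(y))
        f2 = F.estimate_filter(make_ts(3.0 * x), make_ts(y))
        np.testing.assert_allclose(f2.values, f1.values / 3.0, atol=1e-6)

    def test_hop_one_agrees_with_default_hop(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20_000)
        y = np.convolve(x, biphasic_kernel(100.0))[: x.size]
        fast = F.estimate_filter(make_ts(x), make_ts(y))
        exact = F.estimate_filter(make_ts(x), make_ts(y), hop=1)
        rms = np.sqrt(np.mean((fast.values - exact.values) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(exact.values ** 2))

    def test_powerless_input_rejected(self):
        with pytest.raises(ValueError):
            F.estimate_filter(make_ts(np.zeros(1_000)), make_ts(np.zeros(1_000)))


class TestPredictBehavior:
    def test_self_consistency_noise_free(self):
        """Observed traces generated from the filter itself are explained."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30_000)
        filt = _kernel_as_filter(biphasic_kernel(100.0), 100.0)
        y = F.apply_filter(filt, make_ts(x))
        _, report = F.predict_behavior(filt, make_ts(x), y)
        assert report.r2 >= 0.999
        assert 0.1 <= report.filter_length_used_s <= 4.0

    def test_pure_noise_target_has_no_explained_variance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20_000)
        y = np.convolve(x, biphasic_kernel(100.0))[: x.size]
        filt = F.estimate_filter(make_ts(x), make_ts(y))
        noise = rng.standard_normal(20_000)
        _, report = F.predict_behavior(filt, make_ts(x), make_ts(noise))
        assert report.r2 <= 0.05

    def test_r2_degrades_monotonically_with_noise(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(20_000)
        k = biphasic_kernel(100.0)
        clean = np.convolve(x, k)[: x.size]
        filt = F.estimate_filter(make_ts(x), make_ts(clean))
        r2s = []
        for mult in (0.0, 0.5, 1.0, 2.0, 4.0):
            y = clean + rng.standard_normal(x.size) * mult * clean.std()
            _, report = F.predict_behavior(filt, make_ts(x), make_ts(y))
            r2s.append(report.r2)
        assert all(a > b for a, b in zip(r2s, r2s[1:]))


class TestDualPrediction:
    def test_zero_partner_is_identity(self):
        a = make_ts(np.arange(100.0))
        z = make_ts(np.zeros(100))
        np.testing.assert_array_equal(F.dual_prediction(a, z).values, a.values)

    def test_mirrored_predictions_cancel(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(500)
        out = F.dual_prediction(make_ts(x), make_ts(-x))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_two_cell_sum_beats_single_cell_noise_free(self):
        cfg = SimConfig(duration_s=200.0, seed=9, make_voltage=False,
                        noise_sd={"v_r": 0.0, "v_s": 0.0, "v_f": 0.0},
                        immobility_bout_rate_per_min=0.0)
        sess = simulate_steering_session(cfg)
        vr = sess.kinematics.v_r
        r2 = {}
        preds = {}
        for cell in ("mono_R", "bi_R"):
            filt = F.estimate_filter(sess.true_rate[cell], vr)
            preds[cell], rep = F.predict_behavior(filt, sess.true_rate[cell], vr)
            r2[cell] = rep.r2
        dual = F.dual_prediction(preds["mono_R"], preds["bi_R"])
        i0 = int(0.2 * vr.n)
        dual_r2 = F.r_squared(dual.values[i0:], vr.values[i0:])
        assert dual_r2 >= max(r2.values()) - 1e-6


class TestAutocorrelation:
    def test_white_noise_off_peak_bound(self):
        rng = np.random.default_rng(10)
        n = 40_000
        lags, acf = F.autocorrelation(make_ts(rng.standard_normal(n)), 0.5)
        assert np.max(np.abs(acf[1:])) < 4.0 / np.sqrt(n)

    def test_sine_period_peak(self):
        t = np.arange(10_000) / 100.0
        lags, acf = F.autocorrelation(make_ts(np.sin(2 * np.pi * t / 2.0)), 3.0)
        peak = lags[1 + np.argmax(acf[np.abs(lags - 2.0) < 0.5].max() == acf[1:])]
        # the acf of a period-2s sine peaks at 2s
        sel = (lags > 1.5) & (lags < 2.5)
        assert lags[sel][np.argmax(acf[sel])] == pytest.approx(2.0, abs=0.02)

    def test_unity_at_zero_lag(self):
        rng = np.random.default_rng(11)
        _, acf = F.autocorrelation(make_ts(rng.standard_normal(1_000)), 0.1)
        assert acf[0] == pytest.approx(1.0, abs=1e-12)


def test_white_noise_filter_equals_scaled_cross_correlation():
    """With a white input, the cross-spectral ratio reduces to the
    cross-correlation divided by the input variance (compared before the
    final Slepian smoothing, which neither side receives here; the kernel
    is compact relative to the 4 s window so finite-window lag attenuation
    is fully corrected)."""
    from scipy.signal import correlate

    from steerlab.synthetic import monophasic_kernel

    rng = np.random.default_rng(12)
    x = rng.standard_normal(400_000)
    k = monophasic_kernel(100.0, tau_s=0.08, support_s=0.4)
    y = np.convolve(x, k)[: x.size]
    filt = F.estimate_filter(make_ts(x), make_ts(y), bandwidth_hz=None)
    n_lags = k.size
    xc = correlate(y - y.mean(), x - x.mean(), mode="full", method="fft")
    mid = x.size - 1
    cross = xc[mid:mid + n_lags] / (x.size * x.var())
    est = filt.values[(filt.lags >= 0) & (filt.lags < n_lags / 100.0)][:n_lags]
    rms = np.sqrt(np.mean((est - cross) ** 2)) / np.sqrt(np.mean(cross ** 2))
    assert rms < 0.02
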
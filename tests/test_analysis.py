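"""Spike detection, HRF feature extraction, curve fits and the linear
convolution formalism."""

import numpy as np
import pytest

from nvcsim import analysis
from nvcsim.analysis import (calibrate_gain, canonical_hrf, convolve_predict,
                             detect_spikes, fit_canonical_hrf,
                             fit_log_frequency, fit_saturating, hrf_features)


def gaussian_train(times, amp, width, t_end, dt=0.01, basal=0.05):
    t = np.arange(0.0, t_end, dt)
    ca = np.full_like(t, basal)
    for tc in times:
        ca += amp * np.exp(-0.5 * ((t - tc) / width) ** 2)
    return t, ca


class TestDetectSpikes:
    def test_synthetic_train_frequency(self):
        times = [10.0, 20.0, 30.0, 40.0, 50.0]
        t, ca = gaussian_train(times, 0.6, 0.8, 60.0)
        st = detect_spikes(t, ca, basal=0.05)
        assert st.n == 5
        assert st.f_Ca == pytest.approx(0.1, rel=1e-3)
        assert np.allclose(st.times, times, atol=0.05)
        assert np.allclose(st.amplitudes, 0.65, atol=0.02)

    def test_subthreshold_rise_is_not_a_spike(self):
        t, ca = gaussian_train([10.0], 0.15, 1.0, 30.0)
        assert detect_spikes(t, ca, basal=0.05).n == 0

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            detect_spikes(np.array([]), np.array([]), 0.05)

    def test_agrees_with_naive_scan(self, std_event):
        """Hysteresis detection matches a brute-force local-maxima
        scan above the same threshold."""
        t = std_event.time
        ca = std_event["Ca_uM"]
        basal = std_event.rest["Ca"]
        st = detect_spikes(t, ca, basal)
        thr = basal + 0.5 * (ca.max() - basal)
        naive = [k for k in range(1, len(ca) - 1)
                 if ca[k] >= thr and ca[k] >= ca[k - 1]
                 and ca[k] > ca[k + 1]]
        # merge plateau-adjacent naive maxima
        merged = []
        for k in naive:
            if not merged or t[k] - merged[-1] > 1.0:
                merged.append(t[k])
        assert st.n == len(merged)
        assert np.allclose(st.times, merged, atol=0.1)


class TestHRFFeatures:
    def test_pure_double_gamma_timing(self):
        # positive lobe of the canonical form peaks at a1 * b1
        t = np.arange(0.0, 40.0, 0.01)
        y = canonical_hrf(t, 6.0, 6.0, 1.0, 0.07, 18.0, 12.0, 1.5)
        f = hrf_features(t, y, stim_onset=0.0)
        assert f.t_peak == pytest.approx(6.0, abs=0.02)
        assert f.undershoot < 0
        assert 0 < f.t_ON < f.t_peak

    def test_translation_equivariance(self):
        t = np.arange(0.0, 60.0, 0.01)
        y = canonical_hrf(t - 5.0, 6.0, 6.0, 1.0, 0.07, 18.0, 12.0, 1.5)
        f5 = hrf_features(t, y, stim_onset=5.0)
        y2 = canonical_hrf(t - 12.0, 6.0, 6.0, 1.0, 0.07, 18.0, 12.0, 1.5)
        f12 = hrf_features(t, y2, stim_onset=12.0)
        assert f12.t_ON == pytest.approx(f5.t_ON, abs=0.02)
        assert f12.t_peak == pytest.approx(f5.t_peak, abs=0.02)

    def test_flat_trace_raises(self):
        t = np.arange(0.0, 40.0, 0.01)
        with pytest.raises(analysis.NoResponseError):
            hrf_features(t, np.zeros_like(t), 0.0)


class TestCanonicalFit:
    TRUE = (6.0, 6.0, 1.0, 0.07, 18.0, 12.0, 1.5)

    def test_self_recovery(self):
        t = np.arange(0.0, 40.0, 0.05)
        y = canonical_hrf(t, *self.TRUE)
        fit = fit_canonical_hrf(t, y, seed=3)
        assert fit.r_squared > 0.9999
        pred = canonical_hrf(t, fit.d1, fit.a1, fit.b1, fit.c, fit.d2,
                             fit.a2, fit.b2)
        assert np.abs(pred - y / y.max()).max() < 1e-3
        # the well-identified features: both lobe peak positions
        assert fit.a1 * fit.b1 == pytest.approx(6.0, abs=0.05)
        assert fit.a2 * fit.b2 == pytest.approx(18.0, abs=0.5)

    def test_multistart_stability(self):
        t = np.arange(0.0, 40.0, 0.05)
        y = canonical_hrf(t, *self.TRUE)
        fits = [fit_canonical_hrf(t, y, seed=s) for s in (0, 7, 42)]
        peaks = [f.a1 * f.b1 for f in fits]
        assert max(peaks) - min(peaks) < 0.05


class TestCurveFits:
    def test_log_fit_exact_recovery(self):
        # coefficients of the frequency-coding description
        A, x0, B = 0.12, 0.58, 0.05
        x = np.linspace(0.7, 3.0, 12)
        f = A * np.log((x - x0) / B)
        A2, x02, B2, r2 = fit_log_frequency(x, f, seed=0)
        assert A2 == pytest.approx(A, abs=1e-6)
        assert x02 == pytest.approx(x0, abs=1e-6)
        assert B2 == pytest.approx(B, abs=1e-6)
        assert r2 > 1 - 1e-12

    def test_log_fit_needs_enough_points(self):
        with pytest.raises(analysis.FitError):
            fit_log_frequency(np.array([1.0, 2.0, 3.0]),
                              np.array([0.1, 0.2, 0.3]))

    def test_saturating_fit_exponent_recovery_under_noise(self):
        """a x^p/(x^p + b) exponent recovered to within 0.05 at 1%
        noise, across 100 replicates."""
        a, p, b = 3.69, 1.08, 0.95
        x = np.linspace(0.3, 6.0, 15)
        y0 = a * x ** p / (x ** p + b)
        rng = np.random.default_rng(12345)
        errs = []
        for rep in range(100):
            y = y0 * (1.0 + 0.01 * rng.standard_normal(len(x)))
            _, p_hat, _, _ = fit_saturating(x, y, seed=rep, n_starts=4)
            errs.append(abs(p_hat - p))
        errs = np.array(errs)
        assert np.median(errs) < 0.05
        assert (errs < 0.05).mean() > 0.8


class TestConvolution:
    def test_impulse_identity(self):
        kernel = np.array([0.0, 1.0, 0.5, 0.25])
        driver = np.zeros(10)
        driver[0] = 1.0
        out = convolve_predict(kernel, driver, dt=1.0)
        assert np.allclose(out[:4], kernel)

    def test_linearity_and_shift(self):
        rng = np.random.default_rng(0)
        kernel = rng.random(30)
        d1, d2 = rng.random(100), rng.random(100)
        a = convolve_predict(kernel, d1 + d2, 0.1)
        b = (convolve_predict(kernel, d1, 0.1)
             + convolve_predict(kernel, d2, 0.1))
        assert np.allclose(a, b, atol=1e-12)
        shifted = np.roll(d1, 10)
        shifted[:10] = 0.0
        sa = convolve_predict(kernel, shifted, 0.1)
        ref = convolve_predict(kernel, d1, 0.1)
        assert np.allclose(sa[10:], ref[:-10], atol=1e-12)

    def test_gain_calibration_least_squares(self):
        kernel = np.array([0.0, 1.0, 0.5])
        driver = np.sin(np.linspace(0, 6, 200)) ** 2
        target = convolve_predict(kernel, driver, 0.05, gain=2.5)
        assert calibrate_gain(kernel, driver, 0.05,
                              target) == pytest.approx(2.5)
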
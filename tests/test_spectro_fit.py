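"""Spectroscopy fitting: parameter recovery, invariances, spectra."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from naqms.spectro_fit import (EchoAmplitudeSeries, Fid, fid_to_spectrum,
                               fit_biexp_magnitude, fit_biexp_t2star,
                               fit_mono_t2, fit_water_amplitude, peak_area)
from naqms.synthetic_data import DP_TRUTH, HV_TRUTH, make_echo_series, make_fid
from conftest import seeds


class TestBiexpT2Star:
    @pytest.mark.parametrize("truth", [HV_TRUTH, DP_TRUTH], ids=["hv", "dp"])
    def test_noiseless_recovery_to_a_tenth_percent(self, truth):
        fit = fit_biexp_t2star(make_fid(truth))
        assert fit.converged
        assert fit.t2s_slow == pytest.approx(truth.true_t2s_slow, rel=1e-3)
        assert fit.t2s_fast == pytest.approx(truth.true_t2s_fast, rel=1e-3)
        assert fit.m_fast_fraction == pytest.approx(
            truth.true_m_fast_fraction, abs=1e-3)

    def test_single_exponential_limit(self):
        truth = replace(HV_TRUTH, true_m_fast_fraction=0.0)
        fit = fit_biexp_t2star(make_fid(truth))
        assert fit.m_fast_fraction < 0.01
        assert fit.t2s_slow == pytest.approx(13.4, rel=1e-3)

    def test_nested_model_rss_matches_monoexponential(self):
        truth = replace(HV_TRUTH, true_m_fast_fraction=0.0)
        fid = make_fid(truth, n_samples=256)
        bi = fit_biexp_t2star(fid)
        mono = fit_mono_t2(EchoAmplitudeSeries(fid.times, fid.magnitude))
        assert abs(bi.fit_rss - mono.fit_rss) < 1e-9

    def test_noisy_recovery_median_within_bands(self):
        # Small replicate set; the full 200-seed run lives in the
        # acceptance suite.
        mf = HV_TRUTH.true_m_fast_fraction
        env0 = (mf * np.exp(-0.16 / 2.2) + (1 - mf) * np.exp(-0.16 / 13.4))
        out = []
        for s in seeds(30):
            fit = fit_biexp_t2star(make_fid(HV_TRUTH, noise_sd=env0 / 50,
                                            seed=s))
            out.append((fit.t2s_slow, fit.t2s_fast, fit.m_fast_fraction))
        med = np.median(np.array(out), axis=0)
        assert med[0] == pytest.approx(13.4, rel=0.05)
        assert med[1] == pytest.approx(2.2, rel=0.15)
        assert med[2] == pytest.approx(0.46, abs=0.05)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, scale):
        fid = make_fid(HV_TRUTH, n_samples=256, noise_sd=0.01, seed=4)
        base = fit_biexp_t2star(fid)
        scaled = fit_biexp_t2star(Fid(fid.samples * scale, fid.dwell, fid.t0))
        assert scaled.t2s_fast == pytest.approx(base.t2s_fast, rel=1e-5)
        assert scaled.t2s_slow == pytest.approx(base.t2s_slow, rel=1e-5)
        assert scaled.m_fast == pytest.approx(base.m_fast * scale, rel=1e-5)
        assert scaled.noise_offset == pytest.approx(
            base.noise_offset * scale, rel=1e-4)

    def test_sample_order_invariance(self, rng):
        fid = make_fid(HV_TRUTH, n_samples=128, noise_sd=0.02, seed=9)
        t, y = fid.times, fid.magnitude
        perm = rng.permutation(t.size)
        a = fit_biexp_magnitude(t, y)
        b = fit_biexp_magnitude(t[perm], y[perm])
        assert b.t2s_slow == pytest.approx(a.t2s_slow, rel=1e-6)
        assert b.t2s_fast == pytest.approx(a.t2s_fast, rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_biexp_magnitude(np.arange(5.0), np.ones(5))


class TestSpectrum:
    def test_decaying_exponential_gives_sqrt_lorentzian_peak_at_zero(self):
        tau = 10.0  # ms
        fid = Fid(np.exp(-np.arange(1024) * 0.125 / tau), dwell=0.125)
        spec = fid_to_spectrum(fid, zero_fill=4)
        mag = spec.magnitude
        assert abs(spec.frequencies[np.argmax(mag)]) < 20.0
        # continuous-FT closed form |1/(1/tau + 2 pi i f)| at the peak
        dt_s = 0.125e-3
        expected0 = 1.0 / (1.0 - np.exp(-dt_s / (tau * 1e-3))) - 0.5
        assert mag.max() == pytest.approx(expected0, rel=1e-3)

    def test_linearity_in_amplitude(self):
        fid = Fid(np.exp(-np.arange(128) * 0.125 / 5.0), dwell=0.125)
        double = Fid(2 * fid.samples, dwell=0.125)
        s1 = fid_to_spectrum(fid).values
        s2 = fid_to_spectrum(double).values
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_zero_fill_below_one_rejected(self):
        fid = Fid(np.ones(16), dwell=0.1)
        with pytest.raises(ValueError):
            fid_to_spectrum(fid, zero_fill=0.5)


class TestPeakArea:
    def _lorentzian_fid(self, amplitude=1.0, tau=10.0, n=2048):
        return Fid(amplitude * np.exp(-np.arange(n) * 0.125 / tau), dwell=0.125)

    def test_zero_spectrum_gives_zero(self):
        spec = fid_to_spectrum(Fid(np.zeros(64), dwell=0.125))
        assert peak_area(spec, (-500, 500)) == 0.0

    def test_linearity_within_one_percent(self):
        a1 = peak_area(fid_to_spectrum(self._lorentzian_fid(1.0)), (-300, 300))
        a2 = peak_area(fid_to_spectrum(self._lorentzian_fid(2.0)), (-300, 300))
        assert a2 / a1 == pytest.approx(2.0, rel=0.01)

    def test_amplitude_sweep_proportionality(self):
        amps = np.array([0.5, 1, 2, 3, 5])
        areas = np.array([
            peak_area(fid_to_spectrum(self._lorentzian_fid(a)), (-300, 300))
            for a in amps])
        r = np.corrcoef(amps, areas)[0, 1]
        assert r ** 2 > 0.999

    def test_window_widening_matches_closed_form_tail(self):
        # magnitude of the FT of exp(-t/tau) is 1/sqrt((1/tau)^2+(2 pi f)^2);
        # its integral over (-W, W) is arcsinh(2 pi W tau) / pi.
        tau_ms = 10.0
        tau_s = tau_ms * 1e-3
        lw = 1.0 / (np.pi * tau_s)     # full width at half max, Hz
        fid = self._lorentzian_fid(1.0, tau_ms, n=4096)
        spec = fid_to_spectrum(fid, zero_fill=2)
        dt_s = 0.125e-3

        def analytic(width_hz):
            return np.arcsinh(2 * np.pi * width_hz * tau_s) / np.pi / dt_s

        a3 = peak_area(spec, (-3 * lw, 3 * lw), baseline=False)
        a5 = peak_area(spec, (-5 * lw, 5 * lw), baseline=False)
        expected_ratio = analytic(5 * lw) / analytic(3 * lw)
        assert a5 / a3 == pytest.approx(expected_ratio, rel=0.01)

    def test_empty_window_rejected(self):
        spec = fid_to_spectrum(self._lorentzian_fid())
        with pytest.raises(ValueError):
            peak_area(spec, (300, -300))


class TestWaterAmplitude:
    def _damped_sinusoid(self, amplitude=1.0, freq=0.0, tau=40.0, phase=0.3,
                         noise_sd=0.0, seed=None, n=512):
        t = 0.25 * np.arange(n)
        s = amplitude * np.exp(1j * phase) * np.exp(
            (2j * np.pi * freq / 1000.0 - 1.0 / tau) * t)
        if noise_sd:
            g = np.random.default_rng(seed)
            s = s + g.normal(0, noise_sd, n) + 1j * g.normal(0, noise_sd, n)
        return Fid(s, dwell=0.25, nucleus="1H")

    def test_amplitude_recovery_exact(self):
        fit = fit_water_amplitude(self._damped_sinusoid(amplitude=1.0))
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)

    def test_frequency_offset_recovery(self):
        fit = fit_water_amplitude(self._damped_sinusoid(freq=50.0))
        assert fit.frequency_hz == pytest.approx(50.0, abs=1e-3)

    def test_noisy_amplitude_bias_below_two_percent(self):
        amps = [fit_water_amplitude(
            self._damped_sinusoid(amplitude=1.0, freq=20.0,
                                  noise_sd=1 / 30, seed=s)).amplitude
                for s in seeds(100, entropy=2)]
        assert abs(np.mean(amps) - 1.0) < 0.02


class TestMonoT2:
    def test_printed_echo_times_recover_hv_t2(self):
        fit = fit_mono_t2(make_echo_series(29.3))
        assert not fit.flagged
        assert fit.t2 == pytest.approx(29.3, rel=1e-6)

    def test_constant_amplitudes_flagged(self):
        series = EchoAmplitudeSeries(np.array([30.0, 40, 60, 80]),
                                     np.ones(4))
        assert fit_mono_t2(series).flagged

    def test_log_linear_oracle_agreement(self):
        series = make_echo_series(47.0, s0=3.0)
        slope, intercept = np.polyfit(series.echo_times,
                                      np.log(series.amplitudes), 1)
        fit = fit_mono_t2(series)
        assert fit.t2 == pytest.approx(-1.0 / slope, rel=1e-6)
        assert fit.s0 == pytest.approx(np.exp(intercept), rel=1e-6)

    def test_two_echoes_rejected(self):
        with pytest.raises(ValueError):
            fit_mono_t2(EchoAmplitudeSeries(np.array([30.0, 40.0]),
                                            np.array([1.0, 0.9])))
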
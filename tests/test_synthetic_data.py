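"""Generator contracts: closed-form values, seeded determinism, shapes."""

import numpy as np
import pytest
from dataclasses import replace

from naqms.dixon_ff import fat_phase_factors
from naqms.synthetic_data import (DP_TRUTH, HV_TRUTH, AcquisitionTimeline,
                                  CohortSpec, SubjectTruth, make_cohort,
                                  make_dixon_volume, make_dynamic_series,
                                  make_echo_series, make_fid,
                                  make_sodium_image)


def mono_truth(t2_slow: float = 13.4) -> SubjectTruth:
    """A purely slow-relaxing subject (single-exponential limit)."""
    return replace(HV_TRUTH, true_m_fast_fraction=0.0, true_t2s_slow=t2_slow)


class TestMakeFid:
    def test_single_exponential_limit_decays_by_e(self):
        truth = mono_truth(13.4)
        fid = make_fid(truth, amplitude=1.0, n_samples=256, dwell=0.1, t0=0.0)
        m = fid.magnitude
        k = 134  # t = 13.4 ms = one slow time constant exactly
        assert m[k] / m[0] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_magnitude_at_t0_matches_envelope(self, hv_truth):
        fid = make_fid(hv_truth, amplitude=3.7)
        mf = hv_truth.true_m_fast_fraction
        expected = 3.7 * (mf * np.exp(-0.16 / hv_truth.true_t2s_fast)
                          + (1 - mf) * np.exp(-0.16 / hv_truth.true_t2s_slow))
        assert fid.magnitude[0] == pytest.approx(expected, rel=1e-12)

    def test_seeded_determinism(self, hv_truth):
        a = make_fid(hv_truth, noise_sd=0.05, seed=1)
        b = make_fid(hv_truth, noise_sd=0.05, seed=1)
        c = make_fid(hv_truth, noise_sd=0.05, seed=2)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    @pytest.mark.parametrize("kwargs", [
        {"amplitude": 0.0}, {"amplitude": -1.0}, {"dwell": 0.0},
        {"n_samples": 4}, {"noise_sd": -0.1},
    ])
    def test_invalid_inputs_rejected(self, hv_truth, kwargs):
        with pytest.raises(ValueError):
            make_fid(hv_truth, **kwargs)


class TestMakeEchoSeries:
    def test_closed_form_first_echo(self):
        series = make_echo_series(t2=30.0, s0=1.0)
        assert series.amplitudes[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_log_amplitudes_linear_in_te(self):
        series = make_echo_series(t2=29.3, s0=2.0)
        slope, _ = np.polyfit(series.echo_times, np.log(series.amplitudes), 1)
        assert slope == pytest.approx(-1.0 / 29.3, rel=1e-10)

    def test_nonpositive_t2_rejected(self):
        with pytest.raises(ValueError):
            make_echo_series(t2=0.0)


class TestMakeDynamicSeries:
    def test_hv_sodium_decay_segment_follows_half_life(self, hv_truth,
                                                       timeline_60min):
        series = make_dynamic_series(hv_truth, timeline_60min, "na_amplitude")
        t, v, b = series.timestamps, series.values, series.baseline_value
        post = t >= hv_truth.dyn_peak_time
        elev = v[post] - b
        ratios = elev[1:] / elev[:-1]
        dt = np.diff(t[post])
        np.testing.assert_allclose(ratios, 2.0 ** (-dt / 636.0), rtol=1e-12)

    def test_hv_sodium_peak_strictly_after_first_point(self, hv_truth,
                                                       timeline_60min):
        series = make_dynamic_series(hv_truth, timeline_60min, "na_amplitude")
        assert int(np.argmax(series.values)) > 0
        # unimodal: rises then falls
        d = np.diff(series.values)
        k = int(np.argmax(series.values))
        assert np.all(d[:k] > 0) and np.all(d[k:] < 0)

    def test_hv_water_t2_maximal_at_first_timepoint(self, hv_truth,
                                                    timeline_60min):
        series = make_dynamic_series(hv_truth, timeline_60min, "water_t2")
        assert int(np.argmax(series.values)) == 0

    def test_dp_series_near_flat(self, dp_truth, timeline_60min):
        for modality in ("na_amplitude", "water_t2"):
            series = make_dynamic_series(dp_truth, timeline_60min, modality)
            assert series.values.max() / series.values.min() <= 1.1

    def test_unknown_modality_rejected(self, hv_truth, timeline_60min):
        with pytest.raises(ValueError):
            make_dynamic_series(hv_truth, timeline_60min, "b0_drift")

    def test_interleaved_cadence(self, timeline_60min):
        na = timeline_60min.sodium_times()
        h = timeline_60min.proton_times()
        assert na[0] == pytest.approx(129.0 / 2)
        assert h[0] == pytest.approx(129.0 + 45.0 / 2)
        assert np.all(np.diff(na) == pytest.approx(174.0))
        assert len(na) >= 10


class TestMakeDixonVolume:
    def test_pure_water_magnitude_is_t2star_decay_only(self):
        vol = make_dixon_volume(np.zeros((2, 2)), water_t2star=25.0)
        mags = np.abs(vol.echoes)
        expected = np.exp(-vol.echo_times / 25.0)
        np.testing.assert_allclose(mags[:, 0, 0], expected, rtol=1e-12)

    def test_pure_fat_equals_fat_model_exactly(self):
        vol = make_dixon_volume(np.full((1, 1), 100.0), water_t2star=25.0)
        c = fat_phase_factors(vol.echo_times, 3.0)
        expected = c * np.exp(-vol.echo_times / 25.0)
        np.testing.assert_allclose(vol.echoes[:, 0, 0], expected, rtol=1e-12)

    def test_out_of_range_ff_rejected(self):
        with pytest.raises(ValueError):
            make_dixon_volume(np.array([[101.0]]))


class TestMakeCohort:
    def test_large_cohort_mean_near_generating_mean(self):
        cohort = make_cohort(CohortSpec(n_per_group=200, seed=3))
        hv = cohort.table[cohort.table.group == "HV"]
        se = 3.1 / np.sqrt(200)
        assert abs(hv.true_na_concentration.mean() - 19.6) < 3 * se

    def test_zero_sd_gives_identical_subjects(self):
        spec = CohortSpec(n_per_group=5, seed=0)
        for g in spec.group_params:
            spec.group_params[g] = {k: (m, 0.0)
                                    for k, (m, _) in spec.group_params[g].items()}
        cohort = make_cohort(spec)
        for g in ("HV", "DP"):
            sub = cohort.table[cohort.table.group == g]
            assert sub.true_na_concentration.nunique() == 1
            assert sub.true_t2s_fast.nunique() == 1

    def test_seeded_determinism_and_physical_bounds(self):
        a = make_cohort(CohortSpec(n_per_group=30, seed=11))
        b = make_cohort(CohortSpec(n_per_group=30, seed=11))
        assert a.table.equals(b.table)
        assert (a.table.true_na_concentration > 0).all()
        assert a.table.true_ff.between(0, 100).all()
        assert (a.table.true_t2s_fast < a.table.true_t2s_slow).all()
        assert a.table.true_m_fast_fraction.between(0, 1).all()

    def test_rendered_acquisitions_cover_every_subject(self):
        cohort = make_cohort(CohortSpec(n_per_group=2, seed=1, render=True))
        assert set(cohort.acquisitions) == {t.subject_id for t in cohort.truths}
        acq = next(iter(cohort.acquisitions.values()))
        assert acq.fid.samples.size == 1024
        assert acq.na_series.modality == "na_amplitude"


class TestMakeSodiumImage:
    def test_noiseless_region_signals(self, hv_truth):
        scene = make_sodium_image(hv_truth, n_slices=2)
        img = scene.image
        ta_vals = img[scene.masks["ta"]]
        assert np.allclose(ta_vals, ta_vals[0])
        assert np.all(img[scene.masks["noise"]] == 0)

    def test_target_snr_sets_noise(self, hv_truth):
        scene = make_sodium_image(hv_truth, snr=44.0, seed=5)
        assert scene.noise_sd > 0
        with pytest.raises(ValueError):
            make_sodium_image(hv_truth, snr=44.0, noise_sd=0.1)
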
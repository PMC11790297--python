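"""Recovery kinetics, peak finding and per-timepoint baseline tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from naqms.dynamics import (DynamicSeries, compare_to_baseline, fit_recovery,
                            fit_t2_decline, group_mean_series,
                            half_life_to_time_constant, time_to_peak)
from naqms.synthetic_data import (DP_TRUTH, HV_TRUTH, AcquisitionTimeline,
                                  CohortSpec, make_cohort, make_dynamic_series)
from dataclasses import replace


def model_series(t, baseline, amplitude, half_life, modality="na_amplitude"):
    v = baseline + amplitude * 2.0 ** (-t / half_life)
    return DynamicSeries(t, v, modality, baseline_value=baseline)


class TestFitRecovery:
    def test_generator_half_life_recovered(self, hv_truth, timeline_60min):
        truth = replace(hv_truth, dyn_recovery_halflife=300.0)
        series = make_dynamic_series(truth, timeline_60min, "na_amplitude")
        fit = fit_recovery(series, from_peak=True)
        assert fit.half_life == pytest.approx(300.0, rel=1e-4)

    def test_constant_series_flagged_degenerate(self):
        t = np.arange(10) * 100.0
        series = DynamicSeries(t, np.full(10, 5.0), "na_amplitude", 5.0)
        fit = fit_recovery(series, from_peak=False)
        assert fit.flagged

    def test_time_shift_invariance(self):
        t = np.linspace(0, 3000, 24)
        a = fit_recovery(model_series(t, 2.0, 1.0, 500.0), from_peak=True)
        b = fit_recovery(model_series(t + 777.0, 2.0, 1.0, 500.0),
                         from_peak=True)
        assert b.half_life == pytest.approx(a.half_life, rel=1e-9)

    def test_half_life_time_constant_conversion(self):
        assert half_life_to_time_constant(636.0) == pytest.approx(
            636.0 / np.log(2))


class TestFitT2Decline:
    def test_generator_half_life_recovered(self, hv_truth, timeline_60min):
        series = make_dynamic_series(hv_truth, timeline_60min, "water_t2")
        fit = fit_t2_decline(series)
        assert fit.half_life == pytest.approx(620.0, rel=0.01)

    def test_series_at_baseline_flagged(self):
        t = np.arange(8) * 174.0
        series = DynamicSeries(t, np.full(8, 29.3), "water_t2", 29.3)
        assert fit_t2_decline(series).flagged

    def test_amplitude_invariance_of_half_life(self):
        t = np.linspace(0, 2500, 16)
        full = fit_t2_decline(model_series(t, 29.3, 7.0, 620.0, "water_t2"))
        half = fit_t2_decline(model_series(t, 29.3, 3.5, 620.0, "water_t2"))
        assert half.half_life == pytest.approx(full.half_life, rel=1e-9)


class TestTimeToPeak:
    def test_hv_sodium_peak_near_generating_value(self, hv_truth):
        dense = AcquisitionTimeline(na_scan_duration=20.0, h_scan_duration=5.0,
                                    n_cycles=120)
        series = make_dynamic_series(hv_truth, dense, "na_amplitude")
        assert abs(time_to_peak(series) - 480.0) <= 25.0

    def test_monotone_decreasing_gives_first_timestamp(self):
        t = np.arange(6) * 10.0
        series = DynamicSeries(t, np.linspace(5, 1, 6), "na_amplitude", 1.0)
        assert time_to_peak(series) == 0.0

    def test_tied_maxima_resolve_to_earlier(self):
        t = np.arange(9) * 10.0
        v = np.array([0, 0, 3, 0, 0, 0, 3, 0, 0], dtype=float)
        series = DynamicSeries(t, v, "na_amplitude", 0.0)
        assert time_to_peak(series) == 20.0


def wilcoxon_exact_p_enumeration(diffs: np.ndarray) -> float:
    """Two-tailed exact signed-rank p by enumerating all sign patterns."""
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    n = len(diffs)
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= stat_obs:
            count += 1
    return count / 2 ** n


class TestCompareToBaseline:
    def _cohort_series(self, n=8, effect=0.0, seed=0):
        t = np.arange(10) * 174.0 + 64.5
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            base = 10.0 + rng.normal(0, 1)
            v = np.full(t.size, base) + effect + rng.normal(0, 0.1, t.size)
            out.append(DynamicSeries(t, v, "na_amplitude", base,
                                     subject_id=str(i), group="HV"))
        return out

    def test_values_at_baseline_never_significant(self):
        t = np.arange(10) * 174.0
        series = [DynamicSeries(t, np.full(10, 7.0), "na_amplitude", 7.0,
                                subject_id=str(i)) for i in range(6)]
        comps = compare_to_baseline(series)
        assert all(c.p_value == 1.0 and not c.significant and c.flagged
                   for c in comps)

    def test_exact_p_matches_sign_enumeration(self):
        # one timepoint, a printed six-subject difference set
        diffs = np.array([1.2, -0.4, 2.1, 0.9, -0.3, 1.7])
        t = np.array([0.0, 100.0, 200.0])
        series = [DynamicSeries(t, np.full(3, 5.0 + d), "na_amplitude", 5.0)
                  for d in diffs]
        comp = compare_to_baseline(series)[0]
        assert comp.p_value == pytest.approx(
            wilcoxon_exact_p_enumeration(diffs), abs=1e-12)

    def test_monotone_rescaling_leaves_p_unchanged(self):
        series = self._cohort_series(n=8, effect=0.25, seed=3)
        p0 = [c.p_value for c in compare_to_baseline(series)]
        transformed = [DynamicSeries(s.timestamps, np.exp(s.values / 10.0),
                                     s.modality, np.exp(s.baseline_value / 10.0))
                       for s in series]
        p1 = [c.p_value for c in compare_to_baseline(transformed)]
        # value - baseline signs/order are preserved under exp on this data
        np.testing.assert_allclose(p0, p1)

    def test_fewer_than_five_subjects_rejected(self):
        with pytest.raises(ValueError):
            compare_to_baseline(self._cohort_series(n=4))

    def test_power_on_synthetic_hv_cohorts(self):
        # rendered HV sodium series: peak elevation ~26% of baseline with
        # 5% measurement noise; early (near-peak) timepoints should
        # deviate significantly in nearly every 10-subject cohort
        hits = 0
        n_cohorts = 100
        for k in range(n_cohorts):
            cohort = make_cohort(CohortSpec(n_per_group=10, seed=1000 + k,
                                            render=True))
            series = [cohort.acquisitions[t.subject_id].na_series
                      for t in cohort.truths if t.group == "HV"]
            comps = compare_to_baseline(series)
            near_peak = min(range(len(comps)),
                            key=lambda i: abs(comps[i].timepoint - 480.0))
            hits += comps[near_peak].significant
        assert hits / n_cohorts >= 0.9


class TestGroupMean:
    def test_mean_of_identical_series_is_identity(self, hv_truth,
                                                  timeline_60min):
        s = make_dynamic_series(hv_truth, timeline_60min, "na_amplitude")
        mean = group_mean_series([s, s, s])
        np.testing.assert_allclose(mean.values, s.values)

    def test_differing_cadence_interpolated(self, hv_truth):
        tl_a = AcquisitionTimeline(post_exercise_span=3600)
        tl_b = AcquisitionTimeline(na_scan_duration=120.0,
                                   h_scan_duration=40.0, n_cycles=22)
        a = make_dynamic_series(hv_truth, tl_a, "na_amplitude")
        b = make_dynamic_series(hv_truth, tl_b, "na_amplitude")
        mean = group_mean_series([a, b])
        assert mean.timestamps[0] >= max(a.timestamps[0], b.timestamps[0])
        assert mean.values.shape == mean.timestamps.shape
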
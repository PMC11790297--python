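"""Post-exercise recovery dynamics.

Interleaved sodium / proton spectroscopy yields two time courses per
subject after exercise: the sodium signal amplitude (which rises for
several minutes before recovering) and the muscle water T2 (maximal at
the first post-exercise timepoint).  Both recoveries are summarised by a
half-life from a three-parameter exponential model

    v(t) = baseline + (s0_post - baseline) * 2**(-t / half_life)

with t re-zeroed at the start of the fitted segment.  Per-timepoint
deviation from each subject's pre-exercise baseline is tested with the
two-tailed Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

__all__ = [
    "DynamicSeries",
    "RecoveryFit",
    "TimepointComparison",
    "fit_recovery",
    "fit_t2_decline",
    "noise_sd_for_halflife_ci",
    "time_to_peak",
    "compare_to_baseline",
    "group_mean_series",
    "half_life_to_time_constant",
    "time_constant_to_half_life",
]

MODALITIES = ("na_amplitude", "water_t2")

#: Bounds on the fitted half-life, in seconds.
HALF_LIFE_BOUNDS = (10.0, 1.0e4)


@dataclass
class DynamicSeries:
    """One subject's post-exercise time course for a single modality."""

    timestamps: np.ndarray          # s since exercise end
    values: np.ndarray              # arbitrary units (Na) or ms (water T2)
    modality: str
    baseline_value: float           # pre-exercise value, same units
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.timestamps.size < 3:
            raise ValueError("need at least three timepoints")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class RecoveryFit:
    """Three-parameter exponential recovery fit.

    ``s0_post`` is the theoretical post-exercise value at the start of the
    fitted segment, ``half_life`` the time for the elevation above
    ``baseline`` to halve, and ``ci95_half_life`` the half-width of the
    95% confidence interval from the asymptotic covariance.
    """

    s0_post: float
    half_life: float
    baseline: float
    ci95_half_life: float
    fit_rss: float
    n_points: int
    segment_start: float            # absolute time (s) the fit was re-zeroed at
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class TimepointComparison:
    timepoint: float
    statistic: float
    p_value: float
    significant: bool
    n: int
    flagged: bool = False


def half_life_to_time_constant(half_life: float) -> float:
    """Convert a base-2 half-life to the e-folding time constant tau."""
    return half_life / math.log(2)


def time_constant_to_half_life(tau: float) -> float:
    return tau * math.log(2)


def _recovery_model(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    s0, half_life, baseline = p
    return baseline + (s0 - baseline) * np.power(2.0, -t / half_life)


def _fit_segment(t: np.ndarray, v: np.ndarray, t_start: float) -> RecoveryFit:
    if t.size < 4:
        raise ValueError("need at least four points in the fitted segment")
    scale = float(np.max(np.abs(v))) or 1.0
    span = t[-1] - t[0]
    hl0 = float(np.clip(span / 3.0, *HALF_LIFE_BOUNDS))
    x0 = np.array([v[0], hl0, v[-1]])
    lb = np.array([-np.inf, HALF_LIFE_BOUNDS[0], -np.inf])
    ub = np.array([np.inf, HALF_LIFE_BOUNDS[1], np.inf])

    res = least_squares(lambda p: _recovery_model(t, p) - v, x0,
                        bounds=(lb, ub), method="trf",
                        xtol=1e-13, ftol=1e-13, gtol=1e-13)
    s0, hl, base = res.x
    rss = float(2 * res.cost)

    flagged = False
    reason = ""
    if not res.success:
        flagged, reason = True, "did not converge"
    if abs(s0 - base) < 1e-6 * scale:
        flagged, reason = True, "degenerate: recovery amplitude ~ 0"
    if hl >= HALF_LIFE_BOUNDS[1] * (1 - 1e-9) or hl <= HALF_LIFE_BOUNDS[0] * (1 + 1e-9):
        flagged, reason = True, "half-life at bound"

    # 95% CI on the half-life from the asymptotic covariance of the fit.
    dof = t.size - 3
    ci95 = np.nan
    if dof > 0 and not flagged:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / dof)
            ci95 = float(1.959963984540054 * np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            pass

    return RecoveryFit(s0_post=float(s0), half_life=float(hl),
                       baseline=float(base), ci95_half_life=ci95,
                       fit_rss=rss, n_points=int(t.size),
                       segment_start=float(t_start),
                       flagged=flagged, flag_reason=reason)


def noise_sd_for_halflife_ci(timestamps: np.ndarray, s0: float,
                             half_life: float, baseline: float,
                             ci95: float) -> float:
    """Per-point noise sd that makes the fitted half-life's 95% CI equal
    ``ci95`` for the given sampling design and true parameters.

    From the asymptotic covariance of the three-parameter fit the CI
    half-width scales linearly with the noise sd, so the sd reproducing a
    stated CI follows in closed form.  Used to emulate a measured time
    course whose published uncertainty is known but whose raw scatter is
    not.
    """
    t = np.asarray(timestamps, dtype=float) - timestamps[0]
    w = np.power(2.0, -t / half_life)
    j = np.column_stack([
        w,                                                  # d/ds0
        (s0 - baseline) * w * np.log(2.0) * t / half_life ** 2,  # d/dhalf_life
        1.0 - w,                                            # d/dbaseline
    ])
    cov_unit = np.linalg.inv(j.T @ j)[1, 1]
    return float(ci95 / (1.959963984540054 * np.sqrt(cov_unit)))


def fit_recovery(series: DynamicSeries, from_peak: bool = True) -> RecoveryFit:
    """Fit the three-parameter exponential recovery to a dynamic series.

    With ``from_peak=True`` (default, appropriate for the sodium
    amplitude which first rises) the fitted segment starts at the series
    maximum and time is re-zeroed there; a pure decay model cannot
    represent the initial rise.  The peak is located after 3-point
    smoothing but never earlier than the raw maximum, so a sampled point
    just before the true peak does not drag rise samples into the decay
    fit.  With ``from_peak=False`` the full series is fitted from its
    first timepoint.
    """
    if from_peak:
        smoothed = uniform_filter1d(series.values, size=3, mode="nearest")
        i0 = max(int(np.argmax(series.values)), int(np.argmax(smoothed)))
    else:
        i0 = 0
    ts = series.timestamps
    vs = series.values
    fit = _fit_segment(ts[i0:] - ts[i0], vs[i0:], t_start=float(ts[i0]))
    if not from_peak:
        return fit
    # The sampled maximum may straddle the true peak: when dropping the
    # leading point collapses the residual, that point lay on the rise
    # and does not belong to the decay segment.
    for _ in range(2):
        if vs.size - i0 - 1 < 5:
            break
        nxt = _fit_segment(ts[i0 + 1:] - ts[i0 + 1], vs[i0 + 1:],
                           t_start=float(ts[i0 + 1]))
        cur_ms = fit.fit_rss / (fit.n_points - 3)
        nxt_ms = nxt.fit_rss / (nxt.n_points - 3)
        if cur_ms > 0 and nxt_ms < 0.25 * cur_ms:
            fit, i0 = nxt, i0 + 1
        else:
            break
    return fit


def fit_t2_decline(series: DynamicSeries) -> RecoveryFit:
    """Monoexponential decline fit for the water-T2 time course.

    Water T2 peaks immediately post-exercise, so the segment always
    starts at the first timepoint.
    """
    return fit_recovery(series, from_peak=False)


def time_to_peak(series: DynamicSeries) -> float:
    """Timestamp of the series maximum after 3-point moving-average
    smoothing; ties resolve to the raw maximum, earliest first."""
    smoothed = uniform_filter1d(series.values, size=3, mode="nearest")
    top = smoothed.max()
    tied = np.flatnonzero(smoothed >= top - 1e-12 * max(abs(top), 1.0))
    idx = tied[int(np.argmax(series.values[tied]))]
    return float(series.timestamps[idx])


def _common_grid(series_list: list[DynamicSeries]) -> np.ndarray:
    ref = series_list[0].timestamps
    if all(s.timestamps.shape == ref.shape and np.allclose(s.timestamps, ref)
           for s in series_list):
        return ref
    lo = max(s.timestamps[0] for s in series_list)
    hi = min(s.timestamps[-1] for s in series_list)
    return ref[(ref >= lo) & (ref <= hi)]


def _values_on_grid(series: DynamicSeries, grid: np.ndarray) -> np.ndarray:
    if series.timestamps.shape == grid.shape and np.allclose(series.timestamps, grid):
        return series.values
    return np.interp(grid, series.timestamps, series.values)


def compare_to_baseline(series_list: list[DynamicSeries],
                        modality: str | None = None,
                        alpha: float = 0.05) -> list[TimepointComparison]:
    """Per-timepoint Wilcoxon signed-rank test of deviation from baseline.

    Each subject contributes ``value - baseline_value`` at every common
    timepoint; subjects with differing cadences are linearly interpolated
    onto the first subject's grid.  The exact null distribution is used
    for n <= 25 (no zeros or tied magnitudes), otherwise the normal
    approximation with continuity correction.
    """
    if modality is not None:
        series_list = [s for s in series_list if s.modality == modality]
    if len(series_list) < 5:
        raise ValueError("need at least five subjects")
    grid = _common_grid(series_list)
    mat = np.stack([_values_on_grid(s, grid) for s in series_list])
    base = np.array([s.baseline_value for s in series_list])
    diffs = mat - base[:, None]

    out: list[TimepointComparison] = []
    for j, tp in enumerate(grid):
        d = diffs[:, j]
        nz = d[d != 0]
        if nz.size == 0:
            out.append(TimepointComparison(float(tp), 0.0, 1.0, False,
                                           int(d.size), flagged=True))
            continue
        exact = (nz.size <= 25
                 and nz.size == d.size
                 and np.unique(np.abs(nz)).size == nz.size)
        method = "exact" if exact else "approx"
        res = stats.wilcoxon(d, alternative="two-sided", method=method,
                             correction=(method == "approx"),
                             zero_method="wilcox")
        p = float(res.pvalue)
        out.append(TimepointComparison(float(tp), float(res.statistic), p,
                                       bool(p < alpha), int(d.size)))
    return out


def group_mean_series(series_list: list[DynamicSeries],
                      grid: np.ndarray | None = None) -> DynamicSeries:
    """Average subject time courses on a common grid.

    Subjects are linearly interpolated per-subject before averaging,
    since interleaved cadences differ between participants.
    """
    if not series_list:
        raise ValueError("empty series list")
    if grid is None:
        grid = _common_grid(series_list)
    grid = np.asarray(grid, dtype=float)
    mat = np.stack([_values_on_grid(s, grid) for s in series_list])
    return DynamicSeries(
        timestamps=grid,
        values=mat.mean(axis=0),
        modality=series_list[0].modality,
        baseline_value=float(np.mean([s.baseline_value for s in series_list])),
        subject_id="group-mean",
        group=series_list[0].group,
    )
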
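"""Synthetic study-data generation with known ground truth.

No public scanner data exist for this kind of single-centre muscle MR
study, so every input the analysis pipeline consumes is generated here
with known parameters: sodium FIDs with biexponential T2* decay,
multi-echo water amplitude series, post-exercise dynamic timelines on
the interleaved sodium/proton cadence, sodium images with positioned
concentration standards, three-echo Dixon volumes, and two-group
cohorts whose generating means/SDs reproduce the published baseline
tables.  All randomness is seeded and bit-for-bit reproducible.

Default generating values (healthy volunteers HV, dysferlinopathy
patients DP):

=====================  =========  =========
quantity               HV         DP
=====================  =========  =========
[Na] (mM)              19.6(3.1)  36.2(11.4)
water T2 (ms)          29.3(1.1)  33.8(2.7)
T2*_fast (ms)          2.2(1.3)   1.0(0.5)
T2*_slow (ms)          13.4(2.3)  14.0(1.5)
fast fraction          0.46(.09)  0.38(.13)
fat fraction (%)       3.4(1.2)   25.7(15.6)
Na recovery T1/2 (s)   636        (flat)
water-T2 T1/2 (s)      620        (flat)
Na time-to-peak (s)    480        --
=====================  =========  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .dixon_ff import DixonSeries, fat_phase_factors
from .dynamics import DynamicSeries
from .sodium_quant import (DEFAULT_PHANTOM_CONCENTRATIONS,
                           DEFAULT_PHANTOM_RELAXOMETRY, PhantomStandard,
                           TissueRelaxometry, decay_factor)
from .spectro_fit import EchoAmplitudeSeries, Fid

__all__ = [
    "SubjectTruth",
    "AcquisitionTimeline",
    "CohortSpec",
    "Cohort",
    "SubjectAcquisitions",
    "SodiumImageScene",
    "HV_TRUTH",
    "DP_TRUTH",
    "PRESS_ECHO_TIMES_MS",
    "DIXON_ECHO_TIMES_MS",
    "ISIS_DWELL_MS",
    "ISIS_T0_MS",
    "ISIS_N_SAMPLES",
    "NA_SIGNAL_PER_MM",
    "make_fid",
    "make_echo_series",
    "make_dynamic_series",
    "make_dixon_volume",
    "make_sodium_image",
    "make_cohort",
    "default_cohort_spec",
    "tissue_relaxometry_from_truth",
]

#: The six PRESS echo times (ms) of the multi-echo water T2 measurement.
PRESS_ECHO_TIMES_MS = (30.0, 40.0, 60.0, 80.0, 100.0, 150.0)
#: The three Dixon echo times (ms) of the out-in-out scheme.
DIXON_ECHO_TIMES_MS = (3.45, 4.60, 5.75)
#: Sodium FID sampling: 128 ms readout over 1024 samples.
ISIS_DWELL_MS = 0.125
ISIS_N_SAMPLES = 1024
#: First sample time (ms) = the short sodium spectroscopy echo time.
ISIS_T0_MS = 0.16

#: Arbitrary-units sodium ISIS signal per mM of tissue concentration;
#: scaled so a 19.6 mM muscle yields the published baseline amplitude.
NA_SIGNAL_PER_MM = 8.7e-5 / 19.6


@dataclass
class SubjectTruth:
    """Generating parameters for one synthetic participant."""

    group: Literal["HV", "DP"]
    true_na_concentration: float        # mM
    true_water_t2: float                # ms
    true_t2s_fast: float                # ms
    true_t2s_slow: float                # ms
    true_m_fast_fraction: float         # in [0, 1]
    true_ff: float                      # percent
    dyn_recovery_halflife: float = 636.0    # s, sodium amplitude
    dyn_peak_time: float = 480.0            # s, sodium time-to-peak
    dyn_peak_amplitude_ratio: float = 1.26  # sodium peak / baseline, >= 1
    dyn_t2_halflife: float | None = 620.0   # s; None -> sodium half-life
    dyn_t2_peak_ratio: float = 1.24         # water-T2 peak / baseline
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("HV", "DP"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.true_na_concentration <= 0:
            raise ValueError("sodium concentration must be positive")
        if not (0 <= self.true_ff <= 100):
            raise ValueError("fat fraction must lie in [0, 100]")
        if not (0 <= self.true_m_fast_fraction <= 1):
            raise ValueError("fast fraction must lie in [0, 1]")
        if self.true_t2s_fast <= 0 or self.true_t2s_slow <= 0:
            raise ValueError("T2* values must be positive")
        if not self.true_t2s_fast < self.true_t2s_slow:
            raise ValueError("fast T2* must be shorter than slow T2*")
        if self.true_water_t2 <= 0:
            raise ValueError("water T2 must be positive")
        if self.dyn_peak_amplitude_ratio < 1 or self.dyn_t2_peak_ratio < 1:
            raise ValueError("peak/baseline ratios must be >= 1")

    @property
    def t2_halflife(self) -> float:
        return (self.dyn_t2_halflife if self.dyn_t2_halflife is not None
                else self.dyn_recovery_halflife)


#: Group-mean generating parameter sets.
HV_TRUTH = SubjectTruth(group="HV", true_na_concentration=19.6,
                        true_water_t2=29.3, true_t2s_fast=2.2,
                        true_t2s_slow=13.4, true_m_fast_fraction=0.46,
                        true_ff=3.4, dyn_recovery_halflife=636.0,
                        dyn_peak_time=480.0, dyn_peak_amplitude_ratio=1.26,
                        dyn_t2_halflife=620.0, dyn_t2_peak_ratio=1.24)
DP_TRUTH = SubjectTruth(group="DP", true_na_concentration=36.2,
                        true_water_t2=33.8, true_t2s_fast=1.0,
                        true_t2s_slow=14.0, true_m_fast_fraction=0.38,
                        true_ff=25.7, dyn_recovery_halflife=636.0,
                        dyn_peak_time=480.0, dyn_peak_amplitude_ratio=1.085,
                        dyn_t2_halflife=620.0, dyn_t2_peak_ratio=1.07)


@dataclass
class AcquisitionTimeline:
    """Interleaved post-exercise sodium/proton scan cadence.

    Each cycle runs one sodium spectroscopy scan (129 s) followed by one
    proton scan (45 s); timestamps are assigned at scan midpoints.
    ``post_exercise_span`` (s), when given, overrides ``n_cycles`` with
    however many full cycles fit the span (at least one).
    """

    na_scan_duration: float = 129.0
    h_scan_duration: float = 45.0
    n_cycles: int = 12
    post_exercise_span: float | None = None

    def __post_init__(self) -> None:
        if self.na_scan_duration <= 0 or self.h_scan_duration <= 0:
            raise ValueError("scan durations must be positive")
        if self.post_exercise_span is not None:
            if self.post_exercise_span <= 0:
                raise ValueError("post_exercise_span must be positive")
            self.n_cycles = max(1, int(self.post_exercise_span // self.cycle_duration))
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")

    @property
    def cycle_duration(self) -> float:
        return self.na_scan_duration + self.h_scan_duration

    def sodium_times(self) -> np.ndarray:
        """Midpoints (s since exercise end) of the sodium scan windows."""
        starts = np.arange(self.n_cycles) * self.cycle_duration
        return starts + self.na_scan_duration / 2.0

    def proton_times(self) -> np.ndarray:
        starts = np.arange(self.n_cycles) * self.cycle_duration + self.na_scan_duration
        return starts + self.h_scan_duration / 2.0

    @property
    def total_span(self) -> float:
        return self.n_cycles * self.cycle_duration


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _complex_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    return rng.normal(0.0, sd, shape) + 1j * rng.normal(0.0, sd, shape)


# ---------------------------------------------------------------------------
# Signal generators
# ---------------------------------------------------------------------------

def make_fid(truth: SubjectTruth, amplitude: float = 1.0,
             n_samples: int = ISIS_N_SAMPLES, dwell: float = ISIS_DWELL_MS,
             t0: float = ISIS_T0_MS, noise_sd: float = 0.0,
             seed=None) -> Fid:
    """Synthesize a sodium FID with biexponential T2* decay.

    The noiseless envelope at sample k (t_k = t0 + k*dwell, ms) is
    ``amplitude * (mf exp(-t_k/T2*_fast) + (1-mf) exp(-t_k/T2*_slow))``;
    independent Gaussian noise of ``noise_sd`` is added to the real and
    imaginary channels, so the magnitude of noisy output is Rician.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if dwell <= 0:
        raise ValueError("dwell must be positive")
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    if t0 < 0 or noise_sd < 0:
        raise ValueError("t0 and noise_sd must be non-negative")
    t = t0 + dwell * np.arange(n_samples)
    mf = truth.true_m_fast_fraction
    envelope = amplitude * (mf * np.exp(-t / truth.true_t2s_fast)
                            + (1 - mf) * np.exp(-t / truth.true_t2s_slow))
    samples = envelope.astype(complex)
    if noise_sd > 0:
        samples = samples + _complex_noise(_rng(seed), noise_sd, n_samples)
    return Fid(samples=samples, dwell=dwell, t0=t0, nucleus="23Na")


def make_echo_series(t2: float, s0: float = 1.0,
                     echo_times=PRESS_ECHO_TIMES_MS, noise_sd: float = 0.0,
                     seed=None) -> EchoAmplitudeSeries:
    """Monoexponential water amplitudes ``s0 exp(-TE/t2)`` plus noise."""
    if t2 <= 0:
        raise ValueError("t2 must be positive")
    te = np.asarray(echo_times, dtype=float)
    if np.any(te <= 0) or np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be positive and strictly increasing")
    amp = s0 * np.exp(-te / t2)
    if noise_sd > 0:
        amp = amp + _rng(seed).normal(0.0, noise_sd, te.size)
    return EchoAmplitudeSeries(echo_times=te, amplitudes=amp, source="synthetic")


def _hv_sodium_course(t, baseline, truth: SubjectTruth, start_fraction):
    peak = baseline * truth.dyn_peak_amplitude_ratio
    a = peak - baseline
    tp = truth.dyn_peak_time
    rise = baseline + a * (start_fraction + (1 - start_fraction) * t / tp)
    decay = baseline + a * np.power(2.0, -(t - tp) / truth.dyn_recovery_halflife)
    return np.where(t < tp, rise, decay)


def make_dynamic_series(truth: SubjectTruth, timeline: AcquisitionTimeline,
                        modality: str, noise_sd: float = 0.0, seed=None,
                        start_fraction: float = 0.25,
                        dp_trend: float = 0.02) -> DynamicSeries:
    """Render one subject's post-exercise time course.

    Healthy-volunteer sodium amplitude ramps linearly from a configurable
    post-exercise start value to its peak at ``dyn_peak_time`` and then
    recovers exponentially (base-2 half-life); healthy water T2 is
    maximal at the first timepoint and declines monoexponentially.
    Patient series are near-flat with a small downward trend
    (``dp_trend`` fractional drop over the full span).
    """
    if modality not in ("na_amplitude", "water_t2"):
        raise ValueError(f"unknown modality {modality!r}")
    if not 0 <= start_fraction <= 1:
        raise ValueError("start_fraction must lie in [0, 1]")
    if modality == "na_amplitude":
        t = timeline.sodium_times()
        baseline = truth.true_na_concentration * NA_SIGNAL_PER_MM
        ratio = truth.dyn_peak_amplitude_ratio
    else:
        t = timeline.proton_times()
        baseline = truth.true_water_t2
        ratio = truth.dyn_t2_peak_ratio

    if truth.group == "DP":
        values = baseline * ratio * (1.0 - dp_trend * t / t[-1])
    elif modality == "na_amplitude":
        values = _hv_sodium_course(t, baseline, truth, start_fraction)
    else:
        peak = baseline * ratio
        values = baseline + (peak - baseline) * np.power(2.0, -t / truth.t2_halflife)

    if noise_sd > 0:
        values = values + _rng(seed).normal(0.0, noise_sd, t.size)
    return DynamicSeries(timestamps=t, values=values, modality=modality,
                         baseline_value=baseline, subject_id=truth.subject_id,
                         group=truth.group)


def make_dixon_volume(ff_map, water_t2star: float = 25.0, field: float = 3.0,
                      echo_times=DIXON_ECHO_TIMES_MS, noise_sd: float = 0.0,
                      seed=None, m0=1.0, field_map_hz=0.0,
                      fat_spectrum=None) -> DixonSeries:
    """Render three-echo complex Dixon images from a fat-fraction map.

    Per voxel ``S(TE) = (W + F c(TE)) exp(2j pi psi TE) exp(-TE/T2*)``
    with ``W/(W+F) = 1 - ff/100`` and a shared water/fat T2* (ms).
    ``m0`` and ``field_map_hz`` may be scalars or maps of the same shape.
    """
    ff = np.asarray(ff_map, dtype=float)
    if np.any(ff < 0) or np.any(ff > 100):
        raise ValueError("fat fractions must lie in [0, 100] percent")
    if water_t2star <= 0:
        raise ValueError("T2* must be positive")
    te = np.asarray(echo_times, dtype=float)
    if te.size < 3:
        raise ValueError("need three echo times")
    m0_arr = np.broadcast_to(np.asarray(m0, dtype=float), ff.shape)
    psi = np.broadcast_to(np.asarray(field_map_hz, dtype=float), ff.shape)
    if np.asarray(ff_map).shape != ff.shape:  # pragma: no cover
        raise ValueError("mismatched map shapes")

    c = fat_phase_factors(te, field, fat_spectrum)
    w = m0_arr * (1.0 - ff / 100.0)
    f = m0_arr * ff / 100.0
    te_b = te.reshape((-1,) + (1,) * ff.ndim)
    c_b = c.reshape((-1,) + (1,) * ff.ndim)
    signal = (w + f * c_b) * np.exp(2j * np.pi * psi * te_b / 1000.0)
    signal = signal * np.exp(-te_b / water_t2star)
    if noise_sd > 0:
        signal = signal + _complex_noise(_rng(seed), noise_sd, signal.shape)
    return DixonSeries(echoes=signal, echo_times=te, field_strength=field,
                       fat_spectrum=fat_spectrum)


# ---------------------------------------------------------------------------
# Sodium image scenes
# ---------------------------------------------------------------------------

@dataclass
class SodiumImageScene:
    """A rendered sodium image stack with its ROI masks and ground truth."""

    image: np.ndarray                       # magnitude, shape + (n_slices,)
    masks: dict                             # name -> boolean mask
    truth: SubjectTruth
    phantom_concentrations: tuple
    noise_sd: float
    te: float                               # ms
    signal_scale: float


def tissue_relaxometry_from_truth(truth: SubjectTruth) -> TissueRelaxometry:
    return TissueRelaxometry(m_slow_ta=1.0 - truth.true_m_fast_fraction,
                             m_fast_ta=truth.true_m_fast_fraction,
                             t2s_slow_ta=truth.true_t2s_slow,
                             t2s_fast_ta=truth.true_t2s_fast)


def _disc(shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def make_sodium_image(truth: SubjectTruth, te: float = 0.28,
                      shape: tuple = (96, 96), n_slices: int = 4,
                      snr: float | None = None, noise_sd: float | None = None,
                      seed=None, signal_scale: float = 1.0,
                      phantom_concentrations=DEFAULT_PHANTOM_CONCENTRATIONS,
                      ) -> SodiumImageScene:
    """Render a spin-density-weighted sodium magnitude image stack.

    The scene holds a tibialis-anterior disc of the subject's true
    concentration (relaxed with the subject's biexponential T2*), a row
    of agarose concentration standards (phantom relaxometry from the
    package calibration defaults), and an air background for the noise
    ROI.  Region signal is ``signal_scale * concentration * D(te)``.
    ``snr`` sets the noise sd so the measured TA SNR (per the magnitude
    SNR definition) lands at the requested level; alternatively pass
    ``noise_sd`` directly, or neither for a noiseless scene.
    """
    if snr is not None and noise_sd is not None:
        raise ValueError("give either snr or noise_sd, not both")
    d_ta = decay_factor(1.0 - truth.true_m_fast_fraction, truth.true_m_fast_fraction,
                        truth.true_t2s_slow, truth.true_t2s_fast, te)
    p = DEFAULT_PHANTOM_RELAXOMETRY
    d_p = decay_factor(p["m_slow_p"], p["m_fast_p"],
                       p["t2s_slow_p"], p["t2s_fast_p"], te)

    base = np.zeros(shape)
    masks: dict[str, np.ndarray] = {}
    ta_center = (int(shape[0] * 0.6), int(shape[1] * 0.5))
    ta_radius = max(3, min(shape) // 8)
    ta = _disc(shape, ta_center, ta_radius)
    ta_signal = signal_scale * truth.true_na_concentration * d_ta
    base[ta] = ta_signal
    masks["ta"] = ta

    n_ph = len(phantom_concentrations)
    radius = max(2, min(shape) // 16)
    for i, conc in enumerate(phantom_concentrations):
        cx = int(shape[1] * (i + 1) / (n_ph + 1))
        disc = _disc(shape, (int(shape[0] * 0.2), cx), radius)
        base[disc] = signal_scale * conc * d_p
        masks[f"phantom_{int(conc)}"] = disc

    noise_box = np.zeros(shape, dtype=bool)
    noise_box[: shape[0] // 8, : shape[1] // 4] = True
    masks["noise"] = noise_box & ~ta

    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        # Magnitude-image SNR: (S - sigma*sqrt(pi/2)) / (sigma*sqrt(2-pi/2)).
        sigma = ta_signal / (snr * np.sqrt(2 - np.pi / 2) + np.sqrt(np.pi / 2))
    else:
        sigma = float(noise_sd or 0.0)
        if sigma < 0:
            raise ValueError("noise_sd must be non-negative")

    stack = np.repeat(base[..., None], n_slices, axis=2).astype(complex)
    if sigma > 0:
        stack = stack + _complex_noise(_rng(seed), sigma, stack.shape)
    image = np.abs(stack)
    masks = {k: np.repeat(v[..., None], n_slices, axis=2) for k, v in masks.items()}
    return SodiumImageScene(image=image, masks=masks, truth=truth,
                            phantom_concentrations=tuple(phantom_concentrations),
                            noise_sd=sigma, te=te, signal_scale=signal_scale)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: (mean, sd) generating distributions per SubjectTruth field and group.
DEFAULT_GROUP_PARAMS = {
    "HV": {
        "true_na_concentration": (19.6, 3.1),
        "true_water_t2": (29.3, 1.1),
        "true_t2s_fast": (2.2, 1.3),
        "true_t2s_slow": (13.4, 2.3),
        "true_m_fast_fraction": (0.46, 0.09),
        "true_ff": (3.4, 1.2),
        "dyn_recovery_halflife": (636.0, 60.0),
        "dyn_peak_time": (480.0, 60.0),
        "dyn_peak_amplitude_ratio": (1.26, 0.05),
        "dyn_t2_halflife": (620.0, 60.0),
        "dyn_t2_peak_ratio": (1.24, 0.05),
    },
    "DP": {
        "true_na_concentration": (36.2, 11.4),
        "true_water_t2": (33.8, 2.7),
        "true_t2s_fast": (1.0, 0.5),
        "true_t2s_slow": (14.0, 1.5),
        "true_m_fast_fraction": (0.38, 0.13),
        "true_ff": (25.7, 15.6),
        "dyn_recovery_halflife": (636.0, 60.0),
        "dyn_peak_time": (480.0, 60.0),
        "dyn_peak_amplitude_ratio": (1.085, 0.02),
        "dyn_t2_halflife": (620.0, 60.0),
        "dyn_t2_peak_ratio": (1.07, 0.02),
    },
}

# Physical truncation bounds per field (lo, hi); None -> unbounded side.
_FIELD_BOUNDS = {
    "true_na_concentration": (1e-3, None),
    "true_water_t2": (1.0, None),
    "true_t2s_fast": (0.05, None),
    "true_t2s_slow": (0.05, None),
    "true_m_fast_fraction": (0.0, 1.0),
    "true_ff": (0.0, 100.0),
    "dyn_recovery_halflife": (10.0, None),
    "dyn_peak_time": (30.0, None),
    "dyn_peak_amplitude_ratio": (1.0, None),
    "dyn_t2_halflife": (10.0, None),
    "dyn_t2_peak_ratio": (1.0, None),
}


@dataclass
class CohortSpec:
    n_per_group: int = 10
    seed: int = 0
    timeline: AcquisitionTimeline = field(default_factory=AcquisitionTimeline)
    group_params: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_GROUP_PARAMS.items()})
    render: bool = False
    noise: dict = field(default_factory=lambda: {
        "fid_snr": 50.0, "echo_rel_sd": 0.01, "dynamic_rel_sd": 0.05})

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for g, params in self.group_params.items():
            for name, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {g}.{name}")


@dataclass
class SubjectAcquisitions:
    fid: Fid
    echo_series: EchoAmplitudeSeries
    na_series: DynamicSeries
    t2_series: DynamicSeries


@dataclass
class Cohort:
    truths: list
    table: pd.DataFrame
    acquisitions: dict = field(default_factory=dict)    # subject_id -> SubjectAcquisitions


def _draw_truncated(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws; degenerates to the mean when sd == 0."""
    if sd == 0:
        return np.full(size, mean)
    a = -np.inf if lo is None else (lo - mean) / sd
    b = np.inf if hi is None else (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _render_subject(truth: SubjectTruth, timeline, noise, rng) -> SubjectAcquisitions:
    env0 = (truth.true_m_fast_fraction * np.exp(-ISIS_T0_MS / truth.true_t2s_fast)
            + (1 - truth.true_m_fast_fraction) * np.exp(-ISIS_T0_MS / truth.true_t2s_slow))
    fid_noise = env0 / noise["fid_snr"] if noise["fid_snr"] else 0.0
    seeds = rng.integers(0, 2**31 - 1, size=4)
    fid = make_fid(truth, noise_sd=fid_noise, seed=int(seeds[0]))
    echoes = make_echo_series(truth.true_water_t2,
                              noise_sd=noise["echo_rel_sd"], seed=int(seeds[1]))
    na_base = truth.true_na_concentration * NA_SIGNAL_PER_MM
    na = make_dynamic_series(truth, timeline, "na_amplitude",
                             noise_sd=noise["dynamic_rel_sd"] * na_base,
                             seed=int(seeds[2]))
    t2 = make_dynamic_series(truth, timeline, "water_t2",
                             noise_sd=noise["dynamic_rel_sd"] * truth.true_water_t2,
                             seed=int(seeds[3]))
    return SubjectAcquisitions(fid=fid, echo_series=echoes, na_series=na,
                               t2_series=t2)


def make_cohort(spec: CohortSpec) -> Cohort:
    """Draw per-subject truths from the group distributions and (optionally)
    render each subject's synthetic acquisitions.

    Draws are truncated normals (concentrations positive, fractions in
    [0, 1], fat fractions in [0, 100], relaxation times positive); pairs
    violating T2*_fast < T2*_slow are redrawn.  Identical (spec, seed)
    produce bitwise-identical cohorts.
    """
    rng = _rng(spec.seed)
    truths: list[SubjectTruth] = []
    rows = []
    for group in ("HV", "DP"):
        params = spec.group_params[group]
        n = spec.n_per_group
        draws = {}
        for name, (mean, sd) in params.items():
            lo, hi = _FIELD_BOUNDS.get(name, (None, None))
            draws[name] = _draw_truncated(rng, mean, sd, lo, hi, n)
        # enforce component ordering by redrawing offending pairs
        for _ in range(100):
            bad = draws["true_t2s_fast"] >= draws["true_t2s_slow"]
            if not np.any(bad):
                break
            for name in ("true_t2s_fast", "true_t2s_slow"):
                mean, sd = params[name]
                lo, hi = _FIELD_BOUNDS[name]
                draws[name][bad] = _draw_truncated(rng, mean, sd, lo, hi,
                                                   int(bad.sum()))
        else:  # pragma: no cover - essentially unreachable
            clip = draws["true_t2s_fast"] >= draws["true_t2s_slow"]
            draws["true_t2s_fast"][clip] = 0.9 * draws["true_t2s_slow"][clip]

        for i in range(n):
            truth = SubjectTruth(
                group=group, subject_id=f"{group}{i + 1:02d}",
                **{name: float(draws[name][i]) for name in params})
            truths.append(truth)
            row = {"subject_id": truth.subject_id, "group": group}
            row.update({name: getattr(truth, name) for name in params})
            rows.append(row)

    table = pd.DataFrame(rows)
    acquisitions = {}
    if spec.render:
        for truth in truths:
            acquisitions[truth.subject_id] = _render_subject(
                truth, spec.timeline, spec.noise, rng)
    return Cohort(truths=truths, table=table, acquisitions=acquisitions)


def default_cohort_spec(n_per_group: int = 10, seed: int = 0,
                        render: bool = False) -> CohortSpec:
    return CohortSpec(n_per_group=n_per_group, seed=seed, render=render)


def reference_phantom(concentration: float = 20.0) -> PhantomStandard:
    """The 20 mM reference standard with the package calibration defaults."""
    return PhantomStandard(concentration=concentration)
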
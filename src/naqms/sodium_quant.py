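"""Image SNR and phantom-calibrated tissue sodium concentration.

Tissue sodium concentration in the tibialis anterior (TA) is obtained by
referencing the TA region-of-interest signal to a 20 mM NaCl phantom and
correcting both for biexponential T2* decay at the acquisition echo time:

    Na_TA = Na_P * (SI_TA / SI_P) * D_P(TE) / D_TA(TE)

where D_X(TE) = Ms_X exp(-TE/T2*s_X) + Mf_X exp(-TE/T2*f_X) and the
fractions of each compartment sum to one.  Tissue relaxometry comes from
each participant's baseline sodium FID fit; phantom relaxometry is a
one-off calibration measurement.

Image SNR follows the magnitude-image convention
(mean signal - mean background) / background standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

try:  # nibabel images are accepted anywhere an array is
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

__all__ = [
    "RoiStats",
    "PhantomStandard",
    "TissueRelaxometry",
    "SodiumConcentrationResult",
    "CalibrationReport",
    "DEFAULT_PHANTOM_RELAXOMETRY",
    "DEFAULT_PHANTOM_CONCENTRATIONS",
    "roi_stats",
    "snr",
    "sum_central_slices",
    "decay_factor",
    "concentration",
    "calibration_check",
]

#: NaCl concentrations (mM) of the four positioned agarose standards.
DEFAULT_PHANTOM_CONCENTRATIONS = (10.0, 20.0, 30.0, 40.0)

#: One-off phantom relaxometry calibration used when a study config does
#: not override it: (m_fast, m_slow, T2*_fast ms, T2*_slow ms) typical of
#: a 3% agarose sodium gel.
DEFAULT_PHANTOM_RELAXOMETRY = {
    "m_fast_p": 0.6,
    "m_slow_p": 0.4,
    "t2s_fast_p": 4.0,
    "t2s_slow_p": 18.0,
}

#: Default correction echo time (ms): the radial sodium acquisition.
RADIAL_TE_MS = 0.28
#: The cartesian gradient-echo alternative.
CARTESIAN_TE_MS = 1.89


@dataclass
class RoiStats:
    mean: float
    sd: float
    n_voxels: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("ROI must contain at least one voxel")
        if self.sd < 0:
            raise ValueError("ROI sd must be non-negative")


@dataclass
class PhantomStandard:
    """A reference phantom: known concentration plus its relaxometry."""

    concentration: float            # mM
    m_slow_p: float = DEFAULT_PHANTOM_RELAXOMETRY["m_slow_p"]
    m_fast_p: float = DEFAULT_PHANTOM_RELAXOMETRY["m_fast_p"]
    t2s_slow_p: float = DEFAULT_PHANTOM_RELAXOMETRY["t2s_slow_p"]
    t2s_fast_p: float = DEFAULT_PHANTOM_RELAXOMETRY["t2s_fast_p"]
    roi: RoiStats | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("phantom concentration must be positive")
        if abs(self.m_slow_p + self.m_fast_p - 1.0) > 1e-9:
            raise ValueError("phantom fractions must sum to 1")
        if self.t2s_slow_p <= 0 or self.t2s_fast_p <= 0:
            raise ValueError("phantom T2* values must be positive")


@dataclass
class TissueRelaxometry:
    """Per-participant TA relaxometry (from the baseline sodium FID fit)."""

    m_slow_ta: float
    m_fast_ta: float
    t2s_slow_ta: float
    t2s_fast_ta: float
    source: object | None = None    # e.g. the BiexpT2StarFit it came from

    def __post_init__(self) -> None:
        if abs(self.m_slow_ta + self.m_fast_ta - 1.0) > 1e-9:
            raise ValueError("tissue fractions must sum to 1")
        if self.t2s_slow_ta <= 0 or self.t2s_fast_ta <= 0:
            raise ValueError("tissue T2* values must be positive")

    @classmethod
    def from_fit(cls, fit) -> "TissueRelaxometry":
        """Build from a BiexpT2StarFit (fractions exclude the noise offset)."""
        frac_fast = fit.m_fast_fraction
        return cls(m_slow_ta=1.0 - frac_fast, m_fast_ta=frac_fast,
                   t2s_slow_ta=fit.t2s_slow, t2s_fast_ta=fit.t2s_fast,
                   source=fit)


@dataclass
class SodiumConcentrationResult:
    concentration: float            # mM
    correction_factor: float        # D_P / D_TA
    si_ta: float
    si_p: float
    te: float                       # ms


@dataclass
class CalibrationReport:
    slope: float
    intercept: float
    r_squared: float
    n_phantoms: int
    warning: bool                   # True when R^2 < 0.99


def _asarray(image) -> np.ndarray:
    if nib is not None and isinstance(image, nib.spatialimages.SpatialImage):
        return np.asanyarray(image.dataobj)
    return np.asarray(image)


def roi_stats(image, mask, label: str = "") -> RoiStats:
    """Mean/SD/voxel-count of image intensities under a boolean mask."""
    data = _asarray(image)
    m = _asarray(mask).astype(bool)
    if m.shape != data.shape:
        raise ValueError("mask and image shapes differ")
    vals = data[m]
    if vals.size == 0:
        raise ValueError("empty ROI")
    return RoiStats(mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    n_voxels=int(vals.size), label=label)


def snr(signal_roi: RoiStats, noise_roi: RoiStats) -> float:
    """(mean signal - mean noise) / noise standard deviation."""
    if noise_roi.sd <= 0:
        raise ValueError("noise ROI standard deviation must be positive")
    return (signal_roi.mean - noise_roi.mean) / noise_roi.sd


def sum_central_slices(volume, n: int, axis: int = -1):
    """Voxelwise sum of the ``n`` central slices of a stack.

    For a depth-d stack the selected block starts at ``ceil((d - n) / 2)``
    (an even stack with n=2 sums the two middle slices).  A nibabel image
    input returns a nibabel image whose affine reflects the position and
    thickness of the summed slab; array input returns an array.
    """
    is_nifti = nib is not None and isinstance(volume, nib.spatialimages.SpatialImage)
    data = _asarray(volume)
    d = data.shape[axis]
    if not 1 <= n <= d:
        raise ValueError(f"cannot sum {n} central slices of a {d}-slice stack")
    start = (d - n + 1) // 2
    sl = [slice(None)] * data.ndim
    sl[axis] = slice(start, start + n)
    summed = data[tuple(sl)].sum(axis=axis, keepdims=True)
    if not is_nifti:
        return summed
    ax = axis % data.ndim
    affine = volume.affine.copy()
    affine[:3, 3] += affine[:3, ax] * (start + (n - 1) / 2.0)
    affine[:3, ax] *= n
    out = nib.Nifti1Image(summed, affine)
    out.header.set_zooms(tuple(z * (n if i == ax else 1)
                               for i, z in enumerate(volume.header.get_zooms()[:3])))
    return out


def decay_factor(m_slow: float, m_fast: float, t2s_slow: float,
                 t2s_fast: float, te: float) -> float:
    """Biexponential signal-retention factor D(TE)."""
    return m_slow * np.exp(-te / t2s_slow) + m_fast * np.exp(-te / t2s_fast)


def concentration(si_ta: float, si_p: float, phantom: PhantomStandard,
                  tissue: TissueRelaxometry,
                  te: float = RADIAL_TE_MS) -> SodiumConcentrationResult:
    """Relaxation-corrected tissue sodium concentration.

    ``si_ta`` and ``si_p`` are the ROI-mean magnitude signal intensities
    of tissue and reference phantom.  No noise-mean subtraction is
    applied here (it belongs to the SNR calculation); pre-correct the
    inputs if desired.
    """
    if si_p <= 0:
        raise ValueError("phantom signal intensity must be positive")
    if te < 0:
        raise ValueError("echo time must be non-negative")
    d_p = decay_factor(phantom.m_slow_p, phantom.m_fast_p,
                       phantom.t2s_slow_p, phantom.t2s_fast_p, te)
    d_ta = decay_factor(tissue.m_slow_ta, tissue.m_fast_ta,
                        tissue.t2s_slow_ta, tissue.t2s_fast_ta, te)
    cf = d_p / d_ta
    return SodiumConcentrationResult(
        concentration=float(phantom.concentration * (si_ta / si_p) * cf),
        correction_factor=float(cf),
        si_ta=float(si_ta), si_p=float(si_p), te=float(te),
    )


def calibration_check(phantoms: list[PhantomStandard]) -> CalibrationReport:
    """Ordinary least squares of ROI mean signal against concentration.

    Sanity-checks the positioned concentration standards; a warning flag
    is raised when R^2 < 0.99.
    """
    if len(phantoms) < 2:
        raise ValueError("need at least two phantoms")
    conc = np.array([p.concentration for p in phantoms], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("phantom concentrations must not all be identical")
    means = []
    for p in phantoms:
        if p.roi is None:
            raise ValueError("every phantom needs ROI statistics")
        means.append(p.roi.mean)
    fit = _sps.linregress(conc, np.asarray(means))
    r2 = float(fit.rvalue ** 2)
    return CalibrationReport(slope=float(fit.slope), intercept=float(fit.intercept),
                             r_squared=r2, n_phantoms=len(phantoms),
                             warning=bool(r2 < 0.99))
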
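"""Three-echo Dixon fat-water separation and fat-fraction mapping.

Per voxel the three complex echoes are modelled as

    S(TE) = (W + F * c(TE)) * exp(2j pi psi TE) * exp(-TE * R2*)

where ``c(TE)`` is the complex dephasing factor of a multi-peak fat
spectrum, ``psi`` the B0 field offset in Hz and a single R2* is shared by
water and fat.  Estimation uses variable projection: for a trial
(psi, R2*) the complex amplitudes (W, F) follow by linear least squares,
so only the two nonlinear parameters are searched - first on a coarse
grid (vectorised across all voxels), then refined per voxel.  Water/fat
swaps from the periodic psi ambiguity are resolved by region growing
from the brightest voxel, preferring the candidate field offset closest
to the already-visited neighbourhood.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import least_squares

__all__ = [
    "DixonSeries",
    "FatWaterResult",
    "FatFractionSummary",
    "default_fat_spectrum",
    "fat_phase_factors",
    "separate_fat_water",
    "noise_bias_correct",
    "estimate_noise_sd",
    "summarize_ff",
    "GYROMAGNETIC_RATIO_MHZ_PER_T",
    "WATER_PPM",
]

GYROMAGNETIC_RATIO_MHZ_PER_T = 42.5774  # 1H
WATER_PPM = 4.7

#: Rayleigh correction: sd of background magnitude noise = sigma * sqrt(2 - pi/2).
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))

_DEFAULT_SPECTRUM_CACHE: list[tuple[float, float]] | None = None


def default_fat_spectrum() -> list[tuple[float, float]]:
    """Load the packaged six-peak fat spectral model as (ppm, amplitude)."""
    global _DEFAULT_SPECTRUM_CACHE
    if _DEFAULT_SPECTRUM_CACHE is None:
        text = resources.files("naqms").joinpath("data/fat_spectrum_3t.yaml").read_text()
        cfg = yaml.safe_load(text)
        peaks = [(float(p["ppm"]), float(p["amplitude"])) for p in cfg["peaks"]]
        total = sum(a for _, a in peaks)
        _DEFAULT_SPECTRUM_CACHE = [(ppm, a / total) for ppm, a in peaks]
    return list(_DEFAULT_SPECTRUM_CACHE)


def fat_phase_factors(echo_times_ms, field_strength_t: float,
                      fat_spectrum=None) -> np.ndarray:
    """Complex fat dephasing c(TE) = sum_j a_j exp(2j pi df_j TE).

    ``df_j`` is the chemical-shift offset of peak j from water, converted
    to Hz at the given field strength.
    """
    if fat_spectrum is None:
        fat_spectrum = default_fat_spectrum()
    te_s = np.asarray(echo_times_ms, dtype=float) / 1000.0
    c = np.zeros(te_s.shape, dtype=complex)
    for ppm, amp in fat_spectrum:
        df = (ppm - WATER_PPM) * GYROMAGNETIC_RATIO_MHZ_PER_T * field_strength_t
        c += amp * np.exp(2j * np.pi * df * te_s)
    return c


@dataclass
class DixonSeries:
    """Three (or more) complex echo images with their acquisition metadata."""

    echoes: np.ndarray                      # (n_echo, ...spatial), complex
    echo_times: np.ndarray                  # ms
    field_strength: float = 3.0             # T
    fat_spectrum: list | None = None        # [(ppm, amplitude)], sums to 1

    def __post_init__(self) -> None:
        self.echoes = np.asarray(self.echoes, dtype=complex)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.echoes.ndim < 1 or self.echoes.shape[0] < 3:
            raise ValueError("need at least three echoes")
        if self.echo_times.size != self.echoes.shape[0]:
            raise ValueError("echo_times length must match number of echo images")
        if self.fat_spectrum is None:
            self.fat_spectrum = default_fat_spectrum()
        else:
            self.fat_spectrum = [(float(p), float(a)) for p, a in self.fat_spectrum]
            if abs(sum(a for _, a in self.fat_spectrum) - 1.0) > 1e-9:
                raise ValueError("fat spectrum amplitudes must sum to 1")

    @property
    def spatial_shape(self) -> tuple:
        return self.echoes.shape[1:]


@dataclass
class FatWaterResult:
    water: np.ndarray               # arbitrary units, >= 0
    fat: np.ndarray                 # arbitrary units, >= 0
    r2star: np.ndarray              # 1/s
    field_map: np.ndarray           # Hz
    ff: np.ndarray                  # percent in [0, 100]
    undefined_mask: np.ndarray      # voxels where W + F ~ 0 (ff set to 0)
    n_ambiguous: int = 0            # voxels with near-degenerate swap candidates


@dataclass
class FatFractionSummary:
    mean_ff: float
    n_voxels: int
    per_slice: list = field(default_factory=list)   # (slice index, mean, n)
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Separation
# ---------------------------------------------------------------------------

def _design(te_ms: np.ndarray, c: np.ndarray, psi: float, r2: float) -> np.ndarray:
    """3x2 complex design matrix for given field offset (Hz) and R2* (1/s)."""
    te_s = te_ms / 1000.0
    z = np.exp((2j * np.pi * psi - r2) * te_s)
    return np.stack([z, c * z], axis=1)


def _grid_residuals(Sv: np.ndarray, te_ms: np.ndarray, c: np.ndarray,
                    psis: np.ndarray, r2s: np.ndarray) -> np.ndarray:
    """Phase-constrained projection residual for every (psi, r2) combo.

    Water and fat amplitudes are real with one shared phase; for fixed
    (psi, r2) the residual minimised over amplitudes AND phase has a
    closed form.  With v = A^H s and M = Re(A^H A)^-1, the explained
    energy is the largest eigenvalue of the 2x2 form built from
    Re(e^{-i phi} v), so no per-voxel phase search is needed.  Returns
    (n_psi, n_voxel) residuals, minimised over the r2 grid.
    """
    n_vox = Sv.shape[1]
    energy = np.einsum("ev,ev->v", Sv.conj(), Sv).real
    out = np.full((psis.size, n_vox), np.inf)
    for i, psi in enumerate(psis):
        for r2 in r2s:
            a = _design(te_ms, c, psi, r2)
            m = np.linalg.pinv(np.real(a.conj().T @ a))
            v = a.conj().T @ Sv
            rv, iv = v.real, v.imag
            gaa = np.einsum("iv,ij,jv->v", rv, m, rv)
            gbb = np.einsum("iv,ij,jv->v", iv, m, iv)
            gab = np.einsum("iv,ij,jv->v", rv, m, iv)
            lam = 0.5 * (gaa + gbb + np.sqrt((gaa - gbb) ** 2 + 4 * gab ** 2))
            np.minimum(out[i], np.maximum(energy - lam, 0.0), out=out[i])
    return out


def _phase_opt_solve(s: np.ndarray, a: np.ndarray):
    """Optimal shared phase and real (W, F) for one voxel and design.

    Returns (phi, x, residual_vector) for the phase-constrained linear
    subproblem min over real x and phi of ||s - e^{i phi} A x||.
    """
    m = np.linalg.pinv(np.real(a.conj().T @ a))
    v = a.conj().T @ s
    rv, iv = v.real, v.imag
    g = np.array([[rv @ m @ rv, rv @ m @ iv],
                  [iv @ m @ rv, iv @ m @ iv]])
    _, vecs = np.linalg.eigh(g)
    cphi, sphi = vecs[:, -1]            # eigenvector of the largest eigenvalue
    phi = float(np.arctan2(sphi, cphi))
    x = m @ (np.cos(phi) * rv + np.sin(phi) * iv)
    # The eigenvector sign is arbitrary (phi + pi gives the same fit);
    # orient so the dominant species has positive amplitude.
    if x[int(np.argmax(np.abs(x)))] < 0:
        x, phi = -x, phi + np.pi
    model = (a @ x) * np.exp(1j * phi)
    r = s - model
    return phi, x, np.concatenate([r.real, r.imag])


def _candidates(res_psi: np.ndarray, psis: np.ndarray):
    """Best and second-best field-offset candidates per voxel.

    The second candidate is the minimum outside a guard band around the
    global minimum (the classic swapped solution sits roughly half an
    ambiguity period away).
    """
    n_psi, n_vox = res_psi.shape
    best = np.argmin(res_psi, axis=0)
    guard = max(n_psi // 6, 1)
    idx = np.arange(n_psi)[:, None]
    masked = np.where(np.abs(idx - best[None, :]) <= guard, np.inf, res_psi)
    second = np.argmin(masked, axis=0)
    cand_idx = np.stack([best, second], axis=1)
    cand_res = np.take_along_axis(res_psi, cand_idx.T, axis=0).T
    return cand_idx, cand_res


def _neighbors(flat: int, shape: tuple) -> list[int]:
    coords = list(np.unravel_index(flat, shape))
    out = []
    for ax in range(len(shape)):
        for step in (-1, 1):
            c = coords.copy()
            c[ax] += step
            if 0 <= c[ax] < shape[ax]:
                out.append(int(np.ravel_multi_index(c, shape)))
    return out


def _solve_candidate(s: np.ndarray, te: np.ndarray, c: np.ndarray,
                     psi0: float, psi_step: float, r2s: np.ndarray,
                     r2_max: float, refine: bool):
    """Polish one (psi, r2) candidate for a single voxel.

    Returns (psi, r2, residual, real amplitudes (W, F)).  Amplitudes and
    the shared phase are projected out analytically at every step, so
    only the two nonlinear parameters are searched.
    """
    best_r2, best_rn = 0.0, np.inf
    for r2 in r2s:
        _, _, rvec = _phase_opt_solve(s, _design(te, c, psi0, r2))
        rn = float(rvec @ rvec)
        if rn < best_rn:
            best_rn, best_r2 = rn, r2
    psi, r2 = float(psi0), float(best_r2)

    if refine:
        def vp_resid(p):
            return _phase_opt_solve(s, _design(te, c, p[0], p[1]))[2]

        sol = least_squares(
            vp_resid, [psi, r2],
            bounds=([psi - 2 * psi_step, 0.0], [psi + 2 * psi_step, 2 * r2_max]),
            method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
        psi, r2 = float(sol.x[0]), float(sol.x[1])

    _, wf, rvec = _phase_opt_solve(s, _design(te, c, psi, r2))
    return psi, r2, float(rvec @ rvec), np.clip(wf, 0.0, None)


def separate_fat_water(series: DixonSeries, n_psi: int = 73, n_r2: int = 13,
                       r2_max: float = 300.0, refine: bool = True,
                       region_grow: bool = True) -> FatWaterResult:
    """Estimate water, fat, R2*, field map and fat fraction per voxel.

    ``n_psi``/``n_r2`` set the coarse search grid; the field-offset grid
    spans one full ambiguity period ``1 / delta-TE`` centred on zero.
    Both candidate minima of the field-offset residual profile (the true
    solution and its water/fat-swapped alias) are polished per voxel by
    trust-region least squares on the variable-projection residual; the
    clearly better one wins, and near-ties are resolved by region
    growing from the brightest voxel, preferring field-map continuity
    with already-assigned neighbours.
    """
    S = series.echoes
    te = series.echo_times
    if S.shape[0] < 3:
        raise ValueError("fewer echoes than unknowns")
    c = fat_phase_factors(te, series.field_strength, series.fat_spectrum)
    shape = series.spatial_shape
    Sv = S.reshape(S.shape[0], -1)
    n_vox = Sv.shape[1]

    dte = float(np.mean(np.diff(te)))
    psi_half = 1000.0 / (2.0 * dte)
    psis = np.linspace(-psi_half, psi_half, n_psi)
    r2s = np.linspace(0.0, r2_max, n_r2)
    psi_step = psis[1] - psis[0]

    res_psi = _grid_residuals(Sv, te, c, psis, r2s)
    cand_idx, _ = _candidates(res_psi, psis)

    magnitude = np.abs(Sv).sum(axis=0)
    undefined = magnitude == 0
    energy = np.einsum("ev,ev->v", Sv.conj(), Sv).real

    # Polish both candidates everywhere.
    n_cand = cand_idx.shape[1]
    cand_psi = np.zeros((n_vox, n_cand))
    cand_r2 = np.zeros((n_vox, n_cand))
    cand_rn = np.full((n_vox, n_cand), np.inf)
    cand_amp = np.zeros((n_vox, n_cand, 2))
    for v in range(n_vox):
        if undefined[v]:
            continue
        for k in range(n_cand):
            psi, r2, rn, amp = _solve_candidate(
                Sv[:, v], te, c, float(psis[cand_idx[v, k]]), psi_step,
                r2s, r2_max, refine)
            cand_psi[v, k], cand_r2[v, k], cand_rn[v, k] = psi, r2, rn
            cand_amp[v, k] = amp

    # Sort candidates so column 0 holds each voxel's residual-best solution.
    order = np.argsort(cand_rn, axis=1)
    cand_rn = np.take_along_axis(cand_rn, order, axis=1)
    cand_psi = np.take_along_axis(cand_psi, order, axis=1)
    cand_r2 = np.take_along_axis(cand_r2, order, axis=1)
    cand_amp = np.take_along_axis(cand_amp, order[..., None], axis=1)

    # Per-voxel residuals carry a single degree of freedom, so the swap
    # discrimination is weak in noise.  Confidence is the residual ratio
    # of the two candidates; region growing starts at the most confident
    # bright voxel and lets low-confidence voxels follow the field-map
    # continuity of their already-assigned neighbours.
    tol = 1e-9 * np.maximum(energy, np.max(energy, initial=0.0) * 1e-12)
    ratio = cand_rn[:, 1] / np.maximum(cand_rn[:, 0], tol)
    bright = magnitude > 0.05 * np.max(magnitude, initial=0.0)
    ambiguous = (ratio < 1.5) & \
        (np.abs(cand_psi[:, 1] - cand_psi[:, 0]) > psi_half / 4) & \
        bright & ~undefined

    choice = np.zeros(n_vox, dtype=int)
    if region_grow and n_vox > 1:
        conf = np.where(bright & ~undefined, np.minimum(ratio, 1e12), 0.0)
        # Seed at a confident voxel that agrees with the consensus field
        # offset; an isolated confidently-wrong voxel must not set the
        # reference for the whole region.
        psi_best = cand_psi[:, 0]
        sel = bright & ~undefined
        med = float(np.median(psi_best[sel])) if np.any(sel) else 0.0
        agree = np.abs(psi_best - med) < psi_half / 4
        seed_conf = np.where(agree, conf, 0.0)
        seed = int(np.argmax(seed_conf if np.any(seed_conf > 0) else conf))
        psi_sel = np.full(n_vox, np.nan)
        visited = np.zeros(n_vox, dtype=bool)
        heap = [(-conf[seed], seed)]
        while heap:
            _, v = heapq.heappop(heap)
            if visited[v]:
                continue
            visited[v] = True
            nb = [w for w in _neighbors(v, shape) if visited[w]]
            if nb:
                # Continuity only: for near-pure voxels the swapped alias
                # can fit better than the truth, so residuals must not
                # veto the neighbourhood field offset.
                ref = float(np.nanmean(psi_sel[nb]))
                choice[v] = int(np.argmin(np.abs(cand_psi[v] - ref)))
            psi_sel[v] = cand_psi[v, choice[v]]
            for w in _neighbors(v, shape):
                if not visited[w]:
                    heapq.heappush(heap, (-conf[w], w))

    rows = np.arange(n_vox)
    water = cand_amp[rows, choice, 0]
    fat = cand_amp[rows, choice, 1]
    r2star = cand_r2[rows, choice]
    field_map = cand_psi[rows, choice]
    water[undefined] = fat[undefined] = 0.0

    total = water + fat
    undefined |= total <= 1e-12 * max(float(total.max()), 1e-300)
    ff = np.zeros(n_vox)
    ok = ~undefined
    ff[ok] = 100.0 * fat[ok] / total[ok]
    ff = np.clip(ff, 0.0, 100.0)

    return FatWaterResult(
        water=water.reshape(shape), fat=fat.reshape(shape),
        r2star=r2star.reshape(shape), field_map=field_map.reshape(shape),
        ff=ff.reshape(shape), undefined_mask=undefined.reshape(shape),
        n_ambiguous=int(np.count_nonzero(ambiguous)),
    )


# ---------------------------------------------------------------------------
# Magnitude noise handling and summaries
# ---------------------------------------------------------------------------

def noise_bias_correct(magnitude, noise_sd: float):
    """First-moment noise-bias correction of magnitude data.

    Subtracts the two-channel quadrature noise power:
    ``sqrt(max(M^2 - 2 sigma^2, 0))``.  Voxels at or below the noise
    floor return 0.
    """
    m = np.asarray(magnitude, dtype=float)
    if np.any(m < 0):
        raise ValueError("magnitudes must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    return np.sqrt(np.clip(m * m - 2.0 * noise_sd ** 2, 0.0, None))


def estimate_noise_sd(background_values) -> float:
    """Gaussian channel sigma from a background (air) magnitude ROI.

    Background magnitudes are Rayleigh distributed; their sd equals
    ``sigma * sqrt(2 - pi/2)``, so the ROI sd is divided by that factor.
    """
    vals = np.asarray(background_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two background voxels")
    return float(vals.std(ddof=1) / RAYLEIGH_SD_FACTOR)


def summarize_ff(ff_map, mask, undefined=None, slice_axis: int = -1) -> FatFractionSummary:
    """Mean fat fraction over a labelled mask with a per-slice breakdown.

    ``undefined`` marks voxels whose water+fat signal vanished; they are
    excluded from the averages and counted in ``n_excluded``.
    """
    ff = np.asarray(ff_map, dtype=float)
    m = np.asarray(mask).astype(bool)
    if m.shape != ff.shape:
        raise ValueError("mask and fat-fraction map shapes differ")
    valid = m.copy()
    n_excluded = 0
    if undefined is not None:
        und = np.asarray(undefined).astype(bool)
        if und.shape != ff.shape:
            raise ValueError("undefined mask shape differs from map")
        n_excluded = int(np.count_nonzero(valid & und))
        valid &= ~und
    if not np.any(valid):
        raise ValueError("mask selects no (valid) voxels")

    per_slice = []
    if ff.ndim >= 2:
        ax = slice_axis % ff.ndim
        for k in range(ff.shape[ax]):
            sl = [slice(None)] * ff.ndim
            sl[ax] = k
            vs, ms = ff[tuple(sl)], valid[tuple(sl)]
            if np.any(ms):
                per_slice.append((k, float(vs[ms].mean()), int(ms.sum())))
    return FatFractionSummary(mean_ff=float(ff[valid].mean()),
                              n_voxels=int(valid.sum()),
                              per_slice=per_slice, n_excluded=n_excluded)
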
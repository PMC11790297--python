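# Methods

This note documents the models implemented in `naqms`, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that shape the results.

## Signal models

### Biexponential ²³Na T2* (time domain)

Tissue sodium is a spin-3/2 nucleus; quadrupolar interactions in
motion-restricted environments split its transverse relaxation into a
fast and a slow component. The magnitude of the FID is modelled as

    M(t) = M_fast·e^(−t/T2*_fast) + M_slow·e^(−t/T2*_slow) + noise term,

with t measured from the centre of the excitation pulse, so the first
sample (default t₀ = 0.16 ms) already carries relaxation. Parameters
are bounded (amplitudes ≥ 0, T2* ∈ [0.05, 500] ms) and fitted with
SciPy's trust-region reflective solver. Without a user initialisation,
five starts with (fast, slow) T2* pairs log-spaced over [0.3, 50] ms and
a 50/50 amplitude split are run and the lowest-RSS solution wins, ties
going to the smaller fast T2*. Components are sorted post-fit; fits
whose two T2* values differ by < 5% are flagged "effectively
monoexponential". The reported fast fraction is
M_fast/(M_fast + M_slow), excluding the noise term.

**Noise term.** Complex Gaussian noise makes the magnitude Rician, whose
mean is ≈ √(S² + 2σ²) — an additive constant only when S ≫ σ. The noise
term is therefore modelled as a quadrature floor,
M_model = √(signal² + c²) with fitted c (`noise_model="quadrature"`,
the default). The plain additive offset (`noise_model="offset"`) is
retained but mis-tracks the floor crossover: in our 200-replicate SNR-50
simulations it biases the recovered slow T2* ≈ 17% low, versus ≈ 1.5%
for the quadrature model. A full Rician likelihood was deliberately not
implemented; the quadrature mean approximation is accurate to ~1% of σ
except within ~1σ of zero signal.

### Spectra and peak areas

FIDs are Fourier transformed after optional exponential apodization and
zero-filling, with the first point halved (the standard convention that
keeps the baseline flat and Parseval-based bookkeeping consistent).
Peak area is a trapezoidal integral of the magnitude spectrum over a
window, after subtracting a linear baseline through the 10-point edge
means (window default ±250 Hz in pipeline use; configurable).

### Water amplitude and T2

The proton voxel in tibialis anterior muscle is water-dominated, so a
single exponentially damped complex sinusoid
A·e^(iφ)·e^((2πif/1000 − 1/τ)t) is fitted to each echo's FID; A is the
t = 0 extrapolate. Water T2 comes from S(TE) = S0·e^(−TE/T2) across the
six echo times {30, 40, 60, 80, 100, 150} ms, T2 bounded in (1, 1000)
ms, initialised from a log-linear regression; non-decaying input or a
bound-pinned T2 is flagged, never silently returned.

### Tissue sodium concentration

Na_TA = Na_P · (SI_TA/SI_P) · D_P(TE)/D_TA(TE), where D is the
biexponential retention factor and the 20 mM standard is the reference
(the 10/30/40 mM standards feed the calibration linearity check only).
SI values are ROI means of magnitude images; no noise-mean subtraction
is applied inside the formula (it belongs to the SNR definition), and
users may pre-correct with `noise_bias_correct` if desired. The
correction TE defaults to the radial acquisition's 0.28 ms; the
cartesian 1.89 ms is a parameter away. Applying the formula to ROI-mean
signals (rather than per-voxel then averaging) is an interpretation;
with uniform ROIs the two agree exactly. Phantom relaxometry is a
one-off calibration: defaults m_fast/m_slow = 0.6/0.4, T2* = 4/18 ms,
typical of 3% agarose sodium gels; synthetic scenes render and invert
with the same values, so recovery does not depend on this choice.

### Recovery kinetics

v(t) = baseline + (s0 − baseline)·2^(−t/T½), T½ bounded in (10, 10⁴) s,
95% CI from the asymptotic covariance. The base-2 parameterisation
reports half-lives directly (τ = T½/ln 2 via a helper). The sodium
course rises before decaying, so the fitted segment starts at the peak:
located after 3-point smoothing, never earlier than the raw maximum,
and the fit drops up to two leading samples when doing so collapses the
mean squared residual by 4× or more — the signature of a sample on the
rise straddling the true peak. Water T2 always fits from the first
timepoint. Timestamps sit at scan midpoints (129 s sodium, 45 s proton
windows, interleaved). Group-mean curves interpolate subjects onto a
common grid before averaging. Per-timepoint Wilcoxon signed-rank tests
use the exact null for n ≤ 25 without zeros/ties, otherwise the normal
approximation with continuity correction.

### Dixon fat-water separation

Per voxel, S(TE) = (W + F·c(TE))·e^(2πiψTE)·e^(−TE·R2*) with a six-peak
fat spectrum c(TE) (bulk methylene at 1.30 ppm carrying 0.70 of the
amplitude; table shipped as package data and overridable), a single R2*
shared by water and fat, and field offset ψ in Hz. W and F are real
with one shared phase: with three echoes a fully complex (W, F) model
is exactly determined and cannot reject the water/fat-swapped alias,
while the shared-phase constraint leaves one residual degree of freedom
that does. For fixed (ψ, R2*) the amplitudes and phase are eliminated
in closed form (the explained energy is the largest eigenvalue of a
2×2 form), so the coarse search — 73 ψ values spanning one ambiguity
period × 13 R2* values in [0, 300] s⁻¹ — is fully vectorised across
voxels. The best and second-best ψ basins are polished per voxel by
trust-region least squares on the projected residual.

**Swap resolution.** One residual degree of freedom discriminates
weakly in noise, and near-pure voxels are almost exactly aliased, so
candidate choice relies on field-map smoothness: region growing is
seeded at a high-confidence voxel that agrees with the consensus
(median) field offset and each voxel takes the candidate closest to its
visited neighbours' ψ. Voxels whose two candidates fit comparably and
sit far apart are counted in `n_ambiguous`. Limitation: a genuinely
sharp field-map step can still be followed incorrectly, and in stress
tests at 2% complex noise roughly one volume in fifty shows a single
mid-FF voxel flip; noiseless accuracy is ~10⁻¹¹ percentage points over
FF 0–100%.

Magnitude noise bias is corrected as √(max(M² − 2σ², 0)); σ estimated
from a background ROI's Rayleigh sd via the factor √(2 − π/2). At
amplitude 5σ this correction over-corrects by ≈ 2.2% (Jensen concavity
near the floor) after removing the +2.0% raw Rician bias.

### Statistics

Mann–Whitney U: exact p when the smaller group has ≤ 8 observations and
the pooled data are tie-free, otherwise asymptotic with tie and
continuity corrections; both p-values are reported when computable,
since which one a given SPSS analysis used is generally unknowable.
Ties take average ranks everywhere. Significance is two-tailed at
α = 0.05. The summary table reports the integer percent difference
100·(mean_DP − mean_HV)/mean_HV per variable and lists variables with
missing data instead of dropping them. No multiple-testing correction
is applied, by design.

## The synthetic-data generator

The generator emulates the study's acquisitions with known truth:

- **FIDs**: 1024 samples, 0.125 ms dwell (128 ms readout), t₀ = 0.16 ms,
  complex circular Gaussian noise per channel (magnitudes Rician).
- **Echo series**: the six PRESS echo times with Gaussian noise.
- **Dynamics**: interleaved cadence (129 s + 45 s cycles, ≥ 10 cycles,
  default 12 ≈ 35 min; `post_exercise_span` overrides). Healthy sodium:
  linear ramp from a configurable start (default 25% of the elevation)
  to the peak at 480 s, then baseline + A·2^(−Δt/636 s). The ramp shape
  is a modelling choice — only "rises over ~8 min" is known — and its
  start value is exposed rather than fixed. Healthy water T2 peaks at
  the first timepoint and declines with T½ = 620 s. Patient series are
  flat with a 2% downward trend over the span, at a small elevation
  (peak ratios 1.085/1.07 from the published pre/post means).
- **Sodium image scenes**: a TA disc at the subject's concentration with
  the subject's relaxometry, four phantom discs (10–40 mM) with the
  calibration relaxometry, an air background; target-SNR rendering
  inverts the magnitude-SNR definition including the Rayleigh terms.
- **Dixon volumes**: the forward model above at TEs {3.45, 4.60, 5.75}
  ms, 3 T.
- **Cohorts**: truncated-normal draws per parameter (concentrations
  > 0, FF ∈ [0, 100], fractions ∈ [0, 1], T2* > 0; fast < slow enforced
  by redraw) using the published group means/SDs; dispersions that the
  study does not report (dynamic half-life, time-to-peak, peak-ratio
  SDs) were fixed once at plausible magnitudes (60 s, 60 s, 0.02–0.05)
  and are configurable.

What it does **not** emulate: k-space/radial sampling, coil
sensitivities and B1 inhomogeneity, frequency drift, lipid resonances
in the proton voxel, partial volume, motion, or any correlation
structure between a subject's parameters. Passing recovery tests
therefore demonstrates correctness of the inverse methods under the
stated signal models, not robustness to every artefact of real scanner
data.

## Problem sizes and determinism

Simulation sizes were chosen to keep the full test suite under a minute
of compute while leaving Monte-Carlo error well inside the asserted
bands: 200 replicates for the SNR-50 relaxometry and recovery-CI runs,
50–100 for image-SNR and power checks, 11×3-voxel volumes for the Dixon
sweep. All randomness flows through `numpy.random.default_rng` /
`SeedSequence`; equal seeds give bitwise-equal outputs. The
recovery-CI simulations derive their per-point noise from the published
CI itself through the fit's asymptotic covariance — the published
uncertainty is known, the raw scatter is not — and a calibrated
estimator then lands inside the CI with binomial(n, 0.95) frequency,
which is what the corresponding test asserts (lower bound 0.92 at
n = 200).

## Known limitations

- Magnitude-domain (not complex/phased) relaxometry fitting; the
  quadrature floor is an approximation to the Rician mean, not a
  likelihood.
- Dixon swap resolution assumes a smooth field map; no 2-point or
  ≥ 6-echo variants; no T1-bias or motion correction.
- No B1/coil-profile correction in concentration quantification.
- The per-timepoint baseline tests are marginal Wilcoxon tests, not a
  longitudinal mixed model.
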
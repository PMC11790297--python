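# naqms

Quantitative **²³Na/¹H muscle MR analysis** for volume-localised sodium
spectroscopy studies of skeletal muscle — built for studies that compare
dysferlinopathy patients (DP) against matched healthy volunteers (HV) at
rest and dynamically after exercise, and for anyone who needs tested,
reusable implementations of the underlying signal models.

## What it computes

**Biexponential ²³Na T2\* relaxometry.** Tissue sodium relaxes with fast
and slow transverse components; the magnitude of the time-domain FID is
fitted as

```
M(t) = M_fast·exp(−t/T2*_fast) + M_slow·exp(−t/T2*_slow) + noise floor
```

with a trust-region reflective least-squares solver, multi-start
initialisation, and a Rician-aware quadrature noise floor
`sqrt(signal² + c²)`. The fast fraction `M_fast/(M_fast+M_slow)` indexes
sodium in motion-restricted (macromolecule-dense) environments.

**Tissue sodium concentration.** ROI signal referenced to a 20 mM NaCl
standard with relaxation correction at echo time TE:

```
Na_TA = Na_P · (SI_TA/SI_P) · [Ms_P·e^(−TE/T2*s,P) + Mf_P·e^(−TE/T2*f,P)]
                              / [Ms_TA·e^(−TE/T2*s,TA) + Mf_TA·e^(−TE/T2*f,TA)]
```

plus magnitude-image SNR `(mean signal − mean noise)/sd(noise)`, central
slice summation and a phantom calibration linearity check.

**Post-exercise recovery kinetics.** Sodium amplitude rises for ~8 min
post-exercise then recovers; water ¹H T2 peaks immediately. Both are
summarised by a three-parameter exponential,
`v(t) = baseline + (s0 − baseline)·2^(−t/T½)`, with an asymptotic 95% CI
on the half-life, peak finding, and per-timepoint Wilcoxon signed-rank
tests against each subject's pre-exercise baseline.

**Water T2.** Single-resonance amplitude per echo (damped-sinusoid fit to
the complex FID) and a monoexponential `S0·exp(−TE/T2)` fit across echo
times.

**3-point Dixon fat fraction.** Water/fat separation from three complex
echoes with a six-peak fat spectral model, a single shared R2\*, a B0
field-offset map with swap resolution by consensus-seeded region
growing, magnitude noise-bias correction, and masked FF% summaries.

**Group statistics.** Mann–Whitney U (exact and tie-corrected
asymptotic), Spearman rank correlation, Wilcoxon signed-rank, and a
cohort summary table with integer percent group differences.

**Synthetic data.** Every input above can be generated with known ground
truth (`naqms.synthetic_data`): FIDs, echo series, interleaved dynamic
timelines, sodium image scenes with positioned phantoms, Dixon volumes
and full two-group cohorts — seeded and bit-for-bit reproducible. The
generator defaults are the study's published group means/SDs, so every
pipeline stage is testable by parameter recovery.

## Worked example

```bash
python examples/biexp_t2star_relaxometry.py
```

```
generating truth: T2*_fast=2.2 ms, T2*_slow=13.4 ms, fast fraction=46%
noiseless: T2*_fast= 2.200 ms  T2*_slow=13.400 ms  fast fraction= 46.0%  (converged=True)
   SNR 50: T2*_fast= 2.055 ms  T2*_slow=12.851 ms  fast fraction= 44.9%  (converged=True)
```

The noiseless fit returns the generating relaxometry to machine
precision; a single FID at SNR 50 recovers it to a few percent. The
other examples cover concentration quantification
(`sodium_concentration.py` — recovers 19.6/36.2 mM exactly from
noiseless scenes), recovery kinetics (`post_exercise_recovery.py` —
half-lives 636 s and 620 s), Dixon mapping (`dixon_fat_fraction.py` —
max error ~1e-11 percentage points across FF 0–100%) and cohort
statistics (`cohort_statistics.py`).

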
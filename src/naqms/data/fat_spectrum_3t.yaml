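# Six-peak triglyceride spectral model used by the Dixon fat-water separation.
# Chemical shifts are absolute ppm positions; the water resonance sits at 4.7 ppm.
# Relative amplitudes sum to 1.  Users may supply their own table of the same
# shape through DixonSeries(fat_spectrum=...) or a study config file.
water_ppm: 4.7
peaks:
  - {ppm: 5.30, amplitude: 0.048}   # olefinic -CH=CH-
  - {ppm: 4.20, amplitude: 0.039}   # glycerol -CH2-O-
  - {ppm: 2.76, amplitude: 0.006}   # diallylic =CH-CH2-CH=
  - {ppm: 2.10, amplitude: 0.120}   # alpha-carboxyl / allylic -CH2-
  - {ppm: 1.30, amplitude: 0.700}   # bulk methylene -(CH2)n-
  - {ppm: 0.90, amplitude: 0.087}   # terminal methyl -CH3
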
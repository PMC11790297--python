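"""Three-echo Dixon fat-water separation and TA fat-fraction summary.

Renders a small three-echo complex volume whose rows span fat fractions
0-100%, reconstructs water/fat/R2*/field maps with the multi-peak
spectral model, and summarises the fat fraction over a mask.
"""

import numpy as np

from naqms import make_dixon_volume, separate_fat_water, summarize_ff
from naqms.dixon_ff import noise_bias_correct

ff_true = np.linspace(0.0, 100.0, 11).reshape(-1, 1) * np.ones((11, 4))
volume = make_dixon_volume(ff_true, water_t2star=25.0, field_map_hz=30.0)
result = separate_fat_water(volume)

print("true ff per row :", ff_true[:, 0].round(1))
print("estimated ff    :", result.ff.mean(axis=1).round(2))
print(f"max |error|     : {np.abs(result.ff - ff_true).max():.2e} pp")
print(f"R2* (truth 40/s): {result.r2star.mean():.2f} 1/s, "
      f"field map (truth 30 Hz): {result.field_map.mean():.2f} Hz")

mask = ff_true > 0
summary = summarize_ff(result.ff, mask, undefined=result.undefined_mask)
print(f"masked mean ff  : {summary.mean_ff:.2f}% over {summary.n_voxels} voxels")

# magnitude noise-bias correction at work
m = np.array([0.5, 1.0, 5.0])
print("bias-corrected magnitudes (sigma=0.3):",
      noise_bias_correct(m, 0.3).round(3))
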
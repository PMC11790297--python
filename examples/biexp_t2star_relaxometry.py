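"""Biexponential 23Na T2* relaxometry on a synthetic muscle FID.

Generates one noiseless and one noisy (SNR 50) sodium free induction
decay with healthy-control baseline relaxation parameters, fits both
with the magnitude-domain biexponential model, and prints the recovered
fast/slow T2* components and the fast-decaying signal fraction.
"""

import numpy as np

from naqms import fit_biexp_t2star, make_fid
from naqms.synthetic_data import HV_TRUTH

truth = HV_TRUTH
print(f"generating truth: T2*_fast={truth.true_t2s_fast} ms, "
      f"T2*_slow={truth.true_t2s_slow} ms, "
      f"fast fraction={100 * truth.true_m_fast_fraction:.0f}%")

for label, noise_sd, seed in [("noiseless", 0.0, None), ("SNR 50", 0.0192, 1)]:
    fid = make_fid(truth, noise_sd=noise_sd, seed=seed)
    fit = fit_biexp_t2star(fid)
    print(f"{label:>9}: T2*_fast={fit.t2s_fast:6.3f} ms  "
          f"T2*_slow={fit.t2s_slow:6.3f} ms  "
          f"fast fraction={100 * fit.m_fast_fraction:5.1f}%  "
          f"(converged={fit.converged})")

# The fast fraction reflects sodium in motion-restricted (macromolecule
# dense) environments; healthy muscle sits near a 46/54 fast/slow split.
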
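"""Validate the histogram entropy/MI estimators on Gaussian closed forms,
then apply them to a coupled cardiac pair.

For a standard Gaussian the differential entropy is 0.5·log2(2πe) ≈ 2.047
bits; for a bivariate Gaussian with correlation ρ the mutual information is
−0.5·log2(1−ρ²) ≈ 0.2075 bits at ρ = 0.5.  On cardiac pairs the channels are
z-scored and a shared bin width Δb = 0.4833 is used.
"""

import numpy as np

from vfegm import (
    GAUSSIAN_PRESETS,
    GaussianConfig,
    VFSignalConfig,
    estimate_entropy,
    estimate_mi,
    generate_bivariate_gaussian,
    generate_vf_pair,
    info_measures_for_pair,
)

x, y = generate_bivariate_gaussian(
    GaussianConfig(n_samples=200_000, covariance=GAUSSIAN_PRESETS["correlated"], seed=0)
)
h = estimate_entropy(x, 0.05)
m = estimate_mi(x, y, 0.25)
print(f"Gaussian entropy: {h.value:.4f} bits   (closed form {0.5 * np.log2(2 * np.pi * np.e):.4f})")
print(f"Gaussian MI (rho=0.5): {m.mi:.4f} bits (closed form {-0.5 * np.log2(0.75):.4f})")

for coupling in (0.0, 0.5, 1.0):
    pair = generate_vf_pair(VFSignalConfig(coupling=coupling, seed=3))
    mm = info_measures_for_pair(pair)
    print(
        f"coupling={coupling:.1f}: H(LV)={mm.h_lv:.3f}  H(RV)={mm.h_rv:.3f}  "
        f"H(LV,RV)={mm.h_joint:.3f}  MI={mm.mi:.3f} bits"
    )
print("\nMI rises with the coupling knob; the identity MI = H(LV)+H(RV)-H(LV,RV) is exact.")
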
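"""Extract the 255-feature texture vector of a single tumor.

Features are computed per axial slice over the mask-restricted tumor and
averaged; the vector is ordered and named (GLCM, RLM, LBP, SFTA, FD2, IH,
ACM1, ACM2 blocks).
"""

import tumortex as tx

tumor = tx.generate_tumor(label=0, texture_effect=1.0, seed=3)
fv = tx.extract_tumor_features(tumor)
s = fv.as_series()

print(f"vector length: {len(s)}")
print("\nselected features:")
for name in (
    "glcm.G2_contrast",
    "glcm.G18_renyi",
    "rlm.R1_sre",
    "ih.I2_std",
    "acm2.M9_entropy",
    "acm2.M11_diff_entropy",
    "fd2.F2_1_max_mean",
):
    print(f"  {name:<26} {s[name]: .4f}")
print("\nprovenance:", {k: fv.provenance[k] for k in ("d", "N", "q", "r", "l", "n_theta")})
# M11 (ACM2 difference entropy) measures how spread the joint distribution
# of neighboring gradient orientations is -- low for a tumor with one
# dominant edge direction, high for incoherent texture.  FD2 max_mean is
# the largest per-slice average local fractal dimension (~2 = flat relief).
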
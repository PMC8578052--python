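"""Compute an intensity-diffusion matrix from a synthetic mask phantom.

Rasterizes two adjacent ellipsoidal "organs" on a 0.2 mm voxel grid,
blurs each with the 0.5 mm FWHM Gaussian that models FMT resolution, and
prints the resulting spillover fractions: entry [i, j] is the share of
organ i's fluorescence that is measured inside region j ("others" is the
surrounding tissue).
"""

import numpy as np

import fmtpk as F

spec = F.MaskPhantomSpec(
    shape=(60, 40, 40),
    spacing_mm=0.2,
    ellipsoids=(
        F.Ellipsoid(center=(22, 20, 20), semi_axes=(7.5, 10, 10), label="organ_a"),
        F.Ellipsoid(center=(38, 20, 20), semi_axes=(7.5, 10, 10), label="organ_b"),
    ),
)
masks = F.make_phantom(spec)
idv = F.compute_idv(masks, fwhm_mm=0.5, order=("organ_a", "organ_b"))

labels = ["organ_a", "organ_b", "others"]
print("intensity-diffusion matrix (rows: source, columns: measured):")
print(f"{'':10s}" + "".join(f"{l:>10s}" for l in labels))
for i, l in enumerate(labels):
    print(f"{l:10s}" + "".join(f"{v:10.4f}" for v in idv[i]))
print("\nrow sums are 1 (reflective blur conserves intensity):",
      np.round(idv.sum(axis=1), 6))
print("adjacent organs exchange a few percent of signal; distant ones none")
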
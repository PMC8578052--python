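"""Inspect the mixing matrix and what it does to a pure-lung signal.

Assembles the 9x11 measurement operator from the published intensity-
diffusion matrix, the default relative-blood-volume fractions and the
liver/kidney sub-compartment fusion, then shows how 1 %ID placed in the
lung compartment spreads across the measured organ channels.  Without the
vascular term the numbers are exactly the lung row of the IDV matrix.
"""

import numpy as np

import fmtpk as F

idv = F.printed_idv()
print("published IDV row sums:", np.round(idv.sum(axis=1), 3))

mix = F.assemble_mixing()
print("\nmixing matrix M (9 channels x 11 compartments), first columns:")
print(np.round(mix.matrix[:, :4], 3))

state = np.zeros(11)
state[F.COMPARTMENTS.index("Lung")] = 1.0

# without the vascular term the measured vector is the IDV lung row
rbv_off = np.zeros(9)
rbv_off[F.CHANNELS.index("blood")] = 1.0
m_blur = F.assemble_mixing(rbv=rbv_off)
print("\n1 %ID in Lung, intensity diffusion only (= lung row of the IDV):")
for ch, v in zip(F.CHANNELS, F.apply_mixing(m_blur, state[:, None])[:, 0]):
    if v > 1e-6:
        print(f"  {ch:10s} {v:.3f} %ID")

measured = F.apply_mixing(mix, state[:, None])[:, 0]
print("\nwith the vascular term (default rBV; lung rBV=0.5 halves the "
      "tissue share):")
for ch, v in zip(F.CHANNELS, measured):
    if v > 1e-6:
        print(f"  {ch:10s} {v:.3f} %ID")
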
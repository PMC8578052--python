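"""Simulate one noisy longitudinal scan series and recover the rates.

Builds a ground-truth rate set, forward-models the nine organ channels at
the 7-point scan schedule through the mixing matrix, adds 10% relative
noise, and fits both the corrected and the collapse-only model.  The
printed table compares true and estimated rates (1/min); the corrected
column should track the truth to roughly 10%, the uncorrected one not.
"""

import numpy as np

import fmtpk as F

truth = F.KineticParameters(
    np.array([0.018, 0.015, 0.002, 0.004, 0.012, 0.006, 0.009, 0.011])
)
known = F.KnownRates()
mix = F.assemble_mixing()  # printed IDV + default rBV + sub-compartment fusion
scheme = F.make_scheme("7")

meas = F.simulate_measurements(truth, known, mix, scheme, noise_level=0.10, seed=42)
res_c = F.fit(meas, known, mix, scheme)
res_u = F.fit_uncorrected(meas, known, scheme)

print(f"{'parameter':22s} {'true':>8s} {'corrected':>10s} {'uncorrected':>12s}")
for i, name in enumerate(F.PARAM_NAMES):
    print(
        f"{name:22s} {truth.values[i]:8.4f} {res_c.params.values[i]:10.4f} "
        f"{res_u.params.values[i]:12.4f}"
    )
print(
    f"\nmean relative error: corrected "
    f"{100 * F.relative_error(res_c.params, truth).mean():.1f}%, "
    f"uncorrected {100 * F.relative_error(res_u.params, truth).mean():.1f}%"
)
print(f"fit cost (SSE+penalty): corrected {res_c.cost.total:.1f}, "
      f"uncorrected {res_u.cost.total:.1f}")
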
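# fmtpk

Mixing-matrix-corrected whole-body pharmacokinetic modeling for
longitudinal hybrid µCT–FMT data.

Fluorescence-mediated tomography (FMT), fused with micro-CT anatomy, can
follow a fluorescently labeled compound through a mouse for days — but
its 1–3 mm resolution blurs fluorescence between neighboring organs, the
blood inside each organ contaminates its signal, and the liver and
kidneys mix the fluorescence of probe *elimination* (transit toward
intestine or bladder) with that of irreversible *retention*.  Fitting a
kinetic model directly to such organ curves biases the rate estimates
badly.  `fmtpk` implements the corrected approach: a linear mixing matrix
inside the forward model deconvolves all three effects during fitting.
It is a library for imaging scientists and pharmacokinetic modelers, with
a thin CLI for routine runs.

## Model

Compartment amounts `I` (% of injected dose) in eleven compartments
(Lung, Blood, LiverRet, LiverElim, Bone, Spleen, Intestine, KidneyRet,
KidneyElim, Bladder, Others) obey the mass-balancing system

```
dI/dt = K I ,        I(0) = 100 · e_Blood ,
```

with eight unknown Blood-outflow rates (two elimination inflows, five
retention rates, one exchange with the body remainder), each constrained
to [0.001, 0.02] min⁻¹, plus four fixed configuration rates (excretion
transit and back-diffusion).  Measurements resolve nine organ channels;
they are modeled as

```
I_m = M Î_c ,        M = IDVᵀ · S  (9×11),
```

where `S` fuses the liver/kidney sub-compartments and adds vascular
spillover via each organ's relative blood volume (rBV), and `IDV` is the
published 9×9 intensity-diffusion matrix of blur fractions (shipped with
the package; `compute_idv` rebuilds such matrices from segmentation masks
by 3D Gaussian blurring, FWHM 0.5 mm).  The eight rates minimize the
penalized least squares cost `Σ(Î_m − I_m)² + c·ΣK²` by Polak–Ribière+
nonlinear conjugate gradient with exact adjoint gradients of the discrete
RK4 → sampling → mixing chain, under a logistic box reparameterization.
See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

`examples/simulate_and_fit.py` simulates one noisy 7-scan series from a
known truth and fits both model arms:

```
parameter                  true  corrected  uncorrected
kKidneyElimination       0.0180     0.0172       0.0130
kLiverElimination        0.0150     0.0153       0.0135
kKidney                  0.0020     0.0021       0.0036
kLiver                   0.0040     0.0040       0.0046
kBone                    0.0120     0.0121       0.0099
kSpleen                  0.0060     0.0062       0.0049
kLung                    0.0090     0.0089       0.0058
kOthers                  0.0110     0.0125       0.0200

mean relative error: corrected 4.4%, uncorrected 35.3%
fit cost (SSE+penalty): corrected 44.1, uncorrected 1960.5
```

Rates are min⁻¹ (×100 for the %ID/min convention).  With the mixing
matrix in the forward model the estimates track the truth to a few
percent despite 10% measurement noise; the collapse-only fit misattributes
blurred and vascular signal to the wrong compartments.  The other
examples show the mixing matrix itself (`mixing_matrix.py`), the
spillover computation on a synthetic two-organ phantom
(`idv_from_phantom.py`), and a small recovery study
(`recovery_study.py`).

The CLI wraps the same functions:

```
fmtpk simulate --params-json truth.json --scheme 7 --noise 0.1 --out m.csv
fmtpk fit --measurements m.csv --scheme 7 --out report.json
fmtpk study --n 100 --schemes 7,7-early --seed 1 --out-dir out/
fmtpk idv --out idv.csv
```

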
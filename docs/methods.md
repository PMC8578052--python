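# Methods

## The model

`fmtpk` models the whole-body biodistribution of an intravenously injected
fluorescently labeled compound as a linear compartment system

    dI/dt = A I,        I(0) = 100 · e_Blood   (%ID),

over eleven compartments: Lung, Blood, LiverRet, LiverElim, Bone, Spleen,
Intestine, KidneyRet, KidneyElim, Bladder and Others.  Blood drives the
distribution; five retention sites (lung, liver, kidneys, bone, spleen)
trap the compound irreversibly; the liver and kidneys additionally carry
elimination sub-compartments feeding the hepatobiliary (→ intestine) and
renal (→ bladder) excretion routes; "Others" exchanges with blood in both
directions.  `A` is assembled so that `A[j, i]` holds the first-order rate
of the edge i→j and each diagonal entry the negative total outflow, hence
every column sums to zero and total %ID is conserved; the intestine and
bladder are absorbing, so the system is closed over the 72 h window.
Treating excreta as retained inside those compartments is an assumption:
it is the reading consistent with a strictly mass-balancing formulation,
and it does not affect the measured-channel predictions because neither
compartment feeds back.

Eight rates are unknown and estimated (all Blood outflows: the two
elimination inflows and the five retention rates plus the Blood→Others
exchange); they are constrained to a physiological box, by default
[0.001, 0.02] min⁻¹.  Four further rates are treated as known
configuration: LiverElim→Intestine = 0.01 min⁻¹, KidneyElim→Bladder =
0.01 min⁻¹, Others→Blood = 0.005 min⁻¹, and a zero-rate intestinal edge
(the excreta compartments absorb).  These values are documented
assumptions — the transit rates through the elimination pools are not
identifiable from organ-level data on this schedule and must come from
prior experiments; they are exposed in `KnownRates` and in the
configuration file.

Units: all rates min⁻¹, the integration grid minutes, sampling-scheme
times hours (converted internally).  The per-minute convention follows
from the bound pair (0.001, 0.02) min⁻¹, whose ×100 scale matches rates
conventionally quoted as %ID/min.

## Measurement model: the mixing matrix

Fluorescence tomography resolves ~1–3 mm, so the signal extracted from a
segmented organ is not the compartment content.  The measured nine-channel
vector is modeled as `I_m = M I` with `M = IDVᵀ · S` (9×11):

* **Sub-compartment fusion and vascular spillover** (`S`, 9×11): each
  non-blood channel j is, in the default *blend* mode,
  `S[j,·] = (1−rBV_j)·Collapse[j,·] + rBV_j·e_Blood`, a convex
  combination of the fused tissue signal (liver = LiverRet+LiverElim,
  kidneys = KidneyRet+KidneyElim, all others one-to-one) and the blood
  signal weighted by the organ's relative blood volume.  The blood
  (heart) channel is pure blood.  An *additive* mode
  (`Collapse + rBV·e_Blood`) is provided as well; blend is the default
  because it preserves the signal scale of well-perfused organs.
* **Intensity diffusion** (`IDV`, 9×9): the published matrix of blur
  fractions, rows = source organs, columns = measured organs (hence the
  transpose when applying it).  Its diagonal entries are each the row
  maximum and row sums lie in [0.903, 0.999].  The packaged CSV is the
  authoritative copy; a unit test pins the lung row (0.717 self, 0.122
  into bone, 0.115 into others) against the assembled operator to
  prevent orientation drift.

The rBV fractions are configuration, not measurement; defaults (lung
0.50, liver 0.30, spleen 0.35, kidneys 0.24, bone 0.11, intestine 0.10,
bladder 0.05, others 0.05, blood 1.0) are literature-style perfusion
values and every quantity that depends on them says so.

`compute_idv` reproduces the construction of such a matrix from organ
segmentations: each mask indicator is blurred with an isotropic 3D
Gaussian (default FWHM 0.5 mm, σ = FWHM/(2√(2 ln 2))), with reflective
boundaries so intensity is conserved on the grid, and entry [i, j] is the
fraction of source i's blurred intensity inside region j.  The
fraction-of-total normalization was chosen over a mean-within-mask
normalization because it yields near-unity row sums like the published
matrix.  Ellipsoid phantoms (`fmtpk.phantom`) provide synthetic
segmentations for testing; they do not emulate real anatomy.

## Fitting

The eight rates minimize

    f(K) = Σ (Î_m − I_m)² + c Σ K²,

where `Î_m` is the model prediction: RK4 integration on a fine grid
(default 1-min steps over 0–4320 min; a step-halving test guards the
resolution), linear-interpolation sampling at the scheme times, then `M`.
The penalty weight defaults to `c = 1e−4`, small enough that the penalty
is orders of magnitude below the data term on the %ID scale while still
discouraging runaway rates; it is exposed in `FitConfig` and the
noise-free bias it induces is verified to vanish as c → 0.

Because `A` is constant, the four-stage RK4 update is exactly one
multiplication by `Φ = I + hA + (hA)²/2 + (hA)³/6 + (hA)⁴/24`; the engine
therefore advances between sample nodes with integer matrix powers of
`Φ`, which is the same discrete RK4 solution evaluated without the
per-minute loop (the equivalence is tested to machine precision against
the explicit stage recursion).  Gradients are exact reverse-mode (adjoint)
derivatives of this discrete chain: residuals are injected into the
costate at the sample nodes (split across neighboring nodes when a time
is interpolated), the costate is propagated backward with `Φᵀ`, and the
sensitivity `G = Σ_n λ_n x_{n−1}ᵀ` over all fine steps is accumulated
per segment with the doubling recursion for `Σ_j P^{Δ−1−j} C P^j`.  The
gradient with respect to each rate is the Frobenius product of `G` with
the directional derivative of the RK4 polynomial, obtained from the
block-matrix identity.  Two independent oracles check this in the tests:
central finite differences (1e−5 relative) and a complex-step
re-implementation of the entire chain (1e−10 relative).

Minimization uses Polak–Ribière+ nonlinear conjugate gradient with
restarts every 8 iterations (the parameter count) and an Armijo
backtracking line search (c₁ = 1e−4, shrink 0.5) with step memory.  Box
constraints are handled by the logistic reparameterization
`K = lo + (hi−lo)·σ(θ)`; a projection mode is available.  Two numerical
safeguards matter in the transformed space: the first line-search trial
is capped so no coordinate moves more than one logit unit (raw gradients
on the %ID scale are large and would otherwise jump straight into
logistic saturation, where the Jacobian underflows to zero and the
iteration freezes at a box corner), and θ is clipped to ±12, which keeps
rates within 6e−6 of their bounds while keeping the transform
differentiable.  Stopping: transformed-space gradient norm < 1e−8, or
relative cost change < 1e−10, or 500 iterations (then the result carries
`converged=False`).  Default start is the box midpoint; a seeded
uniform-random multi-start is available.  The optimizer's internals
(start, line search, penalty weight, stopping rule) are package choices
and are echoed in every CLI report.

## Simulation study

`run_study` draws n = 100 rate sets i.i.d. uniform on [0.001, 0.02]
min⁻¹, forward-models each through the full mixing matrix at the chosen
schemes, multiplies every measurement by `1 + 0.10·ε` with ε standard
normal (clipping negatives to zero; a uniform noise model of the same SD
scale is selectable), and fits each replicate with the corrected model
and with the collapse-only model (`fit_uncorrected`: sub-compartments
still summed per channel, but no blur and no vascular term).  Reading
"10% relative noise" as multiplicative Gaussian with σ = 0.10, applied
independently per channel and time point, is an assumption; it is the
one that reproduces the headline corrected-arm error level.

Reported metrics follow the published conventions: per-parameter mean of
|est − true|/true over replicates, a grand mean over the eight
parameters, and per-parameter OLS regression (with intercept) of
estimates on truths, reporting slope, classical slope standard error and
R².  One master seed derives the truth draws and one noise stream per
(scheme, replicate) via `SeedSequence` spawn keys, so both arms see
identical data, schemes are paired on truths, and the whole study is
bit-reproducible.

Sampling schemes: the two 7-point schedules are fixed (0.25, 2, 4, 8, 24,
48, 72 h and 0, 0.25, 0.5, 2, 12, 24, 48 h).  The denser schedules are
not specified beyond their sizes, so "20"/"50" are uniform on
[0.25, 72] h and "20-early"/"50-early" geometric on [0.05, 48] h with
t = 0 prepended, concentrating points in the first hour where compartment
exchange is fastest.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions: the same forward model as
the fitter (when corrected), organ-level %ID curves, multiplicative
relative noise, and scan schedules.  It does not emulate FMT
reconstruction artifacts, motion, per-animal IDV variation, segmentation
error, or model misspecification of the kinetics themselves — so passing
recovery tests demonstrate identifiability and correctness of the
estimation machinery under the stated noise, not accuracy on real scans.
The uncorrected-arm results additionally depend on the rBV defaults,
which are not measured quantities here; with stronger vascular spillover
or blur the collapse-only model degrades further.

## Numerical choices and edge cases

* Fine grid h = 1 min over 72 h; all named plain-scheme times fall on
  grid nodes, geometric "-early" times are linearly interpolated (the
  adjoint handles interpolation weights exactly).
* RK4 accuracy: vs. the matrix-exponential solution, agreement is tested
  to 1e−6 of the injected dose at the scan times; per-element relative
  agreement is h-dependent and degrades for the largest admissible total
  outflow rates.
* Nonnegativity of trajectories holds for all admissible rates at h ≤ 1
  min (tested to −1e−9).
* Degenerate regressions (zero truth variance) raise; constant estimates
  return slope 0, R² 0.
* Ellipsoid phantom overlap resolves first-label-wins with a logged
  warning; empty rasterizations raise.
* Measurements are validated nonnegative; zero values stay zero under
  multiplicative noise.

## Known limitations

* No uncertainty quantification per fit (no CIs or profile likelihood).
* Retention is strictly irreversible and there is no arterial input
  function, so the model does not transfer to reversible-binding PET
  tracers without extension.
* The four known rates and the rBV vector are assumptions; conclusions
  that depend on them (chiefly the uncorrected-arm failure magnitude)
  inherit that uncertainty.
* The conjugate-gradient engine is the only optimizer family provided.
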
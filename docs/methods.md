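# Methods

`valdcm` implements a complete effective-connectivity analysis for a
four-node emotion-processing network — fusiform face area (FFA), amygdala
(AMY), lateral prefrontal cortex (LPFC) and medial prefrontal cortex (MPFC)
— observed with BOLD fMRI during an alternating face-/shape-matching block
task whose face blocks carry positive, negative or neutral valence.  The
scientific question the machinery answers is *where* emotional valence
changes coupling in the prefrontal–amygdala circuit: on bottom-up
connections (AMY→MPFC, LPFC→MPFC), top-down connections (MPFC→AMY,
MPFC→LPFC), neither, or both.

## Generative model

Neural dynamics follow the bilinear state equation

dz/dt = (A + Σ_j u_j B_j) z + C u

with intrinsic coupling `A` (Hz), modulatory changes `B_j` per contextual
input (positive and negative valence boxcars), and driving gain `C` (the
all-faces boxcar entering the FFA).  Self-connections are parameterised as
−0.5·exp(θ_self), so the resting point is stable for any real θ_self.  The
intrinsic skeleton is fixed across all models: bidirectional MPFC↔AMY,
MPFC↔LPFC and AMY↔LPFC, feed-forward FFA→AMY and FFA→LPFC with feedback
AMY→FFA and LPFC→FFA (ten directed connections plus four self-connections).

Each region's activity drives a Balloon–Windkessel cascade (vasodilatory
signal, inflow, venous volume, deoxyhemoglobin) with defaults κ = 0.64 s⁻¹,
γ = 0.32 s⁻¹, τ = 2.0 s, α = 0.32, E₀ = 0.4, V₀ = 4 %, and the 3-T BOLD
observation y = V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v)) with
k₁ = 4.3·ϑ₀·E₀·TE, k₂ = ε·r₀·E₀·TE, k₃ = 1−ε (ϑ₀ = 40.3 s⁻¹, r₀ = 25 s⁻¹,
ε = 1, TE = 35 ms).  Only τ is subject-estimated (log-scale); the other
hemodynamic constants are fixed — a deliberate parsimony choice recorded in
the inversion configuration so it can be widened.

Integration is fixed-step Heun (explicit trapezoid) on the microtime grid
dt = TR/16 = 0.125 s, jointly over neural and hemodynamic states, sampled at
volume times.  The positive states f, v, q are propagated as logarithms:
this guarantees positivity for any step size and keeps the integrator
well-defined when strong negative neural drive pushes inflow toward zero
(which happens for tail draws of the subject-parameter distribution).  The
second-order stage matters: plain Euler in log space leaves an O(dt)
step-halving discrepancy of ~1e−2 RMS, an order above the 1e−3 the chain is
validated to.  Stimulus onsets are locked to a 125-ms presentation frame
grid (the microtime step), so input boxcars sample identically on every
refinement of that grid and step-halving measures integrator error alone;
measured, halving dt changes predicted BOLD by ~3e−4 RMS.

## Task design

The paradigm is 12 alternating 20-s blocks (6 face — two per valence — and
6 shape), five contiguous 4-s trials per block, acquired at TR = 2 s for
175 volumes (350 s).  Block placement inside the scan is not fully
determined by the block structure; we use a configurable initial fixation
(default 10 s) and split the remaining 100 s into eleven equal inter-block
gaps, so the last block ends exactly at scan end.  Valence-to-block
assignment is a seeded permutation; the alternation starts with a face
block.  Time is 0-based seconds from the first retained volume; intervals
are half-open.

The GLM design matrix carries five task regressors convolved with the
canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6, 32-s
kernel): `all_faces` and `shapes` as condition boxcars and the three valence
regressors as mean-centered parametric modulators (indicator − 1/3 over face
trials).  Centering is essential: plain valence boxcars would sum exactly to
`all_faces`, making the design singular and the faces-versus-shapes contrast
non-estimable.  With centering the design still contains one intentional
sum-to-zero dependency among the three modulators; estimation uses the
pseudoinverse and every contrast is checked for estimability.  Motion
parameters are appended unconvolved.

## Synthetic data

The generator defines the study conditions under which every downstream
stage is validated.  Group-mean coupling is set to the published group
estimates of the bidirectional family (e.g. LPFC→AMY 0.1702, AMY→MPFC
0.1122, MPFC→AMY modulation by negative valence −0.2732); the driving gain
is 0.3 Hz (a typical DCM driving magnitude; no published value exists).
Subjects are drawn per parameter class with SDs A 0.03, B 0.06, C 0.03,
θ_self 0.05, log-τ 0.05; draws whose dynamics are not integrable
(non-physiological tail combinations) are rejected and redrawn, so the
subject population is the stable region of the parameter distribution.
The generating model is the fully modulated bidirectional member.

Observation noise is white Gaussian per region with SD = signal SD / SNR.
The default SNR is **8**, calibrated — as the package's own calibration of
an otherwise unconstrained noise level — to the end-to-end recovery
properties: in this coupling regime top-down modulation effects on BOLD are
second-order small (they ride on MPFC activity, itself a product of
≈0.1-magnitude couplings), family-level selection at n = 12 needs roughly
SNR ≥ 3 to identify bidirectional modulation, and recovery of the two
MPFC-source intrinsic couplings (the least identifiable parameters, for the
same reason) needs more.  An SNR of 8 for the region *summary* series is
the eigenvariate regime — averaging on the order of a hundred voxels of a
strong block design multiplies voxel-level SNR several-fold — and gives a
reliable margin for family recovery and group-mean parameter recovery
(correlation with truth r > 0.8).  Because noise scales per region, the
overall input gain cancels out of detectability; the SNR is the one
effective dial.  A residual caveat: with only two neutral face blocks per
run, the unmodulated coupling of the MPFC-source connections is identified
from ~40 s of weak activity, and for unfavourable valence orderings their
estimates stay partially confounded with the modulations at any SNR.

VOI voxel data place each region's clean signal on a 2-mm grid inside a
6-mm sphere (123 voxels) with radially decaying gain exp(−‖offset‖²/(2·3²))
plus voxel-level noise at the region's noise SD.  Head motion is a seeded
random walk (translation step 0.04 mm, rotation step 4e−4 rad per volume),
giving mean framewise displacement ≈ 0.14 mm — the compliant-adult regime.
Behavior draws per-trial correctness from per-condition accuracies
(0.966/0.949/0.810/0.935), RT from truncated normals on (0.1 s, 4 s], and an
independent 3.9 % unusable-trial process (no response, or RT < 100 ms).

What the generator does **not** emulate: serially correlated (AR) noise,
scanner drift, physiological confounds, hemodynamic variability beyond τ,
spatially correlated voxel noise, or response-time dependence on trial
difficulty within a condition.  Passing tests therefore demonstrate
correctness of the analysis chain under white-noise, drift-free conditions,
not robustness to every artifact of real fMRI.

## VOI extraction

Per voxel, the faces>shapes t-contrast is computed from the GLM; the
subject peak is the largest-|t| voxel within 12 mm of the group peak, and
the VOI is all voxels within 6 mm of that peak with uncorrected p < 0.05.
The threshold is two-sided: with the published coupling signs, AMY, LPFC
and MPFC express the task as deactivations, and a positive-only criterion
would exclude every subject.  The region summary is the first eigenvariate
— the first left singular vector of the time-centered voxel matrix, scaled
by σ₁/√V and sign-aligned to the VOI mean series.  A subject with no
suprathreshold voxel raises an exclusion signal carrying subject and region.
Motion screening flags subjects whose mean framewise displacement (rotations
converted at 50 mm radius) exceeds 0.5 mm.

## Model inversion

Each model is inverted by variational Laplace under Gaussian assumptions.
Free parameters: off-diagonal A on present connections, B on switched
modulations, the single C entry, θ_self per region, log-τ per region.
Priors are zero-mean shrinkage with variances A 1/16, B 1/4, C 1,
θ_self 1/64, log-τ 1/64; per-region noise log-precision has prior
Normal(4, 1).  Data and predictions are mean-centered per region, making the
likelihood invariant to the arbitrary BOLD baseline.

The free energy is F = accuracy − complexity with Gaussian likelihood and
KL-to-prior complexity over both parameters and noise hyperparameters; the
posterior covariance comes from the Gauss–Newton curvature (Cholesky, with
ridge repair on indefiniteness).  The optimiser alternates an exact
bisection update of each noise log-precision (the per-region gradient is
strictly decreasing, so the root is bracketed and unique) with a
Gauss–Newton step whose sensitivity matrix is computed by central finite
differences (h = 1e−4) of the integrator.  Every candidate — including the
hyperparameter update — is evaluated on the full free energy and accepted
only if F increases; rejected steps are halved up to 8 times.  The accepted
F-trace is therefore non-decreasing by construction.  Convergence is a
full-iteration gain below 0.01 nats or 64 iterations; non-convergence is
reported in the result, not raised.  Typical fits converge in 7–15
iterations (~1 s on one core with the compiled integrator).

Only free-energy differences between models fitted to the same data are
interpreted; absolute values depend on scaling and priors.

## Model space and comparison

Valence modulation is switched independently on the four prefrontal–
amygdala connections for each of the two valences: 8 binary switches,
2⁸ = 256 models, the switch pattern being the model id.  Families:
`none` (1), `bottom_up` (15), `top_down` (15), `bidirectional` (225).
A note on the intrinsic skeleton: varying LPFC↔AMY intrinsic patterns as
well would inflate the space fourfold, which is arithmetically incompatible
with the 256-model census and with both AMY↔LPFC endogenous parameters
being reported; all models therefore share the full bidirectional skeleton
and only modulations vary.

Random-effects BMS treats model identity as a random effect: variational
updates of a Dirichlet over model frequencies from per-subject evidences,
expected probabilities α/Σα, exceedance probabilities by seeded Monte-Carlo
Dirichlet sampling (1e5 draws; MC standard error reported).  Family
comparison first collapses each subject's evidence to
logsumexp(members) − log(size), the uniform-over-families prior that removes
the 225-vs-1 size advantage, then runs the same Dirichlet machinery over the
four families.

BMA averages each subject's posterior means over the models of the winning
family, weighted by that subject's posterior model probabilities restricted
to the family and renormalised; a parameter absent from a member model
contributes zero.  Averaging is winning-family-only (not an Occam window
across all models) — the alternative would mix structures the family-level
inference has just rejected.

Desk-scale sub-spaces preserve the family partition: `per_connection_16`
ties both valences per connection subset (census 1/3/3/9);
`families_4_representatives` keeps one fully-switched member per family.

## Group statistics

BMA parameters are tested per connection with two-sided one-sample t tests
across subjects; the FDR family is all coupling parameters jointly
(Benjamini–Hochberg step-up, q = 0.05, adjusted p = min_{k≥j} m·p₍ₖ₎/k).
Zero-variance columns are flagged degenerate and excluded from the FDR
family rather than given fabricated p-values.  Behavior: trials without a
response or with RT < 100 ms are discarded; condition effects use a one-way
repeated-measures ANOVA (F = MS_condition / MS_condition×subject, no
sphericity correction — a known limitation); face-vs-shape performance uses
paired t tests (identical vectors → t = 0, p = 1; a zero-variance nonzero
difference → ±∞, p = 0, by convention); brain–behavior relations use
Pearson correlations FDR-corrected over the full parameter × measure grid.

## Pipeline

`run_pipeline` chains simulate → extract → invert → compare → average →
stats under one JSON config with a single master seed; per-subject seeds are
spawned from it and recorded in the manifest, so identical configs yield
byte-identical outputs.  A completed run with an unchanged config hash is
skipped on re-run.  Stage failures abort with the stage name and the
offending subject/model id.  Subject × model inversions are independent;
results are reduced in sorted model-id order so any execution order yields
identical outputs.

## Problem sizes used in validation

The validation studies use 12 subjects with the 16-model tied-valence
sub-space for family and parameter recovery (192 inversions), 10 seeded
replicates of 4 subjects × 4 family representatives for modulation-sign
recovery, and 20 noise-only replicate subjects for single-connection
recovery — sizes chosen to exercise the full chain at desk scale while
keeping each study in the minutes range.  Statistical calibration
(type-I rates, FDR) uses 400–1000 null replicates.

## Known limitations

- White-noise observation model; no AR(1) or drift terms in generator or
  likelihood.
- Finite-difference sensitivities cost 2P integrations per iteration;
  adjoint or automatic differentiation would be faster for larger networks.
- Variational Laplace finds local optima; with strong noise the posterior
  honestly shrinks toward the prior, and group-level estimates inherit that
  conservatism.
- Family inference at realistic noise levels is limited by the physics of
  the regime: modulations on connections out of weakly active regions carry
  little evidence, whatever the estimator.
- The eigenvariate rescales each region's amplitude by the VOI gain
  profile; coupling estimates after extraction are correspondingly
  conservative relative to fitting the latent region series.
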
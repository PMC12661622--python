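# Methods

This note documents the models, calibrations and numerical choices behind
`dtialps`, in the order data flows through the pipeline.

## Signal model and tensor fit

Diffusion-weighted signal follows the monoexponential tensor model
`S = S0 · exp(−b · gᵀ D g)` with `D` the symmetric 3×3 diffusion tensor in
mm²/s. The fit is ordinary least squares on the log-attenuation
`log(S0/S)` against design rows
`(b gx², b gy², b gz², 2b gx gy, 2b gx gz, 2b gy gz)`, solved per voxel by
a single pseudoinverse shared across the volume. Choices:

* **OLS, not WLS/RESTORE.** The estimator is deliberately the minimal
  defensible one; it is exact on noise-free data (the test suite requires
  recovery to 1e-9 mm²/s) and the code path is pluggable if a weighted
  variant is ever needed.
* **S0** is the mean of the b=0 volumes per voxel. Signals ≤ 0 are clamped
  to `1e-6 · S0` before the log. Voxels with zero S0 are masked out rather
  than failing the volume.
* **Negative fitted diagonals** are clamped to 0 and counted; the count is
  exposed on every result (`n_clamped`) so QC can see it.
* "Diffusivity along an axis" means the corresponding diagonal element
  (Dxx, Dyy, Dzz), matching the ALPS formula's symbols directly — not an
  eigen-decomposition projection.

## ROI geometry and the index

ROI centers are 0-based voxel indices on the 1-mm JHU-ICBM template
(182×218×182): superior corona radiata (projection) left (116,110,99) /
right (64,110,99) and superior longitudinal fasciculus (association) left
(128,110,99) / right (51,110,99). Reports of the SLF-left center vary by
one voxel in the literature (128 vs 129); 128 is the default and every
center is configurable. The package equates template voxel indices with
world mm (identity affine) and expresses all synthetic grids in that frame,
so printed coordinates apply verbatim; registration of real data to the
template is explicitly out of scope.

"5 mm spheres" is read as 5-mm **diameter** (radius 2.5 mm, configurable),
consistent with the common automated-ALPS convention. A voxel belongs to a
sphere iff its center lies within the radius (distances in mm via voxel
sizes); on a 1-mm grid the 2.5-mm sphere holds 81 voxels (brute-force
lattice count). ROI means are taken over all sphere voxels — no FA or
tissue-mask restriction is applied by default, since the analysis this
models states none.

Per hemisphere, `ALPS = ((Dxx_proj + Dxx_assoc)/2) / ((Dyy_proj +
Dzz_assoc)/2)`; the bilateral index is the mean of the two hemispheres. A
non-positive denominator raises an error naming the subject rather than
propagating NaN. The index is invariant to a global rescaling of the
tensor field (ratio of means), which the property tests enforce.

## Phantoms

`simulate_tensor_field` embeds axis-aligned diagonal tensors: background
voxels are isotropic at 0.8e-3 mm²/s; projection spheres carry
diag(Dxx_proj, Dyy_proj, background) and association spheres
diag(Dxx_assoc, background, Dzz_assoc), so the analytic ALPS of the truth
is exactly the formula applied to the embedded values. `truth_for_alps`
inverts the formula (fiber-axis diffusivities fixed at 0.8e-3/0.7e-3, the
perivascular axis scaled) so a phantom can embed any prescribed index.

`simulate_dwi` adds Rician noise as the magnitude of a complex Gaussian
perturbation with `sigma = S0/snr` (default SNR 30, the plausible b=1000
regime), or plain Gaussian, or none; everything is deterministic given the
seed. The default gradient scheme is 6 b=0 volumes plus 30 directions at
b=1000 s/mm² from a frozen electrostatic-repulsion table (design condition
number 1.59) — a miniature of a multi-shell acquisition that keeps the
tensor identifiable at minimal cost; low-b shells of real acquisitions are
simply additional rows in the same design.

Two grids are used. The default phantom grid is a cropped 2-mm template
(96×110×96) covering the full atlas extent. For simulation batteries the
`minimal_roi_grid` (≈45×7×7 at 2 mm) brackets just the four spheres plus a
3-mm margin: since the index only reads the spheres, results are identical
up to noise realization, and a 126-subject cohort runs in under a second.
The multi-seed recovery studies and the reproduction script use this grid;
that is a scaling choice of this package, stated here once.

## Cohort generator

The generator draws the study conditions it is asked to reproduce:

* **Groups**: 28 HC / 67 PD-good / 31 PD-poor; bilateral baseline ALPS
  ~ Normal(1.18, 0.20), (1.19, 0.16), (1.08, 0.16) respectively; ALPS
  floored at 0.01. Ages ~ Normal(65.7±9.1 / 62.4±7.0 / 68.5±8.5), clipped
  to [35, 95]; sex composition fixed at the demographic counts (15/13,
  38/29, 8/23 F/M).
* **Left–right coupling**: left/right are built from the bilateral latent
  plus a symmetric difference term, with within-group Pearson coupling
  ρ_w. Because the three group means differ, pooling the groups adds
  shared variance that raises the whole-cohort correlation above ρ_w, so
  ρ_w is solved numerically: the population grade correlation of the
  three-component mixture is computed by Gauss–Hermite integration
  (`12·E[F(L)F(R)] − 3` with F the mixture CDF), corrected to the expected
  *sample* Spearman at n = 126 via the standard
  `((n−2)ρ_S + (6/π)·asin ρ_P)/(n+1)` relation, and inverted by Brent's
  method so the expected sample Spearman equals the target (default
  0.819). An 8000-seed check puts the realized mean at 0.8195.
* **Longitudinal structure**: sessions are coded 0, 1(, 2) (18 months
  apart, `time_from_baseline` in years); all groups share a base slope of
  0 per session and the poor group additionally declines by
  `group_time_beta` (default −0.057) per session; repeat sessions add
  N(0, 0.05) measurement noise to the bilateral latent. The mixed model is
  therefore estimating exactly the coefficient the generator embeds.
* **Cognition**: the composite score is linear in the *baseline* ALPS
  residual after age and sex (residualized within the PD pool, and
  separately within HC), plus age and sex nuisance terms (−0.02 z/yr,
  +0.1 z for M, SD 0.7) and independent Gaussian noise. The coupling
  coefficient is the grade-relation map `2·sin(π·ρ_s/6)` of the target
  partial Spearman — 0.226 at baseline, 0.25 at session 3, midpoint at
  session 2 (no value is stated for session 2; chosen once). Because
  sampling orthogonalizes the residual against age/sex exactly, the
  expected sample partial correlation matches the target to O(1/n).
* **Raw battery scores**: the six composite components (MoCA, inverted
  Stroop colour-naming time, category/letter fluency, recognition memory,
  Hooper) are emitted on plausible raw scales with per-subject-centered
  component scatter, so re-scoring the battery reproduces the generated
  composite exactly and the scoring module is exercised end to end. The
  control-baseline reference statistics shipped as defaults are synthetic
  plausible values.

What the generator does **not** emulate: independent group offsets in
cognition (group gaps arise only through the groups' ALPS differences, so
the large cognition deficit of a real poor-outcome group is understated);
dropout and per-analysis missingness (all subjects complete all sessions —
statistical operations are complete-case and handle missingness, but the
default cohorts contain none); event-level outcomes (death/frailty/dementia
flags are classification inputs, not simulated processes); spatial
heterogeneity inside ROIs; and any physiological link between age and
ALPS within group. Passing recovery tests therefore show the estimators
are calibrated to the generative model, not that the model captures real
cohort biology.

## Statistics

* **Group comparison**: Shapiro–Wilk per group at α = 0.05, all-pass
  policy (overridable) gates one-way ANOVA with Tukey HSD against
  Kruskal–Wallis with Dunn's test (rank-sum z with tie correction,
  Holm-adjusted); both branches are computable on demand. The type-I error
  of the gated procedure is checked by a 1000-simulation null study
  (acceptance band 0.035–0.065 at nominal 0.05). Dunn's test is
  implemented in-package (no installed library ships it); with two groups
  its z² reproduces the Kruskal–Wallis H exactly, which serves as an
  identity check.
* **Partial Spearman**: rank-transform everything (average ranks on
  ties), residualize ranked x and y on the ranked covariates by least
  squares, Pearson-correlate the residuals; p from t with n−2−k df. With
  zero covariates this is textbook Spearman to 1e-12; against pingouin's
  `partial_corr(method="spearman")` it agrees to 1e-10.
* **Group × time model**: `outcome ~ group * time + age + sex` with a
  per-subject random intercept, REML (statsmodels MixedLM). A mixed model
  is used rather than classical repeated-measures ANOVA because it yields
  the interaction coefficient directly and tolerates missing sessions; a
  split-plot RM-ANOVA on balanced complete cases is provided as a
  cross-check (`rm_anova_crosscheck`). The reported β is the
  poor-group × time term with HC as reference.
* **Mediation**: linear product-of-coefficients — a from `m ~ x + cov`,
  b and c′ from `y ~ x + m + cov`, c from `y ~ x + cov`; indirect = a·b;
  c = c′ + a·b holds exactly on point estimates and is asserted to 1e-12.
  CIs are percentile bootstrap (default 5000 case resamples, seeded; BCa
  deliberately not used — the seed is part of the interface). Point
  estimates agree with pingouin's `mediation_analysis` to 1e-10. The
  exposure/mediator/outcome roles are fully generic; the CLI default codes
  a non-numeric group column as the poor-outcome indicator.
* **Multiple testing**: post-hoc tables are familywise-controlled (Tukey
  natively, Dunn via Holm); correlation analyses are reported unadjusted.

All stochastic procedures take explicit seeds and are bit-reproducible
given (data, seed). Multi-seed studies derive child seeds from one base
seed through `numpy.random.SeedSequence` with distinct stream keys per
quantity.

## Recovery studies and problem sizes

`dtialps.recovery` re-estimates every embedded quantity by repeated
simulation: 200 cohort seeds for the correlation structure and the
interaction (statistics-only), 200 seeds × 126 subjects through the full
imaging chain on the minimal ROI grid for the group means, and 1000 null
simulations for the comparison's type-I error. Monte-Carlo standard errors
come from the seed-level distributions. The acceptance test for the
imaging-chain group means uses a single cohort against the per-group
2·SD/√n band; the reproduction script averages 200 seeds. These sizes are
the package's defaults and are all adjustable parameters.

## Known limitations

* No registration, DICOM ingestion, or BIDS handling: inputs are assumed
  already on the template grid.
* The OLS tensor fit is unweighted; at very low SNR the Rician floor
  biases diffusivities (visible in the monotone SNR-error tests).
* The MCI rule's "persistent" criterion is operationalized as met at two
  consecutive assessed sessions (policy parameter `consecutive`), one of
  several defensible readings.
* The generator's simplifications listed above bound what green tests
  imply about real cohorts.
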
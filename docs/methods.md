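# Methods

This note documents the models behind `ventricsf`: what the synthetic data
emulate, the conventions fixed by each analysis step, the numerical choices,
and what passing tests do and do not establish about real data.

## The scientific setting

The cerebrospinal-fluid (CSF) system — choroid plexus (production), the
ventricular network (circulation), and reabsorption/clearance pathways — is
increasingly implicated in early amyloid pathology: enlarged ventricles and
choroid plexus, and reduced non-specific PET tracer signal in the ventricular
CSF (a proxy for CSF turnover), co-occur with higher cortical amyloid.  The
package implements the full analysis chain used to study these relationships:
image-derived biomarker extraction, biomarker staging, cohort statistics,
voxel-wise mapping, and sequential mediation — exercised on synthetic
phantoms because cohorts of this kind are not publicly distributable.

## Synthetic cohort model

Participants are drawn in five biomarker stages — CU(Y) (young cognitively
unimpaired reference), A−T−, A+T−, A−T+, A+T+ — with default group sizes
52/166/64/4/92 (378 total).  Five latent variables follow a linear-Gaussian
structural-equation model in the causal order CPV → VR → VV → ABETA → TAU:

```
CPV   = shift_CPV(stage)                                  + 1.00 ε
VR    = −0.54 CPV                                         + 0.70 ε
VV    =  0.38 CPV − 0.84 VR + shift_VV(stage)             + 0.44 ε
ABETA =  0.15 CPV + 0.45 VV + shift_AB(stage)             + 0.80 ε
TAU   =  0.01 VV  + 0.55 ABETA                            + 0.70 ε
```

Stage effects are additive location shifts (no interactions), the simplest
structure consistent with monotone group-mean orderings.  Noise is Gaussian
throughout; no distributional claims beyond that are intended.

**Calibration.**  The CPV/VR/VV coefficients and noise scales were fixed
once, by large-sample simulation, so that the pooled cohort's Spearman
correlations match the configured targets ρ(CPV,VV) = 0.74,
ρ(VV,VR) = −0.71, ρ(CPV,VR) = −0.62 (stored in
`SemSpec.spearman_targets`), and so that the ICV-residualized VV Z-score
versus CU(Y) rises to roughly 4 in the A+T+ group.  At n = 378 the sampling
standard error of these correlations is ≈ 0.02–0.03.

**Tau has no direct stage shifts.**  Tau's stage dependence is transmitted
entirely through ABETA plus a deliberately small residual VV→TAU edge
(0.01).  This keeps the generative model faithful to the
amyloid-mediates-tau structure that the mediation analyses probe: a direct
tau shift per stage would act as an unmediated confounder and manufacture a
spurious conditional VV→tau effect.  Two consequences are accepted and
documented: the small amyloid-discordant A−T+ group (n = 4) is not
tau-elevated in the synthetic cohort, and generated tau SUVRs in the A+T−
group sit above the 1.18 positivity cutoff (tau tracks amyloid linearly
here, unlike real cohorts where tau positivity lags amyloid).  The
literature-scale group-mean SUVRs used for the A/T self-consistency check are
stored as constants (`REFERENCE_STAGE_SUVR_MEANS`), independent of the
generator.

**Physical units.**  Latent values map affinely to physical units, with a
weak ICV coupling for the volumes (so ICV residualization has something to
remove): CPV 1400 ± 330 mm³, VV 17 000 ± 5200 mm³, VR 0.62 ± 0.11 SUVR,
ABETA 1.25 ± 0.28 SUVR, TAU 0.85 ± 0.45 SUVR, then clipped to plausible
ranges.  Per-group volume means in physical units are not published for this
kind of cohort; these scales are synthetic choices of plausible adult
values, not literature-derived.  Covariates: age/sex/APOE4 frequencies per
stage follow typical staging-cohort demographics; ICV is Gaussian by sex
(1.50/1.40 × 10⁶ mm³, SD 1.1 × 10⁵).  Covariates are generatively inert
(they influence no latent node beyond the ICV–volume coupling); they are
nevertheless always included in the statistical models, matching the
analysis convention.

## Phantom geometry

Default grid 96³ voxels at isotropic 2 mm, phantoms generated pre-aligned
(registration is out of scope).  The head is an ellipsoid sized analytically
to the participant's ICV (axis ratios 0.80 : 1.00 : 0.82), with a 1-voxel
meningeal rim inside the boundary and a 1-voxel subarachnoid CSF layer
beneath it.  The cortical ribbon (two voxel layers) is partitioned into a
neocortical-composite sector and an inferolateral temporal meta-ROI sector,
with one further generic grey-matter layer beneath; an inferior-posterior
ellipsoid is the cerebellar grey matter (the PET reference region — a single
cerebellar label stands in for both the full-cerebellum amyloid reference
and the inferior-cerebellum tau reference).  Sector labels stand in for the
anatomical members of the published composites; the mapping is a modelling
convention, not a parcellation.

Each lateral ventricle is a posterior body fused with an anterior frontal
horn; a shared shape scale is found by bisection (40 iterations, 1.5%
tolerance) so the summed cavity volume matches VV + CPV, and choroid-plexus
ellipsoids inside each cavity are scaled the same way to CPV.  Ventricle
labels are the cavity minus the plexus, so extracted VV excludes the plexus,
matching segmentation practice.  Voxel quantization bounds the round-trip
error: ≤ 5% for VV, ≤ 10% for CPV (small blobs).  The horns' lateral reach
grows sublinearly with the shape scale, placing the cohort's Evans' Index
mostly in 0.21–0.31 so that the EI > 0.3 exclusion fires only for extreme
ventriculomegaly, a few percent of participants.

PET volumes are piecewise-constant tissue means plus Gaussian noise
(SD 0.05 SUVR): cortical sectors carry the participant's composite SUVRs,
ventricular CSF carries the VR SUVRs, the choroid plexus carries elevated
off-target signal (1.8/1.9), the meninges carry high signal (1.9/1.5, which
the meninges mask must remove before smoothing), and the cerebellum is the
unit reference.  Subarachnoid CSF is held at a population-mean level rather
than the participant's VR: the participant-specific CSF signal of interest
is ventricular, and coupling the subarachnoid layer to it would leak a
positive cortical association through smoothing spill-over.  What the
phantoms do **not** model: cortical folding, partial-volume physics beyond
mask erosion, scanner noise spectra, registration error.  Passing round-trip
tests therefore shows the pipeline's bookkeeping and estimators are correct,
not that the pipeline is robust to real segmentation or registration error.

## Extraction conventions

* **Evans' Index** — frontal-horn width is the maximal left–right extent of
  ventricle voxels on any axial slice, restricted to the anterior third of
  the ventricles' own anterior–posterior extent (not the skull's); the
  internal skull diameter is the global maximal left–right head extent
  (`skull_convention="same_slice"` measures it on the horn's slice instead).
  Width is voxel-quantized ((max − min + 1) × voxel size); sub-voxel
  interpolation is not attempted.  Exclusion is strict: EI > 0.3.
* **Pipeline order** — meninges masking, then smoothing to 8 mm FWHM, then
  SUVR; masking first prevents meningeal spill-in.  VR is computed on the
  smoothed images by default (`vr_before_smoothing=True` for the
  alternative, since acquisition pipelines differ on this point).
* **VR mask** — (ventricles) minus (choroid plexus), then binary erosion by
  a Euclidean ball of radius round(erosion_mm / min voxel size) voxels
  (default 2 mm → 1 voxel).  Erosion that empties the mask raises an error
  carrying the pre-erosion mask as a diagnostic.
* **A/T staging** — strict inequalities (amyloid > 1.55, tau > 1.18); values
  at the cutoff classify negative.

## Statistics

* Z-scores use the CU(Y) mean/SD after ICV residualization; residualization
  is fit on all included participants (the fitting sample is not specified
  in the conventions this follows, so the most inclusive choice is used).
* Group comparisons: one-way ANOVA, Tukey HSD pairwise p-values from the
  studentized-range distribution, then Benjamini–Hochberg across the
  pairwise family (an unusual combination — both raw Tukey and BH-adjusted
  values are reported).  The FDR family is per outcome by default.  Groups
  with n < 2 are dropped with a warning; the n = 4 A−T+ group is kept but
  flagged as fragile.
* Standardized OLS: continuous variables scaled to SD 1; binary covariates
  (sex, APOE4) centred only, so their coefficients are per-category rather
  than per-SD.  Covariate profiles COV¹ (age, sex, APOE4), COV² (+ICV),
  COV³ (+grey-matter volume) mirror the analysis conventions; analyses can
  be run with or without the CU(Y) group.

## Voxel-wise GLM and random field theory

Per-voxel OLS with a contrast t-statistic; voxels with zero residual
variance get t = 0 (flagged) when the effect is also zero and a documented
cap (10⁶) otherwise.  Smoothness is estimated from the variance of spatial
forward differences of unit-normalized residual images
(FWHM = √(4 ln 2 / λ) per axis) — estimated from residuals rather than
assumed from the nominal kernel, with an override to supply the nominal
value.  The corrected threshold solves expected-Euler-characteristic
= α (α/2 per tail for the default two-sided test) using t-field EC densities
for dimensions 0–3; resel counts use the mask volume (R₃), exposed-face
surface area (R₂) and bounding-box extents (R₁), which is exact for boxes
and a standard approximation otherwise.  The α = 0.001 default follows the
convention for these maps; a voxel-wise Benjamini–Hochberg mode is provided
as the alternative multiple-comparison treatment, since published analyses
of this kind describe both.  Cluster-extent and permutation inference are
out of scope.  Monte-Carlo calibration on simulated null smooth fields
(32³ voxels, 8 mm FWHM, 200 simulations, 30 subjects each — sizes chosen to
make the calibration exhaustive at desk scale) gives a family-wise error of
≈ 0.03 at nominal 0.05: slightly conservative, as expected for RFT at
4-voxel FWHM.

## Mediation

Sequential path models are ordered standardized regressions: each node on
its declared parents plus covariates (age, sex, APOE4, ICV).  Indirect
effects are products of edge coefficients along every directed path of
length ≥ 2 to the terminal outcome.  Inference is Efron's bias-corrected
(BC) percentile bootstrap — no acceleration term, since only bias
correction is specified for this analysis family — resampling whole
participant rows (10 000 iterations by default; simulations in the test
suite use 500 for speed, which leaves CI endpoints accurate to ~0.01).
Resamples yielding rank-deficient designs are redrawn (logged; > 5%
triggers a warning).  Missing data are handled by complete-case analysis.
Two literature-standard topologies ship as presets: `vv_mediates_amyloid`
(CPV, VR → VV → Aβ) and `abeta_mediates_tau` (the full chain to tau); the
two differ in the direction drawn between VR and VV in their sources, and
both are preserved rather than adjudicated.

**Known limitation.**  When one path coefficient is large and the tested
path is truly null (e.g. a = 0.5, b = 0 at n = 300), BC (and plain
percentile) bootstrap intervals for the product over-reject: measured
coverage of zero is ≈ 0.87–0.89 rather than 0.95, consistent with published
simulation studies of bootstrap mediation tests.  This is a property of the
method itself, not of this implementation — the bootstrap SD matches both
the theoretical and the empirical sampling SD of the estimator, and the
bias-correction term is centred at zero under the null.

## Reproducibility

All randomness flows from explicit seeds; the pipeline expands a master
seed into independent per-stage seeds via `numpy.random.SeedSequence`
spawning, and every output table is regenerable from the manifest's
recorded configuration.  Identical spec + seed ⇒ byte-identical cohort
tables and voxel-identical phantoms.
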
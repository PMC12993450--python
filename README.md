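# ventricsf

CSF-system imaging biomarkers on synthetic brain phantoms: tools for studying
how **ventricular enlargement**, **choroid plexus volume (CPV)** and
**ventricular PET radioactivity (VR)** relate to cortical amyloid (Aβ) and
tau load across biomarker-defined disease stages.

## Who this is for

Neuroimaging methodologists who want a fully synthetic, end-to-end testbed
for CSF-clearance analyses: real cohorts of this kind (T1 MRI + amyloid-PET +
tau-PET) are rarely public, so every analysis step here runs against
generated data with known ground truth.

## What it computes

* **Volumetrics** — lateral-ventricle volume (VV), CPV, intracranial volume
  (ICV), grey-matter volume, ICV residualization, and the **Evans' Index**
  (maximal frontal-horn width in the anterior third of the ventricles over
  the internal skull diameter), with the conventional EI > 0.3 exclusion
  filter for disproportionate ventriculomegaly.
* **PET quantification** — meninges masking, Gaussian smoothing to a target
  FWHM (default 8 mm), composite SUVRs (neocortical composite for amyloid,
  temporal meta-ROI for tau, cerebellar grey-matter references), the
  **ventricular-radioactivity SUVR** (ventricles minus choroid plexus,
  eroded ~2 mm), and A/T staging (amyloid SUVR > 1.55, tau SUVR > 1.18).
* **Cohort statistics** — Z-scores against the young cognitively unimpaired
  CU(Y) reference, one-way ANOVA with Tukey HSD and Benjamini–Hochberg FDR,
  Spearman correlations, standardized multivariable OLS.
* **Voxel-wise GLM** — mass-univariate regression of PET volumes on
  ventricular parameters with covariates; smoothness (FWHM) estimated from
  normalized residuals; **random-field-theory** corrected thresholds via
  expected Euler characteristic of the t-field (voxel-wise FDR available as
  an alternative mode).
* **Sequential mediation** — ordered standardized path models over the DAG
  CPV → VR → VV → Aβ → tau; indirect effects as path products with
  **bias-corrected bootstrap** confidence intervals.
* **Synthetic data** — a linear-Gaussian structural-equation cohort
  generator (378 participants in groups 52/166/64/4/92 by default,
  calibrated so that Spearman ρ(CPV,VV) ≈ 0.74, ρ(VV,VR) ≈ −0.71,
  ρ(CPV,VR) ≈ −0.62) and a per-participant 3D phantom renderer whose
  extractable volumes and SUVRs match the table's latent values.

## Worked example

```python
import warnings
from ventricsf.pipeline import demo_config, run_pipeline

config = demo_config(out_dir="demo_run", master_seed=3)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    manifest = run_pipeline(config)
print(manifest.n_simulated, manifest.n_excluded, manifest.n_retained)
```

prints

```
62 5 57
```

i.e. 62 simulated participants, 5 excluded for a measured Evans' Index above
0.3, 57 retained.  `demo_run/` then contains the cohort table, the
per-participant biomarker CSV (volumes, EI, composite SUVRs, VR), the
exclusion report, the A/T staging table, group statistics (ANOVA + Tukey +
FDR and stage-wise Z-scores) and the mediation JSON.  The same pipeline is
available from the shell:

```bash
ventricsf run-all --seed 3 --out-dir demo_run
ventricsf simulate-cohort --seed 1 --out cohort.csv
ventricsf mediate --cohort cohort.csv --preset vv_mediates_amyloid --out med.json
```

On the default full cohort the headline pattern reproduces: each ventricular
parameter alone predicts neocortical amyloid; with all three in one model the
ventricular volume dominates; and the VV→tau association disappears once
amyloid enters the model (amyloid mediates the tau effects).

## Layout

| module | contents |
| --- | --- |
| `ventricsf.cohort` | structural-equation cohort generator |
| `ventricsf.phantom` | 3D phantom renderer |
| `ventricsf.volumetrics` | volumes, ICV residualization, Evans' Index |
| `ventricsf.petquant` | SUVR, VR mask, smoothing, A/T staging |
| `ventricsf.stats` | Z-scores, ANOVA/Tukey/FDR, Spearman, standardized OLS |
| `ventricsf.voxelglm` | voxel-wise GLM, FWHM estimation, RFT thresholds |
| `ventricsf.mediation` | path models and bias-corrected bootstrap |
| `ventricsf.pipeline`, `ventricsf.cli` | orchestration and CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
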
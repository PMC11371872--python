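# mtlpath

Quantitative medial-temporal-lobe (MTL) histopathology and its association
with antemortem MRI morphometry.

`mtlpath` is for neuroimaging and digital-pathology researchers who relate
postmortem burden of p-tau and pTDP-43 inclusions to structural MRI in aging
and Alzheimer's-continuum cohorts. It implements the full analysis chain
downstream of a trained patch classifier:

* **Heatmap quantification** — an attention map over an annotated sampling
  box is partitioned into contiguous ~200 × 200 µm segments of equal area,
  averaged per segment, and summarized by a quantile across segments (the
  99th percentile by default, selected for its agreement with expert
  ratings).
* **Subject summaries** — ROI measures pooled across boxes; a hippocampal
  summary averaged over seven subfields with explicit missingness rules
  (≥ 3 regions, the two dentate subregions counting once, threads excluded
  from the dentate hilus), linearly recalibrated to the ordinal 0–3 rating
  scale.
* **Validation** — Mann–Whitney AUC between adjacent expert-rating
  categories, AUC across Braak / LATE-NC stages, Spearman correlations, and
  the summary-statistic selection experiment.
* **Association models** — per-region OLS of volume (AH, PH) or median
  thickness (ERC, BA35, BA36, PHC) on pathology with standardized β,
  one-sided tests for negative associations, nuisance covariates (age, sex,
  field strength, antemortem interval; ICV for volumes), Bonferroni
  flagging at 0.05/6, and quantitative-vs-semi-quantitative model
  comparison by ΔR²adj, L1 prediction error, ΔAICc and ΔBIC (evidence at
  |ΔBIC| > 2/6/10).
* **Surface inference** — vertex-wise GLM on a template mesh, clusters at
  |t| > 2.0, and familywise correction by Freedman–Lane permutation of the
  maximum cluster surface area.
* **Synthetic data** — generators for heatmaps, ratings, cohorts and
  surfaces with known ground truth, so the whole pipeline is testable
  without any imaging or histology data.

The statistical core follows a statsmodels-like design: a model object is
built from data and `fit()` returns a results object with estimates,
uncertainties, diagnostics and a `summary()` table.

## Worked example

```python
from mtlpath.simulate import generate_cohort
from mtlpath import RegionAssociationModel

cohort = generate_cohort(140, seed=7)   # planted reference effects
fit = RegionAssociationModel(
    cohort, "ERC", ["tangles_q", "threads_q", "mtl_ptdp_rating"]).fit()
print(fit.summary())
```

```
Region model: ERC (n=140, df_resid=132)
adj R2 = 0.242   AICc = -27.67   BIC = -2.58
predictor                  beta        t  p(1-sided)
const                     0.083     0.56       0.713
tangles_q                -0.317    -3.27    0.000691 *
threads_q                -0.192    -1.97      0.0255 *
mtl_ptdp_rating          -0.235    -3.15    0.000996 *
age_at_death             -0.143    -1.89      0.0304
sex                      -0.107    -0.71       0.239
field_strength           -0.043    -0.28       0.389
antemortem_interval      -0.031    -0.41       0.343
* pathology contrast (one-sided negative test)
```

Entorhinal thickness falls by 0.32 standard deviations per standard
deviation of the quantitative tangles measure after covariate adjustment
(one-sided p = 6.9 × 10⁻⁴, below the six-region Bonferroni threshold of
8.33 × 10⁻³); the residual degrees of freedom are 132 = 140 − 8 model
parameters. The cohort generator planted β = −0.30…−0.47 tangles gradients,
which the fit recovers within sampling error.

Surface inference on a synthetic template with a planted thickness-deficit
disc:

```python
from mtlpath.simulate import MeshSpec, generate_surface_dataset
from mtlpath import SurfaceGLM

spec = MeshSpec(nx=32, ny=32, effect_mm_per_sd=0.3, cluster_radius_mm=5.0)
data, planted = generate_surface_dataset(
    60, spec, cohort["tangles_q"].to_numpy()[:60], seed=8)
print(SurfaceGLM(data).fit(n_perm=1000, seed=9).summary())
```

```
Surface GLM: contrast 'pathology' (negative direction), 60 subjects, 1024 vertices
cluster threshold |t| > 2, 1000 permutations
 cluster  vertices   area mm^2   peak t   p (FWE)
       1        80       80.00   -14.30    0.0000
       2         2        2.00    -3.06    0.4865
       3         2        2.00    -3.35    0.4865
 ...
```

The planted 5 mm disc is recovered as an 80-vertex cluster whose surface
area exceeds every permutation maximum (corrected p < 0.001); the scattered
one- and two-vertex clusters are chance exceedances and are correctly
non-significant.

A command-line interface mirrors the pipeline stages
(`mtlpath simulate | quantify | summarize | validate | associate | compare |
surface-infer | run-all`); `run-all` writes a full report bundle (tidy CSVs,
a PLY t-map surface, and a manifest with the config hash and seed).

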
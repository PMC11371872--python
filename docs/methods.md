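# Methods

`mtlpath` re-implements, as a tested and reusable pipeline, a
quantitative-neuropathology analysis linking postmortem medial temporal lobe
(MTL) pathology burden to antemortem MRI morphometry. This note documents the
models and procedures, the parameters that matter, what the synthetic data
emulate (and do not), and the numerical choices made where the design was
genuinely open.

## Heatmap quantification

The upstream input is a per-pixel attention (activation) map in [0, 1] for
one pathology inclusion class (p-tau tangles or threads; neuronal/glial or
neuritic pTDP-43) over an annotated sampling box. The box is reduced to a
scalar burden measure in three steps:

1. **Partitioning.** The box mask is divided into contiguous segments of
   approximately equal area (target 200 × 200 µm = 40,000 µm², configurable).
   The segment count is `max(1, round(mask_area / target_area))`;
   disconnected mask components are partitioned separately. We use recursive
   balanced bisection of the pixel set: each cut is placed at the balanced
   position along either the principal axis of the pixel cloud or the
   geodesic (BFS-distance) ordering from an extremal pixel — whichever ends
   better balanced after repair — followed by reassignment of stray
   components across the cut and a boundary-move rebalancing pass that only
   makes connectivity-preserving moves. Any partitioner is acceptable that
   yields pairwise-disjoint, edge-connected segments covering the mask with
   areas within ±20% of target; the downstream statistics depend on these
   invariants, not on the particular heuristic. The procedure is
   deterministic (the `seed` argument exists for interface uniformity).
2. **Segment averaging.** The activation is averaged over each segment's
   pixels.
3. **Summary statistic.** A quantile or moment across segment averages.
   Candidates: mean, median, max, and the 25th/75th/90th/95th/99th
   percentiles. Quantiles interpolate linearly between closest order
   statistics (position `p(n−1)`), the default convention of mainstream
   numeric stacks. The 99th percentile is the pipeline default: in the
   statistic-selection experiment it discriminates expert ratings most
   consistently because it tracks a sparse high-activation tail while being
   robust to a single spurious maximum.

ROI-level measures pool the segment averages of all sampling boxes belonging
to one anatomical ROI before applying the statistic. An empty input yields a
missing value, never zero.

## Subject-level summaries

The hippocampal summary for one inclusion class is the arithmetic mean of
ROI measures over CA1, CA2, CA3, the dentate gyrus granular cell layer
(DG-GCL), the dentate gyrus hilus (DG-H), CA1/subiculum, and
subiculum/presubiculum, with two rules:

* For the **threads** class, DG-H is excluded before averaging (mossy fibres
  in the hilus are systematically misclassified as threads).
* The summary is missing if fewer than **three** anatomical regions are
  available, with the two dentate subregions jointly counting as one region
  (both values still enter the average when eligible). The region count is
  taken after the threads DG-H exclusion; this ordering is explicit and
  togglable because the alternative is equally defensible.

Raw summaries are linearly recalibrated to the 0–3 ordinal scale by ordinary
least squares of the matching semi-quantitative MTL rating on the raw
summary, mapping raw values through the fitted line. The regression is run
per pathology (p-tau and pTDP-43 separately). Direction matters only for
interpretability: the transform is affine, so every correlation and every
standardized regression coefficient involving the summary is unchanged.
Averaging in canonical ROI order makes the summary exactly invariant to
input ordering.

Semi-quantitative ratings use the scale absent 0, rare 0.5, mild 1,
moderate 2, severe 3. The MTL average rating is the mean over entorhinal
cortex, CA1/subiculum and dentate gyrus; a missing component makes the
average missing (the measure is defined as the mean of exactly those three
regions). LATE-NC staging from regional pTDP-43 ratings is hierarchical with
positivity at rating ≥ 1: stage 1 requires amygdala positivity, stage 2
additionally any of dentate gyrus / CA1-subiculum / entorhinal cortex, stage
3 additionally middle frontal gyrus. Non-contiguous positivity (e.g.
hippocampus positive, amygdala negative) cannot raise the stage and is
flagged; a missing amygdala rating makes the stage indeterminate.

## Rating validation

Agreement between quantitative measures and ordinal expert ratings is
measured by the Mann–Whitney AUC between adjacent rating categories:
`(wins + 0.5·ties) / (n₁·n₂)` counting pairs where the upper-category value
exceeds the lower-category value. One-sided p-values test "upper
stochastically greater": exact enumeration when `n₁·n₂ ≤ 100` and the data
are tie-free, tie-corrected normal approximation otherwise (exactness where
cheap, the standard approximation elsewhere). Spearman correlations use
midranks with two-sided p. The statistic-selection experiment ranks the
eight candidate statistics by mean adjacent-category AUC across inclusion
classes, reporting minimum AUC as tiebreaker; the ranking is flagged
unstable when no candidate clears 0.6 mean AUC.

## Region association models

For each of six MTL subregions — anterior and posterior hippocampus (volume,
mm³) and ERC, BA35, BA36, PHC (median thickness, mm) — ordinary least
squares relates the morphometric outcome to pathology predictors plus
nuisance covariates: age at death, sex, MRI field strength, antemortem
interval, and intracranial volume (ICV) for the two volume outcomes only.
The outcome and all continuous predictors are z-scored, so pathology
coefficients are standardized β; binary covariates (sex, field strength)
enter as 0/1 and their coefficients are not interpreted as standardized
contrasts. Inference on pathology contrasts is one-sided for negative
associations (`p = P(T_df ≤ t)`); two-sided tests are available by flag.
Missing data are handled by listwise deletion per model, with n and df
reported per fit. Results are flagged at uncorrected p < 0.05 and at the
Bonferroni threshold 0.05/6 = 8.33×10⁻³ separately.

Model comparison between a quantitative-pathology model and its
semi-quantitative counterpart (same outcome, same subjects, same nuisance
covariates) uses adjusted R², L1 prediction error (sum of absolute
residuals), AICc and BIC. Information criteria use the Gaussian-RSS form
`AIC = n·ln(RSS/n) + 2k`, `BIC = n·ln(RSS/n) + k·ln(n)` with
`k = coefficients + 1` (error variance counts as a parameter) and
`AICc = AIC + 2k(k+1)/(n−k−1)`; constant likelihood terms are omitted, which
is legitimate because only deltas between models on identical data are
interpreted. Deltas are stored as quantitative minus semi-quantitative, so
negative ΔAICc/ΔBIC/Δprediction-error (positive ΔR²adj) favor the
quantitative model; |ΔBIC| > 2/6/10 is labelled
positive/strong/very-strong evidence.

Subgroups: *advanced ADNC* = Braak stage V or VI; *LATE-NC* = LATE-NC stage
≥ 1. Cohort inclusion requires an antemortem interval ≤ 10 years (boundary
inclusive; a stricter 3-year sensitivity window is available) and passing
MRI segmentation/image QC in the hemisphere ipsilateral to neuropathology.

## Surface cluster inference

Per-vertex cortical thickness on a common triangulated template is regressed
on a shared subject-level design; the t-map for the contrast of interest is
thresholded at |t| > 2.0 in the contrast direction (negative contrasts are
extracted on −t > 2), and contiguous suprathreshold clusters are formed over
the mesh edge graph (vertex adjacency via shared edges). Cluster surface
area uses fractional triangle attribution: a triangle contributes k/3 of its
area when k of its vertices are suprathreshold. This rule is continuous in
the t-map and decomposes into per-vertex area shares, which also makes the
permutation loop fast; all-or-nothing attribution is available by flag.

Familywise correction follows the two-step Freedman–Lane procedure: fit the
nuisance-only model, permute its residual rows (one subject-level
permutation shared across all vertices, never per-vertex), reconstruct
pseudo-data as nuisance fit plus permuted residuals, refit the full model,
and record the maximum cluster area. The corrected p of each observed
cluster is the proportion of permutations with a larger maximum cluster
area. **Tie handling:** on continuous surfaces ties between areas have
measure zero and this proportion is unambiguous; on regular synthetic grids
cluster areas are atomic (integer multiples of the vertex area share) and
tie handling matters. The default counts tied null maxima half (mid-p),
which is unbiased; the strict larger-only count (anti-conservative under
ties) and an add-one smoothed estimate are available by flags. Vertices
with numerically zero residual variance receive t = 0 when the contrast
estimate is also zero (flat data) and a capped ±10⁸ when the fit is perfect
with a nonzero estimate, so noise-free limiting cases behave correctly.

## Synthetic data

The generators emulate the statistical structure of the four kinds of data the pipeline
consumes; they make no attempt at realistic histology appearance, stain
chemistry, scanner physics, or spatial autocorrelation of real cortical
noise.

* **Heatmaps**: homogeneous Poisson blobs (expected density
  `2·severity` per mm², linear hence monotone in severity), Gaussian profile
  (amplitude 0.8, spatial σ = 6 µm, truncated at 3σ) combined by maximum so
  activations stay in [0, 1], plus Gaussian background noise (σ = 0.02),
  clipped to [0, 1]. The linear rate makes the expected blob count
  analytically checkable against a connected-component count.
* **Ordinal ratings**: thresholding of the latent severity at four
  increasing cutpoints (defaults 0.5, 1.5, 3, 5 on the severity scale).
* **Cohorts**: covariates age ~ N(75, 8) yr, sex ~ Bernoulli(0.5), field
  strength ~ Bernoulli(0.7) for 3T, antemortem interval ~ U(0, 10) yr,
  ICV ~ N(1.4×10⁶, 1.5×10⁵) mm³ — free parameters chosen to match the
  plausible ranges of an aging autopsy cohort under a 10-year imaging
  window. Latent tau severity is Gamma(2, 1.5) with Braak stages cut at
  population quantiles such that 60.7% of subjects are stage V/VI; latent
  pTDP-43 severity is Exponential(1), which puts amygdala positivity (and
  hence LATE-NC stage ≥ 1, computed by the actual staging code from
  generated regional ratings) at 22.3% of subjects. Both match the reference
  cohort composition the pipeline targets (85/140 and 31/140). Planted outcome effects
  are standardized: each regional outcome is a linear combination of
  z-scored predictors plus Gaussian noise whose variance is set (by default)
  so the standardized outcome has unit variance, making planted standardized
  β directly recoverable; the default effect sizes mirror the reference
  whole-cohort tangles gradients (−0.23 to −0.47). Outcomes are then mapped
  to natural units (volumes ~2000 mm³, thickness ~2.5 mm), which is
  cosmetic because all fits re-standardize.
* **Surfaces**: a planar triangulated 64 × 64 grid (1 mm spacing) by
  default, with a disc-shaped planted cluster whose thickness decreases
  linearly in the z-scored pathology predictor, iid Gaussian vertex noise,
  and a design of intercept + pathology + an age nuisance covariate.

Because the synthetic noise is iid and the planted effects are exactly
linear, passing tests establish the correctness and calibration of the
*procedures* — not that real histology or MRI data satisfy the models'
assumptions. In particular, the familywise-error study certifies the
permutation machinery under exchangeability, which real spatially-correlated
thickness maps satisfy only after adequate template registration.

## Reference study sizes

The simulation studies in `mtlpath.experiments` (also run by
`scripts/acceptance.py`) use: parameter recovery — 200 cohorts of n = 140
with planted standardized β = −0.4; familywise error — 200 null surface
datasets (n = 40, 64 × 64 grid) at 500 permutations each; power — 100
replicates at n = 60 with a standardized effect of 0.8 (thickness deficit of
0.8 noise-SD per pathology SD) over an 8 mm-radius disc; model comparison —
200 cohorts of n = 140 where the outcome is driven by the continuous tangles
measure (β = −0.5) and the competing model carries its 5-level ordinal
coarsening. Production analyses default to 10,000 permutations; the studies
use 500 per dataset, which bounds the attainable corrected p at 0.002 —
ample for a 0.05-level decision.

## Known limitations

* The partition heuristic guarantees its invariants empirically, not by
  proof; pathological masks (long one-pixel filaments) may exceed the ±20%
  balance tolerance, in which case a warning is raised.
* The Freedman–Lane null is exact only under exchangeable errors; heavy
  heteroscedasticity across subjects would require a different permutation
  scheme.
* The hippocampal summary's missingness rules assume ROI labels from the
  fixed vocabulary; novel labels are rejected rather than ignored.
* Ordinal ratings are generated by deterministic thresholding of the latent
  severity; real expert ratings carry rater noise, so synthetic AUCs are
  optimistic upper bounds.
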
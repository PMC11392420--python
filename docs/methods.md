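# Methods

This note documents the models, conventions and numerical choices of
`proprio_disconnect`, and what the synthetic experiments do and do not
establish about real data.

## Data model

All images live on one shared voxel grid (`VolumeGrid`: values + 4×4
voxel-to-world affine, voxel centres at `affine @ (i, j, k, 1)`, 0-based
indices). No stage resamples: grids that differ in shape, voxel size or
transform beyond 1e-4 are refused, mirroring an analysis carried out
entirely in a single normalised space. Streamlines are polylines in world
mm, read from TRK or a plain-text dialect (one `x y z` per line, blank line
between streamlines) so that fixtures need no binary files.

Streamline rasterisation uses exact 3D voxel traversal (Amanatides–Woo
DDA): a voxel is reported iff the segment enters its cube. Property tests
check it against dense 0.01-voxel sampling of the segment.

## APM Task Score

A session is 9 targets × 6 blocks = 54 trials, each with the robot-placed
position (affected-arm frame) and the participant's mirror-match
(matching-arm frame, reflected about the body midline x = 0 for analysis).
Six parameters are computed per session:

| parameter | definition | units |
|---|---|---|
| `abs_error_xy` | mean of \|Δx\| and \|Δy\| pooled over trials | mm |
| `variability_xy` | mean over targets of per-target sample SDs (x and y pooled) | mm |
| `shift_x`, `shift_y` | mean signed Δ | mm |
| `ratio_x` | span of participant means, 3 left-most vs 3 right-most targets, over the robot span | – |
| `ratio_y` | same with proximal/distal triples | – |

The parameter vector has six components; descriptions of the task leave
the exact aggregation of x and y open, and this package pools x/y for
error and variability but keeps the shifts separable (the phenotypes of
interest — lateral vs distal misperception — differ).

**Normative model.** Each parameter is regressed on (1, age, sex,
handedness) over the control cohort; strictly positive parameters
(absolute error, variability, ratios) get a log pre-transform first. The
proprietary commercial transform is not public, so a transparent log/linear
surrogate is used and exposed in configuration. Z-scores are residuals over
the residual SD (regression df). Sample (n−1) SDs everywhere.

**Folding and composite.** One-sided parameters are folded so 0 is best:
error and variability through ζ(z) = Φ⁻¹((Φ(z)+1)/2); the signed shifts
through |z|, which has the same half-normal null distribution — the fold
expressed directly on a symmetric null. The two-sided ratios stay as
Z-scores (their square enters the RSS, so the sign is immaterial). The RSS
of the six components is located in the empirical normative RSS sample by
mid-rank ECDF percentile, p = (#less + ½#equal + ½)/(m+1), mapped through
Φ⁻¹ and ζ. This reproduces "shares the percentiles of a normal
distribution" without assuming RSS normality; by construction ~5% of
held-out controls exceed the 1.96 impairment cut (ζ(z) > 1.96 ⇔ percentile
> 0.95). The mid-rank map caps out-of-range values at percentile
(m+½)/(m+1), so Task Scores saturate near ζ(Φ⁻¹((m+½)/(m+1))) — about 3.6
for m = 2227. Severely impaired participants are all assigned this ceiling;
analyses that binarise at 1.96 are unaffected, but linear regressions on
the measured score lose sensitivity in the far tail.

The 1.96 threshold is used as the operative impairment rule (note that
under a strictly one-sided reading the 95th percentile corresponds to
1.645; the folded construction makes 1.96 the 95th percentile of the
one-sided score, which is the reading adopted).

## Lesion metrics

Tract lesion load = 100 × |lesion ∩ tract-mask| / |tract-mask|, with the
probabilistic atlas binarised at probability > 0 by default (any atlas
support counts; the threshold is configurable, and binary voxel counting —
not probability weighting — is used, matching the percentage definition).
Grey-matter lesion volume is |lesion ∩ GM| × voxel volume. A tract family
(left/right homologues paired by label suffix) enters the group analysis
iff strictly more than `min_n` = 25 participants have load > 0 on the left
homologue *and* strictly more than 25 on the right; "damage" is load > 0
exactly.

## Disconnectome maps

Per-control tractography is emulated: each control contributes a fixed
streamline set, and the visitation map of a lesion marks every voxel
traversed by a streamline of that control that also crosses the lesion
(threshold ≥ 1 streamline). The N binarised visitation maps are averaged
and scaled to 0–100%, so values are exact multiples of 100/N and invariant
to control order.

## Voxelwise inference

Per voxel, a linear model `value ~ group + grey-matter-volume` with a
one-sided t contrast (impaired > unimpaired). TFCE uses the published
defaults E = 0.5, H = 2, 6-connectivity, 100 integration steps with
midpoint thresholds h = (k−½)·dh, dh = max(t)/100 (midpoint discretisation
keeps the single-peak integral within 0.01% of h³/3; monotonicity under a
constant shift holds up to this discretisation error). FWE-corrected
p-values come from the permutation distribution of the image-wide maximum
TFCE under Freedman–Lane residual permutation (nuisance-model residuals
are permuted and re-added to the nuisance fit) with the add-one rule, so
p ∈ {1/(n_perm+1), …, 1}. Voxels constant across participants are excluded
from the analysis mask (p = 1), and computation is cropped to the mask
bounding box for speed. Constant covariates are rejected rather than
silently dropped.

## Cohort statistics

* ANCOVA: `score ~ side + total lesion volume`, type-III F for side (equals
  t² with two levels). Total — not grey-matter — lesion volume is used as
  the covariate here, since the side comparison addresses gross lesion-size
  imbalance; the tract regressions use grey-matter volume.
* χ²: Pearson 2×2 without continuity correction, p from χ²₁.
* Per-tract regressions: all variables (outcome included) standardised to
  zero mean, unit sample SD; OLS via statsmodels; Cohen's f² = R²/(1−R²).
  BH-FDR is applied once over the pooled family of all coefficient tests
  (3 per tract). Passing `gm_volume=None` reproduces the uncontrolled
  variant without the grey-matter covariate.
* PCA: eigendecomposition of the correlation matrix of the standardised
  predictor block; components ordered by eigenvalue, signs fixed so each
  component's largest-magnitude loading is positive; selected count is the
  smallest k whose cumulative explained variance reaches 95%. The
  component-score regression reports per-component t tests with BH-FDR
  over the k retained components. Lesion side is coded left = 0, right = 1,
  so positive side coefficients mean worse scores with right-hemisphere
  lesions.

## Synthetic study generator

The generator produces the complete miniature study the tests run on:

* **Grid** 32×38×32 at 3 mm (large enough for eight tubular tracts,
  small enough for seconds-scale tests). The brain is a centred ellipsoid;
  grey matter its outer shell.
* **Tracts**: n families of smooth tubular probability maps
  (exp(−(d/r)²) around a sinusoidal centreline, r = 5 mm, support cut at
  2r), mirrored in x for the right homologues.
* **Controls**: per control and tract, 8 streamlines — the exact
  centreline (the bundle core, which makes "a corridor shared by every
  control" a deterministic property) plus jittered copies.
* **Lesions**: the K voxels nearest a random centre under a random
  anisotropic ellipsoidal norm, restricted to one hemisphere; K set by the
  target volume, so achieved volume is exact to voxel rounding, blobs are
  connected, and no lesion crosses the midline. Cohort volumes are
  log-normal with mean 30.5 / SD 39.3 cc, truncated to what the toy
  hemispheres can host.
* **Cohort structure**: n = 203 with a 118:85 right:left split, age
  ~N(62, 14) years, sex 0/1 with the cohort's observed proportions,
  handedness 90% right; a binary ipsilesional motor-impairment flag with
  side-specific rates (15.3% left, 20.3% right).
* **Latent model**: latent = β₀ + β_side·side + Σ β_t·z(load_t) +
  β_gm·z(gm) + ε with loads standardised within the cohort, so the β are
  in score units per SD of load.
* **Trial model**: severity s sets the *means* of a subject's true
  phenotype — lateral shift 10·s mm, contraction max(0.2, 1 − 0.1·s),
  trial noise 5 + 3·s mm (floored at 0.5 mm) — and each subject's true
  values are drawn around those means with between-subject trait
  dispersion (shift SD 5 mm on both axes, contraction SD 0.05, log-normal
  noise-scale SD 0.25). The dispersion is essential: without it the
  normative spread of every parameter is pure estimation noise of a
  54-trial mean (sub-millimetre), any real deviation maps to |z| ≈ 7, and
  the Task Score degenerates to a step function of severity. With it the
  score rises smoothly from ~0.8 at s = 0 past the 1.96 cut near s ≈ 1.
  The normative generator adds a mild age effect (trial-noise scale
  +0.4%/year about the mid-age), small enough (≲0.3 SD across the age
  range) that covariate adjustment matters without dominating.

What the generator does **not** emulate: vascular lesion topographies,
real tract geometry and crossing fibres, diffusion signal and tracking
errors, per-control native-space normalisation, repeat-session learning
effects, or any dependence between lesion location and the latent score
other than through the modelled loads. Passing tests therefore validate
the *implementation* of the scoring and inference chain and its
calibration under a correctly specified generative model — not the
anatomical claims one could draw from real cohorts.

## Design notes on the recovery experiment

The coefficient-recovery experiment injects a single causal tract family
(β = 0.5 SD) alongside side and grey-matter effects. With one causal
tract, each per-tract regression that includes side and grey-matter volume
is correctly specified, so nominal 95% CI coverage is the mathematically
expected behaviour. With several *correlated* causal tracts the per-tract
models are misspecified (omitted-variable bias of the order of
β_other × partial correlation of the loads), which is a property of the
published per-tract design itself, not of this implementation; the
multi-tract situation is what the principal-component regression is for.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed (`numpy.random.default_rng`)
and is bit-reproducible; the pipeline manifest records every output file
with a SHA-256 hash plus the per-stage seeds. The test suite runs the
calibration experiments at the sizes chosen for the package's validation
protocol: normative calibration at 799 controls / 2227 assessments,
voxelwise FWE calibration over 20 null cohorts of n = 80 at 500
permutations, p-value uniformity over 1000 replicate null regressions at
n = 203, and effect recovery over 50 cohorts of n = 400. Production runs
default to 4000 permutations.
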
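# proprio-disconnect

Lesion–behaviour analysis linking white-matter disconnection to
proprioceptive impairment after stroke.

About half of stroke survivors lose some sense of where their affected arm
is (proprioception). A robotic **arm position matching (APM)** task
quantifies this: a robot passively places one arm at each of nine targets
(a 3×3 square, six blocks, 54 trials) and the participant mirror-matches
with the other arm, without vision. This package implements the full
analysis chain that relates APM performance to white-matter damage, plus a
synthetic study generator with known ground truth so every stage can be
validated end-to-end:

1. **APM Task Score** — six matching parameters per session (absolute
   error, variability, systematic shift x/y, contraction/expansion ratio
   x/y) are standardised against a normative control cohort with an
   age/sex/handedness regression (z = (value − prediction)/σ_resid).
   One-sided parameters are folded through the zeta transform
   ζ(z) = Φ⁻¹((Φ(z)+1)/2) so 0 is the best possible performance; the
   root-sum-square of the six components is mapped through the empirical
   normative RSS distribution into the one-sided Task Score. Scores > 1.96
   (the 95th-percentile rule) classify impairment.
2. **Tract lesion load** — per white-matter tract, the percentage of the
   tract's atlas voxels overlapped by the lesion; grey-matter lesion volume
   as the overlap of lesion and grey-matter segmentation.
3. **Disconnectome maps** — per participant, the fraction of control
   subjects (N = 10 by default) with a streamline that both crosses the
   lesion and visits a voxel, scaled to 0–100%.
4. **Statistics** — lesion-side ANCOVA (Task Score ~ side + lesion volume),
   χ² of ipsilesional impairment × hemisphere, per-tract standardised
   regressions (score ~ load + side + grey-matter volume) with
   Benjamini–Hochberg FDR over the pooled coefficient family, PCA of the
   predictor block with 95%-variance component selection and
   principal-component regression, and a voxelwise group GLM on the
   disconnectome maps with TFCE (E = 0.5, H = 2, 6-connectivity) and
   FWE correction from the permutation distribution of the maximum TFCE
   statistic (Freedman–Lane residual permutation).

## Worked example

```python
import numpy as np
from proprio_disconnect import synthetic as syn
from proprio_disconnect.scoring import normative_fit, task_score
from proprio_disconnect.cohort_stats import ancova_side, tract_regression_battery
from proprio_disconnect.lesion_load import tract_inclusion_filter

brain = syn.make_brain(seed=1)                       # 4 tract families, 10 controls
truth = syn.GroundTruth(causal_tracts={"tract1": 0.5},  # 0.5 SD per SD of load
                        side_effect=0.5, gm_effect=0.3)
cohort = syn.make_stroke_cohort(seed=2, brain=brain, truth=truth, n=203)

norm = syn.make_normative_cohort(seed=3, n_controls=300, n_assessments=600)
model = normative_fit(list(norm["session"]))
scores = {p: task_score(s, model) for p, s in cohort.sessions.items()}
y = np.array([scores[p].task_score for p in cohort.table.index])

anc = ancova_side(y, cohort.table["side"], cohort.table["total_volume_cc"])
homologues = [c for c in cohort.table.columns if c.endswith(("_left", "_right"))]
included = tract_inclusion_filter(cohort.table[homologues], min_n=25)
battery = tract_regression_battery(y, cohort.table, included,
                                   cohort.table["side"],
                                   cohort.table["gm_volume_cc"])
print(battery[battery.predictor == "tract_load"]
      [["tract", "coef", "se", "p", "p_fdr", "significant"]].round(4))
```

Output (seed 2, n = 203, 99 participants classified impaired):

```
 tract    coef     se      p  p_fdr  significant
tract0 -0.1159 0.0940 0.2191 0.2921        False
tract1  0.2387 0.0847 0.0053 0.0212         True
tract2 -0.0833 0.0927 0.3700 0.3700        False
tract3  0.1326 0.0835 0.1139 0.2580        False
```

The one tract given a causal effect in the ground truth (`tract1`) is the
only one surviving the 5% FDR; its standardised coefficient (0.24 SD of
Task Score per SD of lesion load) is the injected 0.5 attenuated by the
trial-level measurement chain. The ANCOVA for this draw gives
F = 2.572, p = 0.110 for the lesion-side effect.

The same analyses run from the shell as one reproducible pipeline:

```bash
proprio-disconnect run-all --outdir run/ --seed 7 --n-perm 4000
```

which writes NIfTI volumes, streamline files, CSV tables, the voxelwise
TFCE results and a `manifest.json` with a content hash of every output.

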
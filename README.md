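# conflicticc

Test–retest reliability analysis of a task-based fMRI emotional-conflict
experiment, packaged as a reusable, fully tested pipeline with a synthetic
cohort generator standing in for restricted multi-site human data.

## The problem

Longitudinal treatment studies that scan participants repeatedly (e.g. at
weeks 0, 2 and 8) can only attribute BOLD changes to an intervention if the
task's activation is stable over time in the absence of one.  The standard
stability index is the intraclass correlation **ICC(3,1)** — a two-way
mixed model with subjects as random effects and sessions as fixed effects,
single measurement, consistency form.  From the two-way ANOVA mean squares
(BMS between subjects, EMS residual, k sessions):

```
ICC(3,1) = (BMS − EMS) / (BMS + (k − 1)·EMS)
         =  σ²_b / (σ²_b + σ²_w)     with σ²_b = (BMS − EMS)/k, σ²_w = EMS
```

Because sessions are fixed effects, systematic scanner or practice shifts
between visits do not lower the estimate.  Reliability is classified as
poor (< 0.4), moderate-to-good (0.4–0.75) or excellent (> 0.75); a negative
estimate reflects a reliability of zero.

The task is an emotional Stroop / conflict-adaptation paradigm: happy or
fearful faces with the word "HAPPY" or "FEAR" superimposed; participants
name the facial emotion.  Each run holds 74 one-second stimuli at 3–5 s
jittered ISIs, counterbalanced for equal congruent/incongruent counts;
TR 2 s, 202 volumes per run, 2 runs per session, 3 sessions, up to 4 sites,
n = 36 analyzed participants.

The package covers the whole chain:

| module        | role |
| ------------- | ---- |
| `task_design` | counterbalanced trial sequences, cC/cI/iC/iI conflict-adaptation coding, BIDS-style events I/O |
| `behavior`    | run QC (25% commission / 30% total-error thresholds), error/post-error/±2 SD RT filters, Wilcoxon–Friedman–sign-test Stroop table, behavioral ICCs, exclusion-cascade bookkeeping |
| `synthetic`   | cohorts with **known** variance components at the contrast-map level, 4-D BOLD runs with HRF-convolved signals, trial-wise behavior with a configurable Stroop cost |
| `preprocess`  | PCA minimum-displacement reference volume, 85%-variance motion-regressor PCA, sliding-window spike censoring |
| `glm`         | first-level OLS (double-gamma HRF, Legendre trends, motion nuisance), contrasts, one-sample-t group maps, Bonferroni/permutation FWE, ≥10-voxel cluster extraction |
| `reliability` | ICC(3,1), Shrout–Fleiss F-based CIs, voxel-wise ICC maps, per-cluster / per-atlas-region median ICC tables, classification bands |
| `pipeline` / `cli` | seeded simulate → behave → glm → icc → report orchestration (`conflicticc all --out dir --seed 11`) |

## Worked example

```python
import numpy as np
from conflicticc import synthetic as syn, reliability as rel

truth = syn.two_region_truth(n_subjects=36, icc_high=0.8, icc_low=0.1, seed=42)
stack = syn.simulate_contrast_cohort(truth)          # 36 x 3 x (24,24,16)
icc_map = rel.voxelwise_icc(stack)
table = rel.median_icc(icc_map, truth.region_labels,
                       names={1: "posterior_visual_like",
                              2: "anterior_frontal_like"})
print(table[["name", "median_icc", "class"]])
```

prints

```
                    name  median_icc          class
0  posterior_visual_like    0.743      moderate_good
1  anterior_frontal_like    0.109               poor
```

i.e. the voxel-median ICC recovers the built-in reliability structure: the
posterior region (true ICC 0.8) is classified moderate-to-good while the
anterior region (true ICC 0.1) is poor — the qualitative pattern such
conflict tasks show, with visual regions far more stable than frontal ones.
The `examples/` directory holds one short narrative script per capability
(task generation, behavioral statistics, ICC maps, GLM contrast mapping,
preprocessing utilities, the full pipeline).

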
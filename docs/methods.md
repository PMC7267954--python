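# Methods

This note documents the models, parameter choices and numerical
conventions behind `conflicticc`, and what the synthetic-data tests do and
do not demonstrate about real data.

## The reliability model

For a measure observed on n subjects over k sessions, reliability is
ICC(3,1): two-way model, subjects random, sessions fixed, single
measurement, consistency form.  `reliability.anova_components` computes the
mean squares

```
BMS = k·Σ_i (ȳ_i − ȳ)² / (n−1)          df n−1
JMS = n·Σ_t (ȳ_t − ȳ)² / (k−1)          df k−1
EMS = (SS_total − SS_subj − SS_sess) / ((n−1)(k−1))
```

and the primary estimator is `(BMS − EMS) / (BMS + (k−1)·EMS)`, which
equals `σ²_b/(σ²_b+σ²_w)` under the moment estimators `σ²_b = (BMS−EMS)/k`,
`σ²_w = EMS`.  A secondary `variance_ratio` mode computes
`(σ²_b − σ²_w)/(σ²_b + σ²_w)` from the same estimators; it is exposed
because this difference-over-sum form circulates in the applied literature,
but it is *not* the same quantity (it subtracts the within variance in the
numerator) and is reported only as a comparison mode.

Conventions:

* **Negative estimates** are reported raw (they indicate a reliability of
  zero); `floor_negative=True` floors them at 0 for presentation and sets a
  flag.  Classification always places them in the lowest band.
* **Confidence intervals** are the F-based Shrout–Fleiss intervals:
  F = BMS/EMS on (n−1, (n−1)(k−1)) dof, bounds mapped through
  `(F* − 1)/(F* + k − 1)`.  As EMS → 0 the interval collapses to (1, 1);
  this limit is guarded at 1 − 1e−12.
* **Classification bands**: primary three-band scheme poor < 0.4 ≤
  moderate-good ≤ 0.75 < excellent (both boundaries belong to the middle
  band); an alternate four-band scheme (0.4/0.6/0.8, lower-inclusive) is
  selectable.
* **Missing sessions**: complete-case — subjects with any missing cell are
  dropped with a warning; fewer than 2 remaining subjects is an error.
* **Degenerate input** (zero total variance) yields NaN with a flag, and
  NaN voxels are excluded from region medians rather than treated as zero.
* The behavioral and imaging reliability use the same consistency
  estimator.  (Absolute-agreement variants are deliberately out of scope;
  the consistency form is the one suited to multi-site data with fixed
  session effects.)

`voxelwise_icc` vectorizes the identical arithmetic across voxels; a test
pins it to an explicit-loop oracle at 1e−12 on a seeded grid of small
matrices, and an independent cross-check against `pingouin`'s ICC(C,1) row
guards the single-matrix path.

The region-level statistic is the **median voxel ICC** within each
activation cluster (primary mode) or each integer atlas label (exploratory
mode), mirroring the convention that a cluster's reliability is summarized
by its median rather than its mean.

## Synthetic cohorts

The study conditions emulated are: 36 subjects × 3 sessions (weeks 0/2/8)
× up to 4 sites; 2 runs × 74 trials/session; TR 2 s, 202 volumes
(6 min 44 s acquisition), 4 mm voxels on a desk-scale 24×24×16 grid.

**Contrast level** (`simulate_contrast_cohort`): voxel v in region r,
subject i, session t:

```
y[i,t,v] = amplitude_r + site(i) + s_ir + d_t + ε_itv
s_ir ~ N(0, σ²_b,r)   once per subject × region
ε    ~ N(0, σ²_w,r)   independent per subject, session, voxel
```

so the true ICC per region is exactly σ²_b/(σ²_b+σ²_w).  Session effects
d_t shift everyone equally and leave the consistency ICC unchanged (tested
empirically).  Site offsets are subject-constant and therefore *raise* the
realized ICC; they default to zero so recovery tests are pure, and a test
asserts the inflation direction when they are enabled.

**BOLD level** (`simulate_bold_run`): signal = Σ conditions amplitude ×
(1 s boxcars at the condition's onsets convolved with the canonical
double-gamma HRF, peak ≈ 6 s, undershoot ≈ 16 s), plus linear/quadratic
drift, white noise, and optional spike artifacts; the accompanying motion
table is a 6-parameter smooth random walk with displacement injected at
spike volumes.  One caveat discovered while validating the generator:
with congruent and incongruent trials interleaved at 3–5 s ISIs, the two
HRF-convolved regressors are strongly anti-correlated, giving the
incongruent−congruent contrast a standard error of ≈ 0.82 per unit noise
SD even at 202 volumes.  Sign recovery in ≳95% of voxels therefore needs
noise SD ≲ 0.2 at a 0.3 contrast; at SD 1 the estimate is unbiased but
individual-voxel signs flip often.  Tests assert exactly what holds.

**Behavior** (`simulate_behavior`): RT(ms) = exp(N(μ_i + session wobble,
σ_rt)) + δ_stroop·[incongruent] + δ_fear·[fear face], with μ_i ~
N(log 650 ms, 0.10) the stable subject trait and session wobble SD 0.073
chosen so the implied reliability of a session's median RT is
0.10²/(0.10²+0.073²) ≈ 0.65 — the mid-range of healthy-control behavioral
ICCs for this kind of task.  δ_stroop defaults to 60 ms and δ_fear to
25 ms, matching the median RT costs the task elicits; commission rates are
2%/5% (congruent/incongruent) and omissions 1%, giving accuracies around
0.95–0.98.  Errors trigger the same QC and filter paths as real data.

What the generators do **not** model: spatial autocorrelation of noise,
physiological (cardiac/respiratory) noise, scanner drift nonstationarity,
registration error, anatomical variability, or site-by-time interactions
(the site term is a constant offset only).  Passing tests therefore
demonstrate the statistical machinery is correct under the stated variance
model, not that real acquisitions meet that model.

## GLM and thresholding

First level is per-voxel OLS: condition regressors (SPM-style double-gamma
via nilearn), Legendre trends of order 0–2, optional discrete-cosine
high-pass columns, and motion regressors.  A printed "100 Hz high-pass"
specification is physically impossible at TR 2 s and is read as the
conventional 100 s *period* cutoff; the pipeline log records this.
Rank-deficient designs drop dependent columns via pivoted QR with a logged
report.  Runs within a session are combined by averaging contrast maps (a
fixed-effects combination); the second level is a one-sample t across
subjects with dof n−1, zero-variance voxels capped at ±1e6 and flagged.

Family-wise error control is voxel-level Bonferroni across in-mask voxels
(with a sign-flip permutation max-t alternative), plus a minimum cluster
size of 10 voxels under 6-connectivity (18/26 configurable).  Both are
conservative, testable stand-ins for random-field-theory FWE, which is out
of scope.  When nothing survives, the cluster extractor logs the
uncorrected-threshold (p < .001) fallback convention rather than failing.

## Behavioral filters and statistics

Run QC: commission errors ≤ 25% and total errors ≤ 30% per run; any
failing run flags the subject.  The RT filter removes error trials, the
immediately following trial (never across the run boundary — runs are
separated by rest), and trials beyond ±2 SD of the subject × session ×
trial-type mean computed over correct, non-post-error trials.  The outlier
pass is iterated to a fixed point, which makes the filter idempotent (a
single pass is not: removing a tail shrinks the window).  Accuracy keeps
outliers and post-error trials and counts omissions as errors.  The SD
window is computed within subject (the within-subject convention of the
task literature) over the congruency × emotion cells.

Group tests are nonparametric with a Shapiro–Wilk gate recorded per
comparison: related-samples Wilcoxon signed-rank (Pratt zero handling,
mid-ranked ties, normal approximation for the z statistic), a sign test
substituted when > 25% of paired differences are zero, Friedman across the
three sessions, and a Bonferroni-adjusted alpha of 0.0125.

The exclusion cascade is bookkeeping with defaults matching the emulated
study: 59 recruited − 11 scan-quality − 5 missing/withdrawn − 4 behavioral
− 2 accuracy − 1 lone-site participant = 36 analyzed.

## Pipeline defaults and problem sizes

`PipelineConfig` defaults run the full BOLD route at the protocol scale
(36 × 3 × 2 runs of 202 volumes on a 24×24×16 grid, ≈ 20 s on one core).
The two-region truth uses ICC 0.8 (posterior "visual-like") vs 0.1
(anterior "frontal-like") with contrast amplitude 2.0 and BOLD noise SD
0.5, chosen so the group map shows strong activation (peak t in the
10–17 range typical of such cohorts) and clusters survive the Bonferroni
stand-in at n = 36.  Activation clusters are taken from the first
session's group map, and ICC maps use all three sessions.  Tests and the
examples shrink the cohort/grid/run length to keep the default suite in
seconds; the statistical checks (oracle agreement, recovery, coverage,
ranking) run at the full n = 36 × 3 design because they operate at the
contrast level, where that scale is cheap.

## Known limitations

* Registration, slice timing, smoothing-to-FWHM and tissue masking are
  pass-through stages here; the package assumes co-registered inputs
  (true by construction for synthetic data).
* OLS ignores temporal autocorrelation; synthetic noise is white by
  default.  (Prewhitening would matter for real data.)
* The BOLD-level route attenuates voxel ICC relative to the contrast-level
  truth because GLM estimation noise adds within-subject variance — a real
  phenomenon, but it means the two routes' ICCs are not directly
  comparable at equal truth settings.
* The run length implied by 74 trials at mean 4 s ISI (≈ 370 s + lead-in)
  is slightly shorter than the 202-volume acquisition window; trailing
  fixation fills the difference, and the lead-in fixation (default 10 s)
  is configurable.
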
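"""Voxel-wise ICC(3,1) maps and region-level median reliability.

Draws a contrast-level cohort (36 subjects x 3 sessions) with a known
two-region truth — a posterior "visual-like" region at true ICC 0.8 and an
anterior "frontal-like" region at true ICC 0.1 — and recovers the region
ranking from the voxel-wise ICC map.
"""

import numpy as np

from conflicticc import reliability as rel
from conflicticc import synthetic as syn

truth = syn.two_region_truth(n_subjects=36, icc_high=0.8, icc_low=0.1, seed=42)
stack = syn.simulate_contrast_cohort(truth)
print(f"cohort: {stack.n_subjects} subjects x {stack.n_sessions} sessions, "
      f"grid {stack.mask.shape}, {int(stack.mask.sum())} in-mask voxels")

icc_map = rel.voxelwise_icc(stack)
table = rel.median_icc(
    icc_map, truth.region_labels,
    names={1: "posterior_visual_like", 2: "anterior_frontal_like"},
)
print("\nmedian voxel ICC per region (truth: 0.8 posterior, 0.1 anterior):")
for _, row in table.iterrows():
    print(f"  {row['name']:24s} median ICC {row['median_icc']:5.3f} "
          f"({row['n_defined']} voxels) -> {row['class']}")

# single-measure ICC with its F-based confidence interval
region_mean = stack.values[:, :, truth.region_labels == 1].mean(axis=2)
res = rel.icc31(region_mean)
print(f"\nregion-mean ICC(3,1): {res.icc:.3f} "
      f"[{res.ci_low:.3f}, {res.ci_high:.3f}] ({res.class_label})")
# Averaging voxels strips the independent within-voxel noise, so the
# region-mean ICC sits above the voxel-median estimate.

# the printed-equation comparison mode
vr = rel.icc31(region_mean, form="variance_ratio")
print(f"variance-ratio form (comparison mode): {vr.icc:.3f}")
assert np.isfinite(res.icc)
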
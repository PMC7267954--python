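"""Reference-volume selection, motion-regressor PCA and spike censoring.

Shows the three procedural preprocessing utilities on small synthetic
inputs: a volume series with one displaced frame, a 6-parameter motion
table dominated by one drift direction, and a metric series with a spike.
"""

import numpy as np

from conflicticc import preprocess as pre

# --- minimum-displacement reference volume -------------------------------
rng = np.random.default_rng(0)
base = rng.normal(100.0, 10.0, size=(16, 16, 8))
series = np.repeat(base[..., None], 20, axis=-1) + rng.normal(0, 0.5, (16, 16, 8, 20))
series[..., 12] = np.roll(series[..., 12], 4, axis=0)   # displaced frame
ref = pre.min_displacement_reference(series, smooth_fwhm=6.0, voxel_mm=4.0)
print(f"reference volume: {ref} (the displaced frame 12 is avoided)")

# --- motion-regressor PCA -------------------------------------------------
n_vol = 202
mpe = 0.02 * rng.normal(size=(n_vol, 6))
mpe[:, 2] += np.linspace(0, 1.5, n_vol)     # slow z-drift dominates
regressors = pre.motion_regressors(mpe, variance_keep=0.85)
print(f"motion PCA: {regressors.shape[1]} component(s) preserve 85% of the "
      "motion variance (one dominant drift direction)")

# --- spike censoring ------------------------------------------------------
fd = pre.framewise_displacement(mpe)
fd[100] += 2.5                               # injected head jerk
censor = pre.censor_outliers(fd, window=15, z_thresh=4.0)
print(f"censoring: flagged volumes {list(censor.outliers)}; "
      f"repaired value {censor.repaired[100]:.3f} mm "
      f"(was {fd[100]:.3f} mm)")
# Flagged volumes are replaced by cubic-spline interpolation over their
# neighbors; non-flagged volumes are never altered.
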
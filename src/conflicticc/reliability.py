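"""ICC(3,1) reliability machinery.

Test-retest reliability of a measure observed for n subjects over k sessions
is quantified with the intraclass correlation ICC(3,1): a two-way mixed
model in which subjects are random effects and sessions are fixed effects,
single measurement, consistency form.  From the two-way ANOVA mean squares
(BMS between subjects, JMS between sessions, EMS residual):

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS)

which equals sigma2_b / (sigma2_b + sigma2_w) with the usual moment
estimators sigma2_b = (BMS - EMS)/k and sigma2_w = EMS.  Because sessions
are fixed effects, additive per-session shifts (systematic scanner or
practice effects) do not reduce the ICC.  Negative estimates can occur when
within-subject variance exceeds between-subject variance and are reported
raw (a negative ICC reflects a reliability of zero; flooring is an explicit
presentation option).

A secondary ``variance_ratio`` form computes
(sigma2_b - sigma2_w) / (sigma2_b + sigma2_w) from the same moment
estimators; it is exposed for comparison only and is NOT the primary
estimator (the two differ whenever sigma2_w > 0).

Confidence intervals are the F-based Shrout-Fleiss intervals:
F = BMS/EMS on (n-1, (n-1)(k-1)) degrees of freedom, with bounds mapped
through (F* - 1)/(F* + k - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: classification band schemes: list of (lower-inclusive bound, label),
#: evaluated from the top; negative estimates always fall in the lowest band
SCHEMES = {
    # poor < 0.4 <= moderate_good <= 0.75 < excellent
    "three_band": [(0.75, "excellent"), (0.4, "moderate_good"), (-np.inf, "poor")],
    # 0.8 excellent / 0.6 good / 0.4 moderate / poor
    "four_band": [
        (0.8, "excellent"),
        (0.6, "good"),
        (0.4, "moderate"),
        (-np.inf, "poor"),
    ],
}


@dataclass(frozen=True)
class VarianceComponents:
    """Two-way ANOVA mean squares for an n-subjects x k-sessions matrix."""

    n: int
    k: int
    bms: float   # between-subject mean square, df = n - 1
    jms: float   # between-session mean square, df = k - 1
    ems: float   # residual mean square, df = (n - 1)(k - 1)
    grand_mean: float

    @property
    def sigma2_between(self) -> float:
        """Moment estimator of the between-subject variance component."""
        return (self.bms - self.ems) / self.k

    @property
    def sigma2_within(self) -> float:
        """Moment estimator of the within-subject (residual) variance."""
        return self.ems


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    class_label: str
    negative_floored: bool = False
    degenerate: bool = False


def _drop_incomplete(Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Complete-case handling: drop subjects with any missing session."""
    keep = np.all(np.isfinite(Y), axis=1)
    dropped = int(Y.shape[0] - keep.sum())
    return Y[keep], dropped


def anova_components(Y: np.ndarray) -> VarianceComponents:
    """Two-way (subjects x sessions) ANOVA mean squares.

    Parameters
    ----------
    Y : array, shape (n_subjects, k_sessions)
        One measurement per subject and session.  Subjects with any
        non-finite cell are dropped (complete-case) with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D subjects x sessions matrix")
    Y, dropped = _drop_incomplete(Y)
    if dropped:
        warnings.warn(f"dropped {dropped} subject(s) with missing sessions",
                      stacklevel=2)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 sessions, got {n}x{k}")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    sess_means = Y.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_sess = n * np.sum((sess_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_resid = max(ss_total - ss_subj - ss_sess, 0.0)
    return VarianceComponents(
        n=n,
        k=k,
        bms=ss_subj / (n - 1),
        jms=ss_sess / (k - 1),
        ems=ss_resid / ((n - 1) * (k - 1)),
        grand_mean=float(grand),
    )


def icc_from_components(vc: VarianceComponents, form: str = "shrout_fleiss") -> float:
    """ICC(3,1) point estimate from two-way mean squares.

    ``form='shrout_fleiss'`` (primary) uses the mean-square ratio;
    ``form='variance_ratio'`` computes (s2b - s2w)/(s2b + s2w) from the
    moment estimators, a comparison mode only.
    """
    if form == "shrout_fleiss":
        denom = vc.bms + (vc.k - 1) * vc.ems
        if denom <= 0:
            return np.nan
        return (vc.bms - vc.ems) / denom
    if form == "variance_ratio":
        s2b, s2w = vc.sigma2_between, vc.sigma2_within
        denom = s2b + s2w
        if denom <= 0:
            return np.nan
        return (s2b - s2w) / denom
    raise ValueError(f"unknown ICC form {form!r}")


def icc_ci(
    vc: VarianceComponents, alpha: float = 0.05
) -> tuple[float, float]:
    """F-based Shrout-Fleiss confidence interval for ICC(3,1).

    The observed F = BMS/EMS on (n-1, (n-1)(k-1)) dof is divided /
    multiplied by the appropriate F critical values and mapped through
    (F - 1)/(F + k - 1).  As EMS -> 0 with BMS > 0 the interval collapses
    toward (1, 1); this limit is guarded.
    """
    n, k = vc.n, vc.k
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if vc.ems <= 0:
        if vc.bms > 0:
            return (1.0 - 1e-12, 1.0)
        return (np.nan, np.nan)
    F = vc.bms / vc.ems
    f_low = F / stats.f.isf(alpha / 2, df1, df2)
    f_high = F * stats.f.isf(alpha / 2, df2, df1)
    low = (f_low - 1.0) / (f_low + k - 1.0)
    high = (f_high - 1.0) / (f_high + k - 1.0)
    return (float(low), float(high))


def classify(icc: float, scheme: str = "three_band") -> str:
    """Map an ICC value to a reliability class label.

    Band boundaries 0.4 and 0.75 belong to the middle band of the
    three-band scheme (strict on the upper boundary, inclusive on the
    lower); the four-band scheme is lower-inclusive at 0.4/0.6/0.8.
    Negative estimates reflect a reliability of zero and fall in the lowest
    band; NaN maps to ``'undefined'``.
    """
    if not np.isfinite(icc):
        return "undefined"
    if scheme == "three_band":
        if icc > 0.75:
            return "excellent"
        if icc >= 0.4:
            return "moderate_good"
        return "poor"
    if scheme == "four_band":
        for bound, label in SCHEMES["four_band"][:-1]:
            if icc >= bound:
                return label
        return "poor"
    raise ValueError(f"unknown classification scheme {scheme!r}")


def icc31(
    Y: np.ndarray,
    form: str = "shrout_fleiss",
    alpha: float = 0.05,
    scheme: str = "three_band",
    floor_negative: bool = False,
) -> IccResult:
    """ICC(3,1) with 95% CI and reliability class for one measure.

    Parameters
    ----------
    Y : array, shape (n_subjects, k_sessions)
    form : str
        'shrout_fleiss' (primary mean-square estimator) or
        'variance_ratio' (comparison mode, see module docstring).
    floor_negative : bool
        If True, negative point estimates are floored at 0 for presentation
        and flagged via ``negative_floored``; raw values are the default.
    """
    vc = anova_components(Y)
    icc = icc_from_components(vc, form=form)
    if not np.isfinite(icc):
        return IccResult(np.nan, np.nan, np.nan, vc.n, vc.k,
                         "undefined", degenerate=True)
    low, high = icc_ci(vc, alpha=alpha)
    floored = False
    if floor_negative and icc < 0:
        icc, floored = 0.0, True
    return IccResult(
        icc=float(icc),
        ci_low=low,
        ci_high=high,
        n=vc.n,
        k=vc.k,
        class_label=classify(icc, scheme=scheme),
        negative_floored=floored,
    )


# ---------------------------------------------------------------------------
# voxel-wise maps and region summaries
# ---------------------------------------------------------------------------


def voxelwise_icc(
    stack, mask: np.ndarray | None = None, form: str = "shrout_fleiss"
) -> np.ndarray:
    """Voxel-wise ICC(3,1) map from a subjects x sessions x voxels stack.

    Parameters
    ----------
    stack : ContrastStack or array
        Either a ``ContrastStack`` (with ``.values`` of shape
        (n_subjects, k_sessions, *grid) and ``.mask``) or a bare array of
        that shape.
    mask : bool array, optional
        Overrides the stack's mask; voxels outside carry NaN.

    Returns
    -------
    array of shape ``grid`` with ICC values; NaN outside the mask and at
    degenerate (zero-total-variance) voxels.

    Notes
    -----
    The computation is the same two-way ANOVA as :func:`anova_components`,
    vectorized across voxels.
    """
    values = getattr(stack, "values", stack)
    if mask is None:
        mask = getattr(stack, "mask", None)
    values = np.asarray(values, dtype=float)
    if values.ndim < 3:
        raise ValueError("stack must be (subjects, sessions, *grid)")
    n, k = values.shape[:2]
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and sessions, got {n}x{k}")
    grid_shape = values.shape[2:]
    Y = values.reshape(n, k, -1)

    grand = Y.mean(axis=(0, 1))
    subj_means = Y.mean(axis=1)
    sess_means = Y.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2, axis=0)
    ss_sess = n * np.sum((sess_means - grand) ** 2, axis=0)
    ss_total = np.sum((Y - grand) ** 2, axis=(0, 1))
    ss_resid = np.clip(ss_total - ss_subj - ss_sess, 0.0, None)

    bms = ss_subj / (n - 1)
    ems = ss_resid / ((n - 1) * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "shrout_fleiss":
            denom = bms + (k - 1) * ems
            icc = np.where(denom > 0, (bms - ems) / np.where(denom > 0, denom, 1),
                           np.nan)
        elif form == "variance_ratio":
            s2b = (bms - ems) / k
            denom = s2b + ems
            icc = np.where(denom > 0, (s2b - ems) / np.where(denom > 0, denom, 1),
                           np.nan)
        else:
            raise ValueError(f"unknown ICC form {form!r}")

    icc = icc.reshape(grid_shape)
    if mask is not None:
        icc = np.where(np.asarray(mask, dtype=bool), icc, np.nan)
    return icc


def median_icc(
    icc_map: np.ndarray,
    regions,
    names: dict[int, str] | None = None,
    scheme: str = "three_band",
) -> pd.DataFrame:
    """Median voxel ICC per cluster or atlas region.

    The median ICC within a region is the primary region-level reliability
    statistic; it is computed over that region's voxels with a defined
    (non-NaN) ICC only.

    Parameters
    ----------
    icc_map : array
        Voxel-wise ICC map (NaN = undefined / out of mask).
    regions : ClusterSet or integer-labeled array
        Either a ``ClusterSet`` (from :mod:`conflicticc.glm`) whose clusters
        define the regions, or an integer atlas volume of the same shape
        (label 0 = background).
    names : dict, optional
        Region id -> display name.

    Returns
    -------
    DataFrame with columns region_id, name, n_voxels, n_defined,
    median_icc, class.
    """
    icc_map = np.asarray(icc_map, dtype=float)
    clusters = getattr(regions, "clusters", None)
    if clusters is not None:
        region_iter = [(c.cluster_id, c.voxels) for c in clusters]
    else:
        labels = np.asarray(regions)
        if labels.shape != icc_map.shape:
            raise ValueError("atlas shape does not match ICC map")
        ids = np.unique(labels)
        region_iter = [(int(i), np.nonzero(labels == i)) for i in ids if i != 0]

    rows = []
    for rid, vox in region_iter:
        vals = icc_map[vox]
        defined = vals[np.isfinite(vals)]
        med = float(np.median(defined)) if defined.size else np.nan
        rows.append(
            {
                "region_id": rid,
                "name": (names or {}).get(rid, str(rid)),
                "n_voxels": int(np.size(vals)),
                "n_defined": int(defined.size),
                "median_icc": med,
                "class": classify(med, scheme=scheme) if defined.size else "undefined",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region_id", "name", "n_voxels", "n_defined", "median_icc", "class"],
    )
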
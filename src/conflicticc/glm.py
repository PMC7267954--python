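"""First- and second-level GLM contrast mapping and cluster extraction.

First level: per-voxel ordinary least squares of a run's BOLD time series
on HRF-convolved condition regressors (double-gamma / canonical SPM shape),
Legendre polynomial trend columns (orders 0-2), optional discrete-cosine
high-pass columns (100 s period cutoff) and motion regressors.  Runs within
a session are combined by averaging their contrast maps (a fixed-effects
combination).  Second level: a one-sample t-test per voxel across subjects
(random effects), with Bonferroni (or permutation max-t) family-wise error
control as a conservative stand-in for random-field theory, and connected-
component cluster extraction with a minimum cluster size (default 10
voxels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor
from numpy.polynomial import legendre
from scipy import ndimage, stats
from scipy.linalg import qr as scipy_qr

from conflicticc.task_design import TaskSequence, TrialEvent

logger = logging.getLogger(__name__)

#: condition name -> predicate on a trial
CONDITIONS = {
    "all_faces": lambda t: True,
    "congruent": lambda t: t.congruent,
    "incongruent": lambda t: not t.congruent,
    "happy_face": lambda t: t.face_emotion == "happy",
    "fear_face": lambda t: t.face_emotion == "fear",
    "happy_word": lambda t: t.word == "HAPPY",
    "fear_word": lambda t: t.word == "FEAR",
    "cC": lambda t: t.adaptation_label == "cC",
    "cI": lambda t: t.adaptation_label == "cI",
    "iC": lambda t: t.adaptation_label == "iC",
    "iI": lambda t: t.adaptation_label == "iI",
}

#: named contrasts -> (condition columns, weights)
NAMED_CONTRASTS = {
    "all_faces": ({"all_faces": 1.0}),
    "congruent": ({"congruent": 1.0}),
    "incongruent": ({"incongruent": 1.0}),
    "incongruent-congruent": ({"incongruent": 1.0, "congruent": -1.0}),
    "fear_face-happy_face": ({"fear_face": 1.0, "happy_face": -1.0}),
    "fear_word-happy_word": ({"fear_word": 1.0, "happy_word": -1.0}),
    "iI-cI": ({"iI": 1.0, "cI": -1.0}),
}

#: condition sets that form estimable (non-collinear) first-level designs
CONTRAST_CONDITIONS = {
    "all_faces": ["all_faces"],
    "congruent": ["congruent", "incongruent"],
    "incongruent": ["congruent", "incongruent"],
    "incongruent-congruent": ["congruent", "incongruent"],
    "fear_face-happy_face": ["happy_face", "fear_face"],
    "fear_word-happy_word": ["happy_word", "fear_word"],
    "iI-cI": ["cC", "cI", "iC", "iI"],
}


@dataclass
class DesignMatrix:
    """First-level design: condition + nuisance columns sampled at the TR."""

    matrix: np.ndarray            # (n_volumes, n_columns)
    labels: list[str]
    tr: float
    condition_labels: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


@dataclass
class StatMap:
    """Second-level statistic volume."""

    t: np.ndarray
    p: np.ndarray
    dof: int
    mask: np.ndarray
    degenerate: np.ndarray | None = None  # zero-variance voxels (t capped)


@dataclass
class Cluster:
    cluster_id: int
    voxels: tuple[np.ndarray, ...]   # index arrays, as from np.nonzero
    size: int
    peak_index: tuple[int, ...]
    peak_stat: float
    peak_mm: tuple[float, ...] | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float
    min_size: int
    n_suprathreshold: int            # before the minimum-size filter

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": c.cluster_id,
                "k": c.size,
                "peak_t": c.peak_stat,
                "x": c.peak_index[0],
                "y": c.peak_index[1],
                "z": c.peak_index[2] if len(c.peak_index) > 2 else 0,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "k", "peak_t", "x", "y", "z"])

    def label_volume(self, shape: tuple[int, ...]) -> np.ndarray:
        """Integer-labeled volume with each cluster's id."""
        out = np.zeros(shape, dtype=int)
        for c in self.clusters:
            out[c.voxels] = c.cluster_id
        return out


def condition_regressor(
    trials: list[TrialEvent],
    condition: str,
    frame_times: np.ndarray,
    hrf_model: str = "spm",
) -> np.ndarray:
    """HRF-convolved regressor for one condition of one run.

    Unit-duration boxcars at the condition's onsets convolved with the
    canonical double-gamma HRF (peak ~6 s, undershoot ~16 s), sampled at
    the frame times.  Returns zeros if the condition has no trials.
    """
    pred = CONDITIONS[condition]
    onsets = [t.onset for t in trials if pred(t)]
    if not onsets:
        return np.zeros(len(frame_times))
    durations = [t.duration for t in trials if pred(t)]
    cond = np.array([onsets, durations, np.ones(len(onsets))])
    reg, _ = compute_regressor(cond, hrf_model, frame_times, con_id=condition)
    return reg[:, 0]


def legendre_trends(n_volumes: int, order: int = 2) -> np.ndarray:
    """Legendre polynomial trend columns, orders 0..order, on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    return legendre.legvander(x, order)


def cosine_drift(n_volumes: int, tr: float, period_cut: float = 100.0) -> np.ndarray:
    """Discrete-cosine high-pass basis with the given period cutoff (s).

    Returns only the non-constant components (the constant is carried by
    the order-0 Legendre trend).
    """
    n_basis = int(np.floor(2 * n_volumes * tr / period_cut))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * (t + 0.5) * k / n_volumes) for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def build_design(
    seq: TaskSequence,
    n_volumes: int,
    tr: float = 2.0,
    run_index: int = 1,
    conditions: list[str] | None = None,
    motion: np.ndarray | None = None,
    trend_order: int = 2,
    highpass_period: float | None = None,
) -> DesignMatrix:
    """Assemble the first-level design matrix for one run.

    Parameters
    ----------
    conditions : list of condition names
        Defaults to ``['congruent', 'incongruent']``.  Conditions with no
        trials are omitted with a warning.
    motion : (n_volumes, m) array, optional
        Motion regressors (e.g. from ``preprocess.motion_regressors``).
    trend_order : int
        Legendre trend order (default 2: constant, linear, quadratic).
    highpass_period : float, optional
        If given, append discrete-cosine high-pass columns with this period
        cutoff in seconds (the conventional reading of a "100 s cutoff").
    """
    trials = seq.run(run_index)
    if trials:
        end = max(t.onset + t.duration for t in trials)
        if end > n_volumes * tr:
            raise ValueError(
                f"events end at {end:.1f}s, beyond the run ({n_volumes * tr:.1f}s)"
            )
    conditions = list(conditions or ["congruent", "incongruent"])
    frame_times = np.arange(n_volumes) * tr

    cols, labels, cond_labels = [], [], []
    for cond in conditions:
        reg = condition_regressor(trials, cond, frame_times)
        if not np.any(reg):
            warnings.warn(f"condition {cond!r} has no trials; column omitted",
                          stacklevel=2)
            continue
        cols.append(reg)
        labels.append(cond)
        cond_labels.append(cond)

    trend = legendre_trends(n_volumes, trend_order)
    for j in range(trend.shape[1]):
        cols.append(trend[:, j])
        labels.append(f"trend_{j}")
    if highpass_period:
        dct = cosine_drift(n_volumes, tr, highpass_period)
        for j in range(dct.shape[1]):
            cols.append(dct[:, j])
            labels.append(f"drift_{j}")
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != n_volumes:
            raise ValueError("motion regressors must have one row per volume")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            labels.append(f"motion_{j}")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("design matrix is rank deficient (collinear columns)",
                      stacklevel=2)
    return DesignMatrix(matrix=X, labels=labels, tr=tr,
                        condition_labels=cond_labels)


@dataclass
class GlmFit:
    betas: dict[str, np.ndarray]       # label -> 3-D beta map
    residual_variance: np.ndarray      # 3-D map
    dof: int
    dropped_columns: list[str]


def fit_glm(bold: np.ndarray, design: DesignMatrix,
            mask: np.ndarray | None = None) -> GlmFit:
    """Per-voxel ordinary least squares.

    ``bold`` has shape (*grid, n_volumes).  Rank-deficient designs are
    handled by dropping dependent columns (QR with pivoting) with a logged
    report; dropped columns get zero beta maps.
    """
    X = design.matrix
    n_vol = X.shape[0]
    if bold.shape[-1] != n_vol:
        raise ValueError("BOLD volume count does not match the design")
    grid = bold.shape[:-1]
    Y = bold.reshape(-1, n_vol).T          # (n_volumes, n_voxels)
    if mask is not None:
        flat_mask = np.asarray(mask, dtype=bool).ravel()
        Y = Y[:, flat_mask]

    keep = list(range(X.shape[1]))
    rank = np.linalg.matrix_rank(X)
    dropped: list[str] = []
    if rank < X.shape[1]:
        _, _, piv = scipy_qr(X, pivoting=True)
        keep = sorted(piv[:rank])
        dropped = [design.labels[j] for j in range(X.shape[1]) if j not in keep]
        logger.warning("rank-deficient design: dropped columns %s", dropped)
        X = X[:, keep]

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n_vol - X.shape[1]
    res_var = (resid**2).sum(axis=0) / max(dof, 1)

    def unflatten(v: np.ndarray) -> np.ndarray:
        if mask is None:
            return v.reshape(grid)
        out = np.zeros(int(np.prod(grid)))
        out[flat_mask] = v
        return out.reshape(grid)

    betas = {}
    kept_labels = [design.labels[j] for j in keep]
    for row, lab in enumerate(kept_labels):
        betas[lab] = unflatten(beta[row])
    for lab in dropped:
        betas[lab] = np.zeros(grid)
    return GlmFit(betas=betas, residual_variance=unflatten(res_var),
                  dof=dof, dropped_columns=dropped)


def compute_contrast(
    betas: dict[str, np.ndarray], contrast: str | dict[str, float]
) -> np.ndarray:
    """Weighted sum of condition beta maps.

    ``contrast`` is a named contrast (see ``NAMED_CONTRASTS``) or an
    explicit {condition: weight} mapping.  Missing conditions raise KeyError.
    """
    weights = NAMED_CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    out = None
    for cond, w in weights.items():
        term = w * betas[cond]
        out = term if out is None else out + term
    return out


def contrast_tmap(
    fit: GlmFit, design: DesignMatrix, contrast: str | dict[str, float]
) -> tuple[np.ndarray, int]:
    """First-level t map for a contrast: c'beta / sqrt(s2 * c'(X'X)^-1 c).

    Returns the t map and its residual degrees of freedom.
    """
    weights = NAMED_CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    X = design.matrix
    kept = [lab for lab in design.labels if lab not in fit.dropped_columns]
    cols = [design.labels.index(lab) for lab in kept]
    Xk = X[:, cols]
    cvec = np.array([weights.get(lab, 0.0) for lab in kept])
    xtx_inv = np.linalg.pinv(Xk.T @ Xk)
    var_scale = float(cvec @ xtx_inv @ cvec)
    estimate = compute_contrast(fit.betas, weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = estimate / np.sqrt(fit.residual_variance * var_scale)
    return np.nan_to_num(t, nan=0.0, posinf=_T_CAP, neginf=-_T_CAP), fit.dof


def session_contrast(run_contrasts: list[np.ndarray]) -> np.ndarray:
    """Fixed-effects combination of a session's runs: the mean contrast map."""
    return np.mean(run_contrasts, axis=0)


_T_CAP = 1e6  # replaces infinite t at zero-variance voxels


def second_level(
    contrast_maps: np.ndarray, mask: np.ndarray | None = None
) -> StatMap:
    """Random-effects group map: one-sample t-test per voxel across subjects.

    ``contrast_maps`` has shape (n_subjects, *grid).  Voxels with zero
    between-subject variance and a nonzero mean produce infinite t; these
    are capped at +/-1e6 and flagged in ``StatMap.degenerate``.
    """
    maps = np.asarray(contrast_maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("second level needs at least 2 subjects")
    grid = maps.shape[1:]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    degenerate = (sd == 0) & (mean != 0)
    t = np.where(degenerate, np.sign(mean) * _T_CAP, t)
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    dof = n - 1
    p = 2 * stats.t.sf(np.abs(t), dof)
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    return StatMap(t=t, p=p, dof=dof, mask=np.asarray(mask, dtype=bool),
                   degenerate=degenerate)


def bonferroni_t_threshold(alpha: float, n_voxels: int, dof: int) -> float:
    """Two-sided Bonferroni voxel-level t threshold across ``n_voxels``."""
    return float(stats.t.isf(alpha / n_voxels / 2, dof))


def permutation_max_t_threshold(
    contrast_maps: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Sign-flip permutation max-t FWE threshold for a one-sample design."""
    maps = np.asarray(contrast_maps, dtype=float)[:, np.asarray(mask, dtype=bool)]
    n = maps.shape[0]
    rng = np.random.default_rng(seed)
    max_ts = np.empty(n_permutations)
    for b in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)[:, None]
        flipped = maps * signs
        mean = flipped.mean(axis=0)
        se = flipped.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean / se)
        max_ts[b] = np.nanmax(t)
    return float(np.quantile(max_ts, 1 - alpha))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def extract_clusters(
    stat: StatMap | np.ndarray,
    threshold: float,
    min_size: int = 10,
    connectivity: int = 6,
    two_sided: bool = True,
    affine: np.ndarray | None = None,
) -> ClusterSet:
    """Supra-threshold connected components of a statistic map.

    Voxels with |t| > threshold (or t > threshold if ``two_sided=False``)
    are grouped into connected components (6-neighborhood by default);
    components smaller than ``min_size`` are dropped.  An empty result logs
    a suggestion to fall back to an uncorrected threshold (the convention
    used when no cluster survives FWE correction).
    """
    t = stat.t if isinstance(stat, StatMap) else np.asarray(stat, dtype=float)
    mask = stat.mask if isinstance(stat, StatMap) else np.ones(t.shape, dtype=bool)
    supra = (np.abs(t) > threshold) if two_sided else (t > threshold)
    supra &= mask
    n_supra = int(supra.sum())

    labeled, n_comp = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    clusters: list[Cluster] = []
    next_id = 1
    for comp in range(1, n_comp + 1):
        vox = np.nonzero(labeled == comp)
        size = len(vox[0])
        if size < min_size:
            continue
        vals = t[vox]
        peak = int(np.argmax(np.abs(vals)))
        peak_index = tuple(int(ax[peak]) for ax in vox)
        peak_mm = None
        if affine is not None:
            hom = np.append(np.asarray(peak_index, dtype=float), 1.0)
            peak_mm = tuple((affine @ hom)[:3])
        clusters.append(
            Cluster(cluster_id=next_id, voxels=vox, size=size,
                    peak_index=peak_index, peak_stat=float(vals[peak]),
                    peak_mm=peak_mm)
        )
        next_id += 1
    clusters.sort(key=lambda c: -abs(c.peak_stat))
    for new_id, c in enumerate(clusters, start=1):
        c.cluster_id = new_id
    if not clusters:
        logger.info(
            "no supra-threshold cluster at t>%.3f; consider an uncorrected "
            "threshold (e.g. p<.001) as a fallback", threshold
        )
    return ClusterSet(clusters=clusters, threshold=threshold,
                      min_size=min_size, n_suprathreshold=n_supra)
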
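"""Synthetic multi-site, multi-session cohorts with known reliability.

The study design being emulated: ~36 healthy participants, each scanned at
3 sessions (weeks 0, 2 and 8) at one of up to 4 sites, performing an
event-related emotional-conflict task (2 runs x 74 trials, TR 2 s, 202
volumes per run, 4 mm isotropic voxels).  The real data are restricted, so
every downstream stage is exercised on simulated cohorts with *known*
variance components.

Three generators are provided:

* :func:`simulate_contrast_cohort` draws per-voxel contrast values directly
  from the two-way model  y = amplitude + site + subject + session + noise,
  giving exact control of the true ICC = s2_b / (s2_b + s2_w) per region;
* :func:`simulate_bold_run` synthesizes a 4-D BOLD run (HRF-convolved
  condition signals + polynomial drift + white noise + optional spikes)
  plus a 6-parameter motion table, to exercise the GLM end of the chain;
* :func:`simulate_behavior` draws trial-wise reaction times and errors with
  a configurable Stroop cost, fear-face slowing, and error rates.

All generators are deterministic given (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from conflicticc import glm as _glm
from conflicticc.task_design import TaskSequence

DEFAULT_GRID = (24, 24, 16)   # desk-scale analog of a 64x64x~36 EPI matrix
DEFAULT_VOXEL_MM = 4.0


@dataclass
class CohortTruth:
    """Ground-truth description of a synthetic contrast-level cohort.

    Attributes
    ----------
    region_labels : int array, 3-D
        Integer-labeled grid (0 = background / out of mask).
    amplitude, sigma2_b, sigma2_w : dict[int, float]
        Per-region mean contrast amplitude, between-subject variance and
        within-subject (session-to-session) variance, in contrast units
        (squared for the variances).
    session_effects : sequence of float
        Additive constants per session (fixed effects; length = n_sessions).
    site_offsets : sequence of float
        Additive constant per site.  Site offsets are subject-constant, so
        they count toward between-subject variance and *raise* the realized
        ICC; zero them for pure recovery tests.
    site_of_subject : int array, optional
        Site index per subject; defaults to a balanced round-robin.
    """

    region_labels: np.ndarray
    amplitude: dict[int, float]
    sigma2_b: dict[int, float]
    sigma2_w: dict[int, float]
    n_subjects: int = 36
    session_effects: tuple[float, ...] = (0.0, 0.0, 0.0)
    site_offsets: tuple[float, ...] = (0.0,)
    site_of_subject: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        self.region_labels = np.asarray(self.region_labels)
        for rid in self.amplitude:
            if self.sigma2_b.get(rid, 0.0) < 0 or self.sigma2_w.get(rid, 0.0) < 0:
                raise ValueError(f"negative variance for region {rid}")
        if self.site_of_subject is None:
            self.site_of_subject = np.arange(self.n_subjects) % len(self.site_offsets)

    @property
    def n_sessions(self) -> int:
        return len(self.session_effects)

    def true_icc(self, region: int) -> float:
        """True ICC = s2_b / (s2_b + s2_w), ignoring site offsets."""
        b, w = self.sigma2_b[region], self.sigma2_w[region]
        return b / (b + w) if (b + w) > 0 else np.nan


@dataclass
class ContrastStack:
    """Subjects x sessions x voxel-grid stack of first-level contrast values."""

    values: np.ndarray            # (n_subjects, n_sessions, *grid)
    mask: np.ndarray              # bool, shape = grid
    truth: CohortTruth | None = None
    provenance: str = "synthetic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape[2:] != self.mask.shape:
            raise ValueError("mask shape does not match value grid")
        in_mask = self.values[..., self.mask]
        if not np.all(np.isfinite(in_mask)):
            raise ValueError("non-finite contrast values inside the mask")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[1]


def two_region_truth(
    n_subjects: int = 36,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    icc_high: float = 0.8,
    icc_low: float = 0.1,
    total_variance: float = 1.0,
    amplitude_high: float = 1.0,
    amplitude_low: float = 1.0,
    region_size: int = 250,
    session_effects: tuple[float, ...] = (0.0, 0.0, 0.0),
    site_offsets: tuple[float, ...] = (0.0,),
    seed: int = 0,
) -> CohortTruth:
    """Truth with a high-reliability posterior ("visual-like", label 1) blob
    and a low-reliability anterior ("frontal-like", label 2) blob.

    Variances are chosen so s2_b + s2_w = ``total_variance`` and
    s2_b/(s2_b+s2_w) equals the requested ICC per region.  The two cuboid
    regions are placed at opposite ends of the y-axis of the grid.
    """
    labels = np.zeros(grid, dtype=int)
    nx, ny, nz = grid
    side = max(2, round(region_size ** (1 / 3)))
    x0 = nx // 2 - side // 2
    z0 = nz // 2 - side // 2
    labels[x0:x0 + side, 1:1 + side, z0:z0 + side] = 1          # posterior
    labels[x0:x0 + side, ny - 1 - side:ny - 1, z0:z0 + side] = 2  # anterior
    return CohortTruth(
        region_labels=labels,
        amplitude={1: amplitude_high, 2: amplitude_low},
        sigma2_b={1: icc_high * total_variance, 2: icc_low * total_variance},
        sigma2_w={1: (1 - icc_high) * total_variance,
                  2: (1 - icc_low) * total_variance},
        n_subjects=n_subjects,
        session_effects=session_effects,
        site_offsets=site_offsets,
        seed=seed,
    )


def simulate_contrast_cohort(truth: CohortTruth) -> ContrastStack:
    """Draw a contrast-level cohort from the two-way variance model.

    For voxel v in region r, subject i, session t:

        y[i, t, v] = amplitude_r + site_offset[site(i)] + s_ir + d_t + e_itv

    with s_ir ~ N(0, s2_b[r]) drawn once per subject x region and
    e ~ N(0, s2_w[r]) independent per subject, session and voxel.
    Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n, k = truth.n_subjects, truth.n_sessions
    grid = truth.region_labels.shape
    values = np.zeros((n, k) + grid, dtype=float)
    mask = truth.region_labels > 0

    site_term = np.asarray(truth.site_offsets)[truth.site_of_subject]  # (n,)
    d = np.asarray(truth.session_effects)                              # (k,)

    for rid, amp in truth.amplitude.items():
        vox = truth.region_labels == rid
        nv = int(vox.sum())
        if nv == 0:
            continue
        s_i = rng.normal(0.0, np.sqrt(truth.sigma2_b[rid]), size=n)
        eps = rng.normal(0.0, np.sqrt(truth.sigma2_w[rid]), size=(n, k, nv))
        region_vals = (
            amp
            + site_term[:, None, None]
            + s_i[:, None, None]
            + d[None, :, None]
            + eps
        )
        values[:, :, vox] = region_vals
    return ContrastStack(values=values, mask=mask, truth=truth)


# ---------------------------------------------------------------------------
# BOLD-level simulation
# ---------------------------------------------------------------------------


@dataclass
class BoldNoise:
    """Noise model for a simulated BOLD run."""

    sigma: float = 1.0                       # white-noise SD, signal units
    drift_linear: float = 0.0                # linear drift amplitude
    drift_quadratic: float = 0.0             # quadratic drift amplitude
    spike_volumes: tuple[int, ...] = ()      # volumes with injected artifacts
    spike_amplitude: float = 8.0             # artifact size, signal units
    motion_step_sd: float = 0.02             # random-walk step SD, mm
    motion_spike_mm: float = 2.0             # displacement at spike volumes


def simulate_bold_run(
    seq: TaskSequence,
    amplitudes: dict[str, np.ndarray],
    noise: BoldNoise | None = None,
    tr: float = 2.0,
    n_volumes: int = 202,
    run_index: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one 4-D BOLD run plus a motion-parameter table.

    Parameters
    ----------
    seq : TaskSequence
        Task timing; only ``run_index`` is used.
    amplitudes : dict
        Condition name (as understood by the GLM design builder, e.g.
        ``'congruent'``, ``'incongruent'``) -> 3-D amplitude map (signal
        change per voxel).  All maps must share one grid shape.
    noise : BoldNoise
        White noise, polynomial drift and spike artifacts; None = noiseless.
    tr, n_volumes : float, int
        Acquisition pacing; the task must fit within ``n_volumes * tr``.

    Returns
    -------
    (bold, motion) : 4-D array (*grid, n_volumes) and (n_volumes, 6) array
        Motion columns are 3 translations (mm) then 3 rotations (degrees),
        smooth random walks with displacement injected at spike volumes.
    """
    noise = noise or BoldNoise(sigma=0.0)
    rng = np.random.default_rng(seed)
    trials = seq.run(run_index)
    if trials:
        end = max(t.onset + t.duration for t in trials)
        if end > n_volumes * tr:
            raise ValueError(
                f"task ends at {end:.1f}s but run lasts {n_volumes * tr:.1f}s"
            )

    grids = {np.asarray(a).shape for a in amplitudes.values()}
    if len(grids) > 1:
        raise ValueError("amplitude maps have inconsistent shapes")
    grid = grids.pop() if grids else DEFAULT_GRID

    frame_times = np.arange(n_volumes) * tr
    bold = np.zeros(grid + (n_volumes,), dtype=float)
    for cond, amp_map in amplitudes.items():
        reg = _glm.condition_regressor(trials, cond, frame_times)
        bold += np.asarray(amp_map, dtype=float)[..., None] * reg[None, None, None, :]

    t = np.linspace(-1, 1, n_volumes)
    drift = noise.drift_linear * t + noise.drift_quadratic * (1.5 * t**2 - 0.5)
    bold += drift

    if noise.sigma > 0:
        bold += rng.normal(0.0, noise.sigma, size=bold.shape)
    for v in noise.spike_volumes:
        bold[..., v] += noise.spike_amplitude

    motion = np.cumsum(rng.normal(0.0, noise.motion_step_sd, size=(n_volumes, 6)),
                       axis=0)
    for v in noise.spike_volumes:
        motion[v, :3] += noise.motion_spike_mm
    return bold, motion


# ---------------------------------------------------------------------------
# behavioral simulation
# ---------------------------------------------------------------------------


@dataclass
class BehaviorParams:
    """Trial-wise response model for the emotional-conflict task.

    RT (ms) for subject i, session t, trial j:

        rt = exp(N(mu_i + session_shift[t], sigma_rt)) + delta_stroop * [incongruent]
                                                       + delta_fear * [fear face]

    mu_i ~ N(log(base_rt_ms), sigma_subject) once per subject (the stable
    individual trait that carries test-retest reliability), plus an
    independent session-level wobble N(0, sigma_session) that acts as
    within-subject variance.  Errors are Bernoulli per trial: commission
    with a higher rate on incongruent trials, omission at a flat rate.

    Defaults give median congruent RT near 670 ms and incongruent near
    725 ms (a ~55-60 ms Stroop cost) with accuracies around 0.95-0.98,
    matching the healthy-control ranges the task is designed around, and a
    between/within split giving behavioral ICCs in the 0.6-0.7 range.
    """

    base_rt_ms: float = 650.0
    # between/within split chosen so the session-to-session reliability of a
    # subject's median RT is ~0.65: 0.10^2 / (0.10^2 + 0.073^2) = 0.65
    sigma_subject: float = 0.10    # between-subject SD of log base RT
    sigma_session: float = 0.073   # within-subject session wobble (log units)
    sigma_rt: float = 0.20         # trial-to-trial SD (log units)
    delta_stroop_ms: float = 60.0  # incongruent - congruent cost
    delta_fear_ms: float = 25.0    # fear-face slowing
    session_shift_ms: tuple[float, ...] = (0.0, 0.0, 0.0)
    commission_rate_congruent: float = 0.02
    commission_rate_incongruent: float = 0.05
    omission_rate: float = 0.01


def simulate_behavior(
    sequences: dict[int, TaskSequence] | TaskSequence,
    n_subjects: int = 36,
    n_sessions: int = 3,
    params: BehaviorParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate trial-wise responses for a cohort.

    Parameters
    ----------
    sequences : TaskSequence or dict session -> TaskSequence
        Task timing; a single sequence is reused for every session
        (mirroring the fixed run order of the protocol).

    Returns
    -------
    DataFrame with one row per subject x session x trial: columns subject,
    session, run, trial, congruent, face_emotion, adaptation_label,
    response, rt_ms, correct, commission_error, omission_error.
    """
    params = params or BehaviorParams()
    rng = np.random.default_rng(seed)
    if isinstance(sequences, TaskSequence):
        sequences = {s: sequences for s in range(1, n_sessions + 1)}

    mu = np.log(params.base_rt_ms) + rng.normal(0, params.sigma_subject, n_subjects)
    rows = []
    for i in range(1, n_subjects + 1):
        for t in range(1, n_sessions + 1):
            seq = sequences[t]
            session_mu = (
                mu[i - 1]
                + rng.normal(0, params.sigma_session)
                + np.log1p(params.session_shift_ms[t - 1] / params.base_rt_ms)
            )
            for trial in seq.trials:
                commission_rate = (
                    params.commission_rate_incongruent
                    if not trial.congruent
                    else params.commission_rate_congruent
                )
                omitted = rng.random() < params.omission_rate
                commission = (not omitted) and rng.random() < commission_rate
                if omitted:
                    response, rt, correct = "none", np.nan, False
                else:
                    rt = float(
                        np.exp(rng.normal(session_mu, params.sigma_rt))
                        + params.delta_stroop_ms * (not trial.congruent)
                        + params.delta_fear_ms * (trial.face_emotion == "fear")
                    )
                    correct = not commission
                    response = (
                        trial.face_emotion
                        if correct
                        else ("fear" if trial.face_emotion == "happy" else "happy")
                    )
                rows.append(
                    {
                        "subject": i,
                        "session": t,
                        "run": trial.run_index,
                        "trial": trial.trial_index,
                        "congruent": trial.congruent,
                        "face_emotion": trial.face_emotion,
                        "adaptation_label": trial.adaptation_label,
                        "response": response,
                        "rt_ms": rt,
                        "correct": correct,
                        "commission_error": commission,
                        "omission_error": omitted,
                    }
                )
    return pd.DataFrame(rows)
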
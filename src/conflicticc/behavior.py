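"""Behavioral QC, trial filtering, Stroop statistics and behavioral ICCs.

Trial-wise responses are handled as pandas DataFrames with one row per
trial (columns: subject, session, run, trial, congruent, face_emotion,
adaptation_label, response, rt_ms, correct, commission_error,
omission_error — the layout produced by
:func:`conflicticc.synthetic.simulate_behavior`).

Quality control: a run fails when its commission-error rate exceeds 25% or
its total error rate (commission + omission) exceeds 30%; subjects with any
failing run are flagged for exclusion.

Reaction-time filtering removes (1) error trials, (2) the trial immediately
following an error (within the same run only — runs are separated by
rest), and (3) trials whose RT lies more than 2 SD from the mean of that
subject x session x trial-type cell, with mean and SD computed over
correct, non-post-error trials.  Accuracy analyses keep RT outliers and
post-error trials.

Group statistics follow the nonparametric route: a Shapiro-Wilk normality
gate, related-samples Wilcoxon signed-rank tests for paired comparisons
(Pratt handling of zero differences; a sign test is substituted when more
than 25% of paired differences are zero), Friedman tests across the three
sessions, and a Bonferroni-adjusted alpha of 0.0125.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from conflicticc import reliability

COMMISSION_THRESHOLD = 0.25
TOTAL_ERROR_THRESHOLD = 0.30
RT_SD_WINDOW = 2.0
BONFERRONI_ALPHA = 0.0125

_REQUIRED = [
    "subject", "session", "run", "trial", "congruent", "face_emotion",
    "rt_ms", "correct", "commission_error", "omission_error",
]


@dataclass(frozen=True)
class TrialResponse:
    """A single trial's response record."""

    run_index: int
    trial_index: int
    response: str                 # 'happy' | 'fear' | 'none'
    rt_ms: float | None
    correct: bool
    commission_error: bool
    omission_error: bool

    def __post_init__(self):
        if self.correct and self.response == "none":
            raise ValueError("correct trials must carry a response")
        if self.commission_error and self.omission_error:
            raise ValueError("commission and omission errors are exclusive")
        if (self.rt_ms is not None) != (self.response != "none"):
            raise ValueError("RT must be present iff a response was made")


@dataclass(frozen=True)
class RunQC:
    """Per-run error-rate quality control."""

    subject: int
    session: int
    run: int
    n_trials: int
    commission_rate: float
    total_error_rate: float

    @property
    def passed(self) -> bool:
        return (
            self.commission_rate <= COMMISSION_THRESHOLD
            and self.total_error_rate <= TOTAL_ERROR_THRESHOLD
        )


def _check_frame(df: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"response table is missing columns {missing}")


def qc_runs(responses: pd.DataFrame) -> pd.DataFrame:
    """Run-level QC table with per-run error rates and pass flags.

    Returns one row per subject x session x run with columns
    commission_rate, total_error_rate, passed, plus a subject-level
    ``subject_excluded`` flag (any failing run excludes the subject).
    """
    _check_frame(responses)
    rows = []
    for (subj, sess, run), g in responses.groupby(["subject", "session", "run"]):
        n = len(g)
        commission = g["commission_error"].sum() / n
        total = (g["commission_error"].sum() + g["omission_error"].sum()) / n
        qc = RunQC(subj, sess, run, n, commission, total)
        rows.append(
            {
                "subject": subj, "session": sess, "run": run, "n_trials": n,
                "commission_rate": commission, "total_error_rate": total,
                "passed": qc.passed,
            }
        )
    out = pd.DataFrame(rows)
    failing = set(out.loc[~out["passed"], "subject"])
    out["subject_excluded"] = out["subject"].isin(failing)
    return out


def filter_rt_trials(
    responses: pd.DataFrame,
    sd_window: float = RT_SD_WINDOW,
    trial_type_cols: tuple[str, ...] = ("congruent", "face_emotion"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the RT trial-exclusion rules.

    Removes error trials, post-error trials (same run only) and RT outliers
    beyond ``sd_window`` SDs of the subject x session x trial-type mean
    (mean and SD over correct, non-post-error trials).

    Returns
    -------
    (retained, removal_counts)
        ``retained`` is the surviving subset of ``responses``;
        ``removal_counts`` has keys 'error', 'post_error', 'rt_outlier'
        (each trial is counted once, under the first rule that removes it).
    """
    _check_frame(responses)
    for col in trial_type_cols:
        if col not in responses.columns:
            raise ValueError(f"trial-type coding column {col!r} missing")
    df = responses.sort_values(["subject", "session", "run", "trial"]).copy()

    is_error = ~df["correct"]
    prev_error = (
        is_error.groupby(
            [df["subject"], df["session"], df["run"]]
        ).shift(1, fill_value=False)
    )
    post_error = prev_error & ~is_error

    base = ~is_error & ~post_error          # trials defining the RT window
    group_cols = ["subject", "session", *trial_type_cols]
    # the outlier pass is iterated to a fixed point (each pass recomputes
    # the mean/SD over surviving trials), which makes the filter idempotent
    outlier = pd.Series(False, index=df.index)
    while True:
        eligible = base & ~outlier
        stats_base = df[eligible].groupby(group_cols)["rt_ms"]
        mean = stats_base.transform("mean").reindex(df.index)
        sd = stats_base.transform("std").reindex(df.index)
        lo = mean - sd_window * sd
        hi = mean + sd_window * sd
        valid = eligible & sd.notna() & (sd > 0)
        new = valid & ((df["rt_ms"] < lo) | (df["rt_ms"] > hi))
        if not new.any():
            break
        outlier |= new

    counts = {
        "error": int(is_error.sum()),
        "post_error": int(post_error.sum()),
        "rt_outlier": int((outlier & ~is_error & ~post_error).sum()),
    }
    retained = df[~is_error & ~post_error & ~outlier]
    return retained, counts


def compute_accuracy(
    responses: pd.DataFrame,
    by: tuple[str, ...] = ("congruent",),
) -> pd.DataFrame:
    """Proportion correct per trial type, over *all* trials.

    RT outliers and post-error trials are deliberately included; omissions
    count as incorrect.
    """
    _check_frame(responses)
    out = (
        responses.groupby(["subject", "session", *by])["correct"]
        .agg(accuracy="mean", n_trials="size")
        .reset_index()
    )
    return out


def summarize(
    responses: pd.DataFrame,
    sd_window: float = RT_SD_WINDOW,
) -> pd.DataFrame:
    """Per subject x session summary of median RT and accuracy.

    Median RTs use the filtered trial set; accuracies use all trials.
    Columns: rt_congruent, rt_incongruent, rt_happy, rt_fear, rt_iI, rt_cI,
    acc_congruent, acc_incongruent, acc_happy, acc_fear, n_retained.
    """
    retained, _ = filter_rt_trials(responses, sd_window=sd_window)
    rows = []
    for (subj, sess), g_all in responses.groupby(["subject", "session"]):
        g = retained[(retained["subject"] == subj) & (retained["session"] == sess)]
        row = {"subject": subj, "session": sess, "n_retained": len(g)}
        row["rt_congruent"] = g.loc[g["congruent"], "rt_ms"].median()
        row["rt_incongruent"] = g.loc[~g["congruent"], "rt_ms"].median()
        row["rt_happy"] = g.loc[g["face_emotion"] == "happy", "rt_ms"].median()
        row["rt_fear"] = g.loc[g["face_emotion"] == "fear", "rt_ms"].median()
        if "adaptation_label" in g:
            row["rt_iI"] = g.loc[g["adaptation_label"] == "iI", "rt_ms"].median()
            row["rt_cI"] = g.loc[g["adaptation_label"] == "cI", "rt_ms"].median()
        row["acc_congruent"] = g_all.loc[g_all["congruent"], "correct"].mean()
        row["acc_incongruent"] = g_all.loc[~g_all["congruent"], "correct"].mean()
        row["acc_happy"] = g_all.loc[
            g_all["face_emotion"] == "happy", "correct"].mean()
        row["acc_fear"] = g_all.loc[
            g_all["face_emotion"] == "fear", "correct"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def _paired_test(a: np.ndarray, b: np.ndarray, zero_frac_trigger: float = 0.25):
    """Wilcoxon signed-rank z and p; sign test when zero diffs dominate."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    diff = diff[np.isfinite(diff)]
    if len(diff) < 2:
        raise ValueError("need at least 2 complete pairs")
    zero_frac = np.mean(diff == 0)
    if np.all(diff == 0):
        return {"test": "wilcoxon", "z": 0.0, "p": 1.0, "n": len(diff)}
    if zero_frac > zero_frac_trigger:
        from statsmodels.stats.descriptivestats import sign_test

        stat, p = sign_test(diff, 0)
        return {"test": "sign", "z": float(stat), "p": float(p), "n": len(diff)}
    res = stats.wilcoxon(diff, zero_method="pratt", method="approx")
    return {
        "test": "wilcoxon",
        "z": float(res.zstatistic),
        "p": float(res.pvalue),
        "n": len(diff),
    }


def stroop_stats(summary: pd.DataFrame) -> pd.DataFrame:
    """Nonparametric Stroop test table from a per-subject-session summary.

    For each session: paired tests of incongruent vs congruent (RT and
    accuracy) and fear vs happy (RT and accuracy); plus one Friedman test
    per measure across the three sessions, and a Shapiro-Wilk normality
    check recorded per comparison (the gate that justifies the
    nonparametric route).  The Bonferroni-adjusted alpha (0.0125) is
    reported alongside each p-value.
    """
    if summary["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects with complete pairs")
    pairs = [
        ("rt_stroop", "rt_incongruent", "rt_congruent"),
        ("rt_emotion", "rt_fear", "rt_happy"),
        ("acc_stroop", "acc_incongruent", "acc_congruent"),
        ("acc_emotion", "acc_fear", "acc_happy"),
    ]
    rows = []
    for sess, g in summary.groupby("session"):
        for name, col_a, col_b in pairs:
            a, b = g[col_a].to_numpy(), g[col_b].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            res = _paired_test(a[ok], b[ok])
            with np.errstate(all="ignore"):
                diff = a[ok] - b[ok]
                sw_p = (
                    float(stats.shapiro(diff).pvalue)
                    if len(diff) >= 3 and np.ptp(diff) > 0
                    else np.nan
                )
            rows.append(
                {
                    "session": sess,
                    "measure": name,
                    "effect": float(np.median(diff)),
                    "test": res["test"],
                    "z": res["z"],
                    "p": res["p"],
                    "n": res["n"],
                    "shapiro_p": sw_p,
                    "alpha_bonferroni": BONFERRONI_ALPHA,
                    "significant": res["p"] < BONFERRONI_ALPHA,
                }
            )
    # Friedman across the three sessions, per measure
    wide = summary.pivot(index="subject", columns="session")
    for measure in ["rt_congruent", "rt_incongruent", "acc_congruent",
                    "acc_incongruent"]:
        block = wide[measure].dropna()
        if block.shape[1] >= 3 and len(block) >= 3:
            fr = stats.friedmanchisquare(*[block[c] for c in block.columns])
            rows.append(
                {
                    "session": 0,
                    "measure": f"friedman_{measure}",
                    "effect": np.nan,
                    "test": "friedman",
                    "z": float(fr.statistic),
                    "p": float(fr.pvalue),
                    "n": len(block),
                    "shapiro_p": np.nan,
                    "alpha_bonferroni": BONFERRONI_ALPHA,
                    "significant": fr.pvalue < BONFERRONI_ALPHA,
                }
            )
    return pd.DataFrame(rows)


#: measures reported in the behavioral reliability table
ICC_MEASURES = {
    "rt_congruent": ("rt_congruent", None),
    "rt_incongruent": ("rt_incongruent", None),
    "rt_happy": ("rt_happy", None),
    "rt_fear": ("rt_fear", None),
    "acc_congruent": ("acc_congruent", None),
    "acc_incongruent": ("acc_incongruent", None),
    "acc_happy": ("acc_happy", None),
    "acc_fear": ("acc_fear", None),
    "rt_incongruent-congruent": ("rt_incongruent", "rt_congruent"),
    "rt_fear-happy": ("rt_fear", "rt_happy"),
    "rt_iI-cI": ("rt_iI", "rt_cI"),
    "acc_incongruent-congruent": ("acc_incongruent", "acc_congruent"),
}


def measure_matrix(summary: pd.DataFrame, measure: str) -> np.ndarray:
    """Subjects x sessions matrix for one (possibly contrast) measure."""
    col, minus = ICC_MEASURES[measure]
    wide = summary.pivot(index="subject", columns="session", values=col)
    if minus is not None:
        wide = wide - summary.pivot(index="subject", columns="session",
                                    values=minus)
    return wide.to_numpy(dtype=float)


def behavioral_icc(
    summary: pd.DataFrame,
    measures: list[str] | None = None,
    scheme: str = "four_band",
) -> pd.DataFrame:
    """Test-retest reliability table for the behavioral measures.

    One row per measure with ICC(3,1), its 95% CI and a class label,
    covering the per-condition medians/accuracies and the contrast
    measures (incongruent-congruent, fear-happy, iI-cI).
    """
    rows = []
    for measure in measures or list(ICC_MEASURES):
        if ICC_MEASURES[measure][0] not in summary.columns:
            continue
        Y = measure_matrix(summary, measure)
        res = reliability.icc31(Y, scheme=scheme)
        rows.append(
            {
                "measure": measure,
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n": res.n,
                "k": res.k,
                "class": res.class_label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exclusion-cascade bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class ExclusionCounts:
    """Participant exclusion bookkeeping for a multi-site reliability study.

    Defaults reflect the study design being emulated: of 59 recruited
    healthy controls, scans were excluded for excessive motion (4),
    incomplete sequences (1) or data-quality problems such as ghosting (6);
    5 more were missing a session or withdrew.  Of the remainder, 4 had
    unusable behavioral data and 2 fell below the accuracy threshold; the
    last exclusion removes a participant left alone at their site.
    """

    recruited: int = 59
    excessive_motion: int = 4
    incomplete_scan: int = 1
    data_quality: int = 6
    missing_session_or_withdrew: int = 5
    behavioral_unusable: int = 4
    below_accuracy_threshold: int = 2
    lone_site_participant: int = 1


def exclusion_cascade(counts: ExclusionCounts | None = None) -> pd.DataFrame:
    """Stage-by-stage exclusion table ending at the analyzed sample size.

    Returns a DataFrame with one row per stage (stage, removed, remaining);
    the final ``remaining`` is the analyzed n (36 with the defaults).
    """
    c = counts or ExclusionCounts()
    stages = [
        ("recruited", 0),
        ("excessive_motion", c.excessive_motion),
        ("incomplete_scan", c.incomplete_scan),
        ("data_quality", c.data_quality),
        ("missing_session_or_withdrew", c.missing_session_or_withdrew),
        ("behavioral_unusable", c.behavioral_unusable),
        ("below_accuracy_threshold", c.below_accuracy_threshold),
        ("lone_site_participant", c.lone_site_participant),
    ]
    remaining = c.recruited
    rows = []
    for stage, removed in stages:
        remaining -= removed
        rows.append({"stage": stage, "removed": removed, "remaining": remaining})
    return pd.DataFrame(rows)


def analyzed_n(counts: ExclusionCounts | None = None) -> int:
    """Final analyzed sample size after the exclusion cascade."""
    return int(exclusion_cascade(counts)["remaining"].iloc[-1])
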
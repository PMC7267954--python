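import numpy as np
import pandas as pd
import pytest

from conflicticc import task_design as td


def bruteforce_two_way_anova(Y):
    """Explicit-loop two-way (subjects x sessions) ANOVA mean squares.

    Independent oracle for the vectorized implementation: everything is
    computed with plain Python loops and running sums.
    """
    Y = [list(map(float, row)) for row in Y]
    n, k = len(Y), len(Y[0])
    total = sum(sum(row) for row in Y)
    grand = total / (n * k)
    ss_subj = 0.0
    for i in range(n):
        mean_i = sum(Y[i]) / k
        ss_subj += k * (mean_i - grand) ** 2
    ss_sess = 0.0
    for t in range(k):
        mean_t = sum(Y[i][t] for i in range(n)) / n
        ss_sess += n * (mean_t - grand) ** 2
    ss_total = 0.0
    for i in range(n):
        for t in range(k):
            ss_total += (Y[i][t] - grand) ** 2
    ss_resid = ss_total - ss_subj - ss_sess
    bms = ss_subj / (n - 1)
    jms = ss_sess / (k - 1)
    ems = ss_resid / ((n - 1) * (k - 1))
    return bms, jms, ems


def bruteforce_icc31(Y):
    """ICC(3,1) from the brute-force mean squares."""
    bms, _, ems = bruteforce_two_way_anova(Y)
    k = len(Y[0])
    denom = bms + (k - 1) * ems
    return (bms - ems) / denom if denom > 0 else float("nan")


@pytest.fixture(scope="session")
def anova_oracle():
    return bruteforce_two_way_anova


@pytest.fixture(scope="session")
def icc_oracle():
    return bruteforce_icc31


@pytest.fixture(scope="session")
def short_sequence():
    """A 2-run, 20-trials-per-run sequence for fast GLM tests."""
    return td.generate_sequence(2, 20, (3.0, 5.0), seed=11)


@pytest.fixture(scope="session")
def standard_sequence():
    """The protocol-scale sequence: 2 runs x 74 trials."""
    return td.generate_sequence(2, 74, (3.0, 5.0), seed=7)


def make_response_frame(rows):
    """Build a response table from compact tuples.

    Each row: (subject, session, run, trial, congruent, emotion, rt_ms,
    correct) — rt_ms None means omission; correct False with an RT means a
    commission error.
    """
    records = []
    for subj, sess, run, trial, cong, emo, rt, correct in rows:
        omitted = rt is None
        records.append(
            {
                "subject": subj,
                "session": sess,
                "run": run,
                "trial": trial,
                "congruent": cong,
                "face_emotion": emo,
                "adaptation_label": "cC",
                "response": "none" if omitted else ("happy" if correct else "fear"),
                "rt_ms": np.nan if omitted else float(rt),
                "correct": bool(correct) and not omitted,
                "commission_error": (not correct) and not omitted,
                "omission_error": omitted,
            }
        )
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def response_builder():
    return make_response_frame
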
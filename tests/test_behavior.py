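"""Behavioral QC, trial filtering, Stroop statistics and exclusion logic."""

import numpy as np
import pytest

from conflicticc import behavior as beh
from conflicticc import synthetic as syn
from conflicticc import task_design as td


def _run_rows(n_trials, n_commission=0, n_omission=0, subject=1, session=1, run=1):
    rows = []
    for i in range(1, n_trials + 1):
        if i <= n_commission:
            rows.append((subject, session, run, i, True, "happy", 600.0, False))
        elif i <= n_commission + n_omission:
            rows.append((subject, session, run, i, True, "happy", None, False))
        else:
            rows.append((subject, session, run, i, True, "happy", 600.0, True))
    return rows


class TestQcRuns:
    def test_commission_over_25_percent_fails(self, response_builder):
        df = response_builder(_run_rows(74, n_commission=19))
        qc = beh.qc_runs(df)
        assert qc.loc[0, "commission_rate"] == pytest.approx(19 / 74)
        assert not qc.loc[0, "passed"]

    def test_rates_just_under_thresholds_pass(self, response_builder):
        df = response_builder(_run_rows(74, n_commission=18, n_omission=4))
        qc = beh.qc_runs(df)
        assert qc.loc[0, "commission_rate"] == pytest.approx(18 / 74)
        assert qc.loc[0, "total_error_rate"] == pytest.approx(22 / 74)
        assert qc.loc[0, "passed"]

    def test_error_free_run_passes(self, response_builder):
        qc = beh.qc_runs(response_builder(_run_rows(74)))
        assert qc.loc[0, "passed"]

    def test_any_failing_run_excludes_subject(self, response_builder):
        rows = _run_rows(10, run=1) + _run_rows(10, n_commission=5, run=2)
        qc = beh.qc_runs(response_builder(rows))
        assert qc["subject_excluded"].all()


class TestFilterRtTrials:
    def test_two_sd_outlier_removed(self, response_builder):
        # hand-checkable case: nine 600 ms trials and one 2000 ms trial;
        # the brute-force mean/SD place only 2000 ms outside +/- 2 SD
        rts = [600.0] * 9 + [2000.0]
        rows = [(1, 1, 1, i + 1, True, "happy", rt, True)
                for i, rt in enumerate(rts)]
        mean, sd = np.mean(rts), np.std(rts, ddof=1)
        outliers = [rt for rt in rts if abs(rt - mean) > 2 * sd]
        assert outliers == [2000.0]
        retained, counts = beh.filter_rt_trials(response_builder(rows))
        assert len(retained) == 9
        assert counts == {"error": 0, "post_error": 0, "rt_outlier": 1}
        assert 2000.0 not in retained["rt_ms"].values

    def test_error_and_post_error_removed(self, response_builder):
        rows = [(1, 1, 1, i, True, "happy", 600.0, i != 3) for i in range(1, 7)]
        retained, counts = beh.filter_rt_trials(response_builder(rows))
        assert counts["error"] == 1
        assert counts["post_error"] == 1
        assert set(retained["trial"]) == {1, 2, 5, 6}

    def test_post_error_rule_stops_at_run_boundary(self, response_builder):
        rows = [
            (1, 1, 1, 1, True, "happy", 600.0, True),
            (1, 1, 1, 2, True, "happy", 600.0, False),   # error, last of run 1
            (1, 1, 2, 1, True, "happy", 600.0, True),    # first of run 2
            (1, 1, 2, 2, True, "happy", 610.0, True),
        ]
        retained, counts = beh.filter_rt_trials(response_builder(rows))
        assert counts["post_error"] == 0
        assert (retained["run"] == 2).sum() == 2

    def test_removal_counts_match_hand_enumeration(self, response_builder):
        # mixed case: 1 error at trial 3 (removes 3 and 4), one extreme RT
        rts = [600, 605, 595, 600, 598, 602, 601, 599, 600, 2500]
        rows = [(1, 1, 1, i + 1, True, "happy", rt, i != 2)
                for i, rt in enumerate(rts)]
        retained, counts = beh.filter_rt_trials(response_builder(rows))
        assert counts == {"error": 1, "post_error": 1, "rt_outlier": 1}
        assert len(retained) == 7

    def test_filter_is_idempotent_on_cohort_data(self, standard_sequence):
        responses = syn.simulate_behavior(standard_sequence, n_subjects=4, seed=17)
        once, _ = beh.filter_rt_trials(responses)
        twice, counts = beh.filter_rt_trials(once)
        assert counts == {"error": 0, "post_error": 0, "rt_outlier": 0}
        assert len(twice) == len(once)


class TestComputeAccuracy:
    def test_simple_proportion(self, response_builder):
        df = response_builder(_run_rows(74, n_commission=4))
        acc = beh.compute_accuracy(df)
        assert acc.loc[0, "accuracy"] == pytest.approx(70 / 74)

    def test_all_omissions_zero_accuracy(self, response_builder):
        df = response_builder(_run_rows(5, n_omission=5))
        acc = beh.compute_accuracy(df)
        assert acc.loc[0, "accuracy"] == 0.0

    def test_outliers_and_post_error_trials_included(self, response_builder):
        # the RT filter would drop the 2000 ms trial; accuracy must not
        rts = [600.0] * 9 + [2000.0]
        rows = [(1, 1, 1, i + 1, True, "happy", rt, True)
                for i, rt in enumerate(rts)]
        rows.append((1, 1, 1, 11, True, "happy", 600.0, False))
        acc = beh.compute_accuracy(response_builder(rows))
        assert acc.loc[0, "n_trials"] == 11
        assert acc.loc[0, "accuracy"] == pytest.approx(10 / 11)


@pytest.fixture(scope="module")
def cohort_summary():
    seq = td.generate_sequence(2, 74, (3, 5), seed=7)
    responses = syn.simulate_behavior(seq, n_subjects=20, seed=5)
    return beh.summarize(responses)


class TestStroopStats:
    def test_stroop_effect_detected(self, cohort_summary):
        table = beh.stroop_stats(cohort_summary)
        rt_rows = table[(table["measure"] == "rt_stroop") & (table["session"] > 0)]
        assert len(rt_rows) == 3
        assert (rt_rows["p"] < 0.0125).all()
        # the effect is the incongruent-minus-congruent median difference
        assert (rt_rows["effect"] > 30).all()

    def test_zero_effect_gives_p_one(self):
        import pandas as pd

        summary = pd.DataFrame(
            {
                "subject": np.arange(10),
                "session": 1,
                "rt_congruent": np.linspace(600, 700, 10),
                "rt_incongruent": np.linspace(600, 700, 10),
                "rt_happy": np.linspace(600, 700, 10),
                "rt_fear": np.linspace(610, 710, 10),
                "acc_congruent": 0.95,
                "acc_incongruent": 0.95,
                "acc_happy": 0.95,
                "acc_fear": 0.95,
            }
        )
        table = beh.stroop_stats(summary)
        row = table[table["measure"] == "rt_stroop"].iloc[0]
        assert row["z"] == 0.0
        assert row["p"] == 1.0

    def test_constant_rt_shift_invariance(self, cohort_summary):
        shifted = cohort_summary.copy()
        for col in ["rt_congruent", "rt_incongruent", "rt_happy", "rt_fear"]:
            shifted[col] = shifted[col] + 250.0
        a = beh.stroop_stats(cohort_summary)
        b = beh.stroop_stats(shifted)
        rt = a["measure"].str.startswith("rt")
        assert np.allclose(a.loc[rt, "z"], b.loc[rt, "z"], equal_nan=True)

    def test_insufficient_pairs_rejected(self):
        import pandas as pd

        summary = pd.DataFrame({"subject": [1], "session": [1]})
        with pytest.raises(ValueError):
            beh.stroop_stats(summary)


class TestBehavioralIcc:
    def test_perfect_repeats_give_icc_one(self):
        import pandas as pd

        rows = []
        for subj in range(1, 9):
            for sess in range(1, 4):
                rows.append(
                    {
                        "subject": subj, "session": sess,
                        "rt_congruent": 600.0 + 10 * subj,
                        "rt_incongruent": 660.0 + 10 * subj,
                        "rt_happy": 600.0 + 10 * subj,
                        "rt_fear": 620.0 + 10 * subj,
                        "acc_congruent": 0.9, "acc_incongruent": 0.9,
                        "acc_happy": 0.9, "acc_fear": 0.9,
                    }
                )
        table = beh.behavioral_icc(pd.DataFrame(rows),
                                   measures=["rt_congruent", "rt_incongruent"])
        assert np.allclose(table["icc"], 1.0)

    def test_congruent_rt_recovery_at_known_reliability(self, standard_sequence):
        # generator default: between/within split implies ~0.65 reliability
        # of the per-session median RT
        responses = syn.simulate_behavior(standard_sequence, n_subjects=36, seed=3)
        summary = beh.summarize(responses)
        table = beh.behavioral_icc(summary, measures=["rt_congruent"])
        assert table.loc[0, "icc"] == pytest.approx(0.65, abs=0.15)

    def test_contrast_icc_not_above_condition_iccs(self, standard_sequence):
        # differencing two highly correlated conditions strips the shared
        # stable variance, so the contrast cannot be more reliable
        responses = syn.simulate_behavior(standard_sequence, n_subjects=36, seed=8)
        summary = beh.summarize(responses)
        table = beh.behavioral_icc(
            summary,
            measures=["rt_congruent", "rt_incongruent", "rt_incongruent-congruent"],
        ).set_index("measure")
        contrast = table.loc["rt_incongruent-congruent", "icc"]
        conditions = table.loc[["rt_congruent", "rt_incongruent"], "icc"].min()
        assert contrast <= conditions + 0.05


class TestExclusionCascade:
    def test_analyzed_n_from_printed_counts(self):
        table = beh.exclusion_cascade()
        assert table["remaining"].iloc[0] == 59
        # usable imaging after scan-quality and missing-session exclusions
        assert table.loc[table["stage"] == "missing_session_or_withdrew",
                         "remaining"].iloc[0] == 43
        assert beh.analyzed_n() == 36

    def test_custom_counts(self):
        counts = beh.ExclusionCounts(recruited=10, excessive_motion=1,
                                     incomplete_scan=0, data_quality=0,
                                     missing_session_or_withdrew=1,
                                     behavioral_unusable=0,
                                     below_accuracy_threshold=1,
                                     lone_site_participant=0)
        assert beh.analyzed_n(counts) == 7
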
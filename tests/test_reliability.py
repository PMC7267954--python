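"""ICC(3,1) machinery against brute-force and independent oracles."""

import numpy as np
import pytest

from conflicticc import reliability as rel
from conflicticc import synthetic as syn


class TestAnovaComponents:
    def test_hand_computed_example(self):
        # rows are per-subject constants -> no residual or session variance
        vc = rel.anova_components([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
        assert vc.ems == pytest.approx(0.0, abs=1e-12)
        assert vc.jms == pytest.approx(0.0, abs=1e-12)
        assert vc.bms == pytest.approx(3.0, abs=1e-12)

    def test_identical_rows_no_between_variance(self):
        vc = rel.anova_components([[1.0, 2.0, 3.0]] * 4)
        assert vc.bms == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, anova_oracle):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(2, 7)
            k = rng.integers(2, 5)
            Y = rng.normal(size=(n, k))
            vc = rel.anova_components(Y)
            bms, jms, ems = anova_oracle(Y)
            assert vc.bms == pytest.approx(bms, abs=1e-12)
            assert vc.jms == pytest.approx(jms, abs=1e-12)
            assert vc.ems == pytest.approx(ems, abs=1e-12)

    def test_incomplete_subjects_dropped(self):
        Y = np.array([[1.0, 2.0], [np.nan, 1.0], [3.0, 4.0]])
        with pytest.warns(UserWarning, match="dropped 1"):
            vc = rel.anova_components(Y)
        assert vc.n == 2

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            rel.anova_components([[1.0, 2.0]])


class TestIcc31:
    def test_perfect_repeats_give_one(self):
        res = rel.icc31([[1, 1, 1], [2, 2, 2], [5, 5, 5]])
        assert res.icc == pytest.approx(1.0)
        assert res.class_label == "excellent"

    def test_zero_total_variance_is_degenerate(self):
        res = rel.icc31([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert np.isnan(res.icc)
        assert res.degenerate

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        Y = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "session": np.tile(np.arange(3), 12),
                "value": Y.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="session",
                                   ratings="value")
        row = table[table["Type"] == "ICC(C,1)"]  # consistency, single rater
        expected = float(row["ICC"].iloc[0])
        ci = row["CI95"].iloc[0]  # rounded to 2 decimals by pingouin
        res = rel.icc31(Y)
        assert res.icc == pytest.approx(expected, abs=1e-9)
        assert res.ci_low == pytest.approx(ci[0], abs=0.006)
        assert res.ci_high == pytest.approx(ci[1], abs=0.006)

    def test_session_shift_invariance(self):
        # sessions are fixed effects: additive per-session constants must
        # not change the consistency ICC
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        shifted = Y + np.array([0.0, 5.0, -3.0])
        assert rel.icc31(shifted).icc == pytest.approx(rel.icc31(Y).icc, abs=1e-12)

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(8, 3))
        assert rel.icc31(3.5 * Y + 7.0).icc == pytest.approx(
            rel.icc31(Y).icc, abs=1e-12
        )

    def test_variance_ratio_form_differs_when_noisy(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(20, 3)) + 0.5 * rng.normal(size=(20, 1))
        primary = rel.icc31(Y, form="shrout_fleiss").icc
        printed = rel.icc31(Y, form="variance_ratio").icc
        assert printed != pytest.approx(primary, abs=1e-6)

    def test_mean_icc_at_equal_variances(self):
        # with sigma2_b = sigma2_w the true variance-ratio reliability is
        # 0.5; the estimator mean over many cohorts should sit close to it
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(1000):
            subj = rng.normal(size=(36, 1))
            Y = subj + rng.normal(size=(36, 3))
            vals.append(rel.icc31(Y).icc)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_negative_icc_reported_raw_and_floorable(self):
        # anti-correlated repeats force the within variance above the
        # between variance
        Y = np.array([[1.0, -1.0], [-1.0, 1.0], [2.0, -2.0], [-2.0, 2.0]])
        res = rel.icc31(Y)
        assert res.icc < 0
        assert res.class_label == "poor"
        floored = rel.icc31(Y, floor_negative=True)
        assert floored.icc == 0.0
        assert floored.negative_floored


class TestIccCi:
    def test_interval_brackets_point_estimate(self, icc_oracle):
        rng = np.random.default_rng(21)
        Y = rng.normal(size=(36, 3)) + rng.normal(size=(36, 1))
        res = rel.icc31(Y)
        assert res.ci_low <= icc_oracle(Y) <= res.ci_high

    def test_zero_residual_limit(self):
        vc = rel.VarianceComponents(n=10, k=3, bms=5.0, jms=0.0, ems=0.0,
                                    grand_mean=0.0)
        low, high = rel.icc_ci(vc)
        assert low >= 1 - 1e-9
        assert high == 1.0

    def test_nominal_coverage_at_true_icc_06(self):
        # 95% F-based interval should cover the true value in ~95% of
        # cohorts drawn from the two-way model (true ICC 0.6)
        rng = np.random.default_rng(2024)
        covered = 0
        n_rep = 1000
        for _ in range(n_rep):
            subj = rng.normal(0, np.sqrt(0.6), size=(36, 1))
            Y = subj + rng.normal(0, np.sqrt(0.4), size=(36, 3))
            res = rel.icc31(Y)
            covered += res.ci_low <= 0.6 <= res.ci_high
        assert covered / n_rep == pytest.approx(0.95, abs=0.02)


class TestClassify:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.39, "poor"),
            (0.4, "moderate_good"),
            (0.75, "moderate_good"),
            (0.76, "excellent"),
            (-0.07, "poor"),
        ],
    )
    def test_three_band_boundaries(self, value, label):
        assert rel.classify(value) == label

    def test_four_band_scheme(self):
        assert rel.classify(0.65, scheme="four_band") == "good"
        assert rel.classify(0.85, scheme="four_band") == "excellent"
        assert rel.classify(0.45, scheme="four_band") == "moderate"
        assert rel.classify(0.1, scheme="four_band") == "poor"

    def test_nan_is_undefined(self):
        assert rel.classify(float("nan")) == "undefined"


class TestVoxelwiseIcc:
    def test_matches_per_voxel_estimates(self, icc_oracle):
        rng = np.random.default_rng(7)
        stack = rng.normal(size=(8, 3, 4, 4, 2)) + rng.normal(size=(8, 1, 1, 1, 1))
        icc_map = rel.voxelwise_icc(stack)
        for idx in [(0, 0, 0), (2, 3, 1), (3, 1, 0)]:
            Y = stack[(slice(None), slice(None)) + idx]
            assert icc_map[idx] == pytest.approx(icc_oracle(Y), abs=1e-12)

    def test_zero_within_variance_gives_one(self):
        truth = syn.two_region_truth(n_subjects=12, grid=(10, 10, 6),
                                     icc_high=1.0, icc_low=1.0, seed=1)
        stack = syn.simulate_contrast_cohort(truth)
        icc_map = rel.voxelwise_icc(stack)
        in_mask = icc_map[stack.mask]
        assert np.allclose(in_mask, 1.0)

    def test_out_of_mask_is_nan(self):
        truth = syn.two_region_truth(n_subjects=6, grid=(8, 8, 4), seed=2)
        stack = syn.simulate_contrast_cohort(truth)
        icc_map = rel.voxelwise_icc(stack)
        assert np.all(np.isnan(icc_map[~stack.mask]))

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(8)
        stack = rng.normal(size=(6, 3, 3, 3, 2))
        perm = rng.permutation(6)
        a = rel.voxelwise_icc(stack)
        b = rel.voxelwise_icc(stack[perm])
        assert np.allclose(a, b, equal_nan=True)

    def test_parameter_recovery_mae(self):
        # n=36, k=3: mean absolute error of voxel ICC estimates < 0.1 at
        # each true reliability level, 200 voxels per level
        for true_icc in (0.0, 0.2, 0.5, 0.8):
            truth = syn.CohortTruth(
                region_labels=np.ones((200, 1, 1), dtype=int),
                amplitude={1: 1.0},
                sigma2_b={1: true_icc},
                sigma2_w={1: 1.0 - true_icc},
                n_subjects=36,
                seed=100 + int(true_icc * 10),
            )
            stack = syn.simulate_contrast_cohort(truth)
            icc_map = rel.voxelwise_icc(stack)
            mae = np.nanmean(np.abs(icc_map[stack.mask] - true_icc))
            assert mae < 0.1, f"MAE {mae:.3f} at true ICC {true_icc}"

    def test_monotone_in_between_subject_variance(self):
        means = []
        for s2b in (0.2, 0.6, 1.2):
            truth = syn.CohortTruth(
                region_labels=np.ones((300, 1, 1), dtype=int),
                amplitude={1: 0.0},
                sigma2_b={1: s2b},
                sigma2_w={1: 0.5},
                n_subjects=36,
                seed=55,
            )
            stack = syn.simulate_contrast_cohort(truth)
            means.append(np.nanmean(rel.voxelwise_icc(stack)[stack.mask]))
        assert means[0] < means[1] < means[2]


class TestMedianIcc:
    def test_simple_median(self):
        icc_map = np.array([[[0.1]], [[0.5]], [[0.9]]])
        labels = np.ones((3, 1, 1), dtype=int)
        table = rel.median_icc(icc_map, labels)
        assert table.loc[0, "median_icc"] == pytest.approx(0.5)

    def test_one_row_per_atlas_label(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 137, size=(12, 12, 8))
        icc_map = rng.uniform(-0.2, 1.0, size=labels.shape)
        table = rel.median_icc(icc_map, labels)
        assert len(table) == 136

    def test_undefined_region_flagged(self):
        icc_map = np.full((2, 2, 1), np.nan)
        labels = np.ones((2, 2, 1), dtype=int)
        table = rel.median_icc(icc_map, labels)
        assert table.loc[0, "class"] == "undefined"
        assert table.loc[0, "n_defined"] == 0

    def test_cluster_set_mode(self):
        from conflicticc.glm import Cluster, ClusterSet

        icc_map = np.zeros((4, 4, 1))
        icc_map[0, 0, 0] = 0.8
        icc_map[0, 1, 0] = 0.6
        cluster = Cluster(
            cluster_id=1,
            voxels=(np.array([0, 0]), np.array([0, 1]), np.array([0, 0])),
            size=2, peak_index=(0, 0, 0), peak_stat=5.0,
        )
        cs = ClusterSet([cluster], threshold=3.0, min_size=1, n_suprathreshold=2)
        table = rel.median_icc(icc_map, cs)
        assert table.loc[0, "median_icc"] == pytest.approx(0.7)
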
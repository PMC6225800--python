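"""AUC engine, repeated CV, DeLong comparison and the table runner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from kneestudy.evaluate import (
    ComparisonResult,
    CVConfig,
    auc,
    compare_auc,
    run_repeated_cv,
    run_repeated_cv_best_auto,
    single_feature_screen,
    table_runner,
)
from kneestudy.outcomes import FeatureSet, FeatureSetSpec


def _brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.8, 0.3, 0.2]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties_is_half(self):
        assert auc(np.full(10, 0.5), np.array([1, 0] * 5)) == 0.5

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(100):
            n = 12
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            assert auc(scores, labels) == pytest.approx(
                _brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @given(st.integers(0, 10**6))
    @settings(deadline=None, max_examples=25)
    def test_invariance_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[:2] = [0, 1]
        base = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        from scipy.stats import rankdata

        assert auc(rankdata(scores), labels) == pytest.approx(base, abs=1e-12)

    @given(st.integers(0, 10**6))
    @settings(deadline=None, max_examples=25)
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(30), 1)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[:2] = [0, 1]
        assert auc(scores, labels) + auc(scores, 1 - labels) == pytest.approx(
            1.0, abs=1e-12
        )


class TestRepeatedCV:
    def test_reports_one_auc_per_repeat(self, rng):
        x = rng.standard_normal(120)
        y = rng.integers(0, 2, 120)
        res = run_repeated_cv(x, y, CVConfig(n_repeats=5, seed=3))
        assert res.auc_per_repeat.shape == (5,)
        assert res.auc_mean == pytest.approx(np.mean(res.auc_per_repeat))
        assert res.auc_sd == pytest.approx(np.std(res.auc_per_repeat, ddof=1))

    def test_reproducible_given_seed(self, rng):
        x = rng.standard_normal(100)
        y = rng.integers(0, 2, 100)
        a = run_repeated_cv(x, y, CVConfig(seed=5))
        b = run_repeated_cv(x, y, CVConfig(seed=5))
        np.testing.assert_array_equal(a.oof_scores, b.oof_scores)

    def test_binormal_closed_form_oracle(self):
        # feature ~ N(d*y, 1) with d=1: theoretical AUC = Phi(d / sqrt 2)
        rng = np.random.default_rng(42)
        n = 5000
        y = rng.integers(0, 2, n)
        x = rng.standard_normal(n) + y * 1.0
        res = run_repeated_cv(x, y, CVConfig(seed=1))
        assert 100 * res.auc_mean == pytest.approx(
            100 * norm.cdf(1 / np.sqrt(2)), abs=2.0
        )

    def test_separable_feature_is_near_perfect(self, rng):
        x = rng.standard_normal(300)
        y = (x > 0.2).astype(int)
        res = run_repeated_cv(x, y, CVConfig(seed=2))
        assert res.auc_mean > 0.99

    def test_label_permutation_drives_auc_to_chance(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.standard_normal((n, 3))
        y = (x[:, 0] > 0).astype(int)
        y_perm = rng.permutation(y)
        res = run_repeated_cv(x, y_perm, CVConfig(seed=4))
        assert 100 * res.auc_mean == pytest.approx(50.0, abs=3.0)

    def test_small_class_rejected(self):
        x = np.arange(30.0)
        y = np.r_[np.ones(3), np.zeros(27)].astype(int)
        with pytest.raises(ValueError, match="smallest class"):
            run_repeated_cv(x, y, CVConfig())


class TestDemographicGain:
    def test_sex_bmi_augmentation_improves_auc(self):
        """When the generator gives BMI and sex clear loadings on pain,
        adding them to the manual grades raises the cross-validated AUC in
        nearly every cohort replicate."""
        from kneestudy.cohort import CohortConfig, generate_cohort_table
        from kneestudy.grading import GRADE_COLUMNS
        from kneestudy.outcomes import derive_labels

        wins = 0
        n_reps = 6
        for r in range(n_reps):
            tab = generate_cohort_table(
                CohortConfig(
                    n_subjects=1500,
                    pain_bmi_coef=0.8,
                    pain_sex_coef=0.8,
                    seed=4200 + r,
                )
            )
            labels = derive_labels(tab, "CLINIC")
            y = labels.astype(int).to_numpy()
            cfg = CVConfig(seed=r)
            manual = run_repeated_cv(
                tab[GRADE_COLUMNS].to_numpy(float), y, cfg
            ).auc_mean
            demo = run_repeated_cv(
                tab[GRADE_COLUMNS + ["sex", "bmi"]].to_numpy(float), y, cfg
            ).auc_mean
            wins += demo > manual
        assert wins >= n_reps - 1


class TestCompareAUC:
    def _null_pair(self, seed, n=300):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        cfg = CVConfig(seed=seed)
        ra = run_repeated_cv(rng.standard_normal(n), y, cfg)
        rb = run_repeated_cv(rng.standard_normal(n), y, cfg)
        return ra, rb

    def test_self_comparison_is_null(self):
        ra, _ = self._null_pair(0)
        res = compare_auc(ra, ra, paired=True)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_pairing_violation_rejected(self, rng):
        y = rng.integers(0, 2, 100)
        ra = run_repeated_cv(rng.standard_normal(100), y, CVConfig(seed=1))
        rb = run_repeated_cv(rng.standard_normal(100), y, CVConfig(seed=2))
        with pytest.raises(ValueError, match="fold structure"):
            compare_auc(ra, rb, paired=True)

    def test_known_gap_detected(self):
        # ~10-point generator-known AUC gap at moderate n: the test should
        # call it significant
        rng = np.random.default_rng(3)
        n = 2000
        y = rng.integers(0, 2, n)
        strong = rng.standard_normal(n) + 1.1 * y   # AUC ~ 0.78
        weak = rng.standard_normal(n) + 0.55 * y    # AUC ~ 0.65
        cfg = CVConfig(seed=9)
        res = compare_auc(
            run_repeated_cv(strong, y, cfg), run_repeated_cv(weak, y, cfg)
        )
        assert res.significant
        assert res.auc_a > res.auc_b

    def test_unpaired_mode_on_disjoint_rows(self, rng):
        y1 = rng.integers(0, 2, 200)
        y2 = rng.integers(0, 2, 150)
        ra = run_repeated_cv(rng.standard_normal(200), y1, CVConfig(seed=1))
        rb = run_repeated_cv(rng.standard_normal(150), y2, CVConfig(seed=1))
        res = compare_auc(ra, rb, paired=False)
        assert 0 <= res.p_value <= 1
        assert "unpaired" in res.method


class TestTableRunner:
    def test_grid_shape_counts_and_determinism(self, small_cohort_table):
        cfg = CVConfig(n_repeats=2, seed=0)
        specs = [
            ("CLINIC", FeatureSetSpec(FeatureSet.MANUAL), False),
            ("CLINIC", FeatureSetSpec(FeatureSet.MANUAL_DEMO), False),
            ("CONSISTENT", FeatureSetSpec(FeatureSet.MANUAL), False),
            ("CONSISTENT", FeatureSetSpec(FeatureSet.MANUAL_DEMO), True),
        ]
        t1 = table_runner(small_cohort_table, specs, cfg)
        assert len(t1) == 4
        # n-samples equals a brute-force recount of post-exclusion rows
        from kneestudy.outcomes import derive_labels, filter_widespread

        cons = derive_labels(small_cohort_table, "CONSISTENT")
        expected_n = int(cons.notna().sum())
        row = t1[(t1.outcome == "CONSISTENT") & (~t1.widespread_removed)]
        assert int(row.n.iloc[0]) == expected_n
        kept, _ = filter_widespread(small_cohort_table)
        expected_nw = int(derive_labels(kept, "CONSISTENT").notna().sum())
        roww = t1[(t1.outcome == "CONSISTENT") & (t1.widespread_removed)]
        assert int(roww.n.iloc[0]) == expected_nw
        t2 = table_runner(small_cohort_table, specs, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_referent_row_has_no_p_value(self, small_cohort_table):
        cfg = CVConfig(n_repeats=2, seed=0)
        specs = [
            ("CLINIC", FeatureSetSpec(FeatureSet.MANUAL), False),
            ("CLINIC", FeatureSetSpec(FeatureSet.MANUAL_DEMO), False),
        ]
        t = table_runner(small_cohort_table, specs, cfg)
        ref = t[t.feature_set == "MANUAL"]
        assert np.isnan(ref.p_vs_referent.iloc[0])
        assert np.isfinite(t[t.feature_set == "MANUAL_DEMO"].p_vs_referent.iloc[0])

    def test_single_feature_screen_layout(self, small_cohort_table):
        cfg = CVConfig(n_repeats=2, seed=1)
        t = single_feature_screen(
            small_cohort_table, "CLINIC", cfg,
            features=["kl_grade_pa", "chondrocalcinosis_pf_la"],
        )
        assert list(t.feature) == ["kl_grade_pa", "chondrocalcinosis_pf_la"]
        assert t.auc_pct.between(0, 100).all()
        # the strongly-loaded global grade beats the zero-loading feature
        assert t.auc_pct.iloc[0] > t.auc_pct.iloc[1]

    def test_best_auto_nested_selection_runs(self, rng):
        n = 150
        y = rng.integers(0, 2, n)
        variants = {
            "AUTO_SHAPE": rng.standard_normal((n, 3)) + y[:, None] * 0.8,
            "AUTO_TEXTURE": rng.standard_normal((n, 3)),
            "AUTO_COMBINED": rng.standard_normal((n, 3)) + y[:, None] * 0.3,
        }
        res = run_repeated_cv_best_auto(
            variants, y, CVConfig(n_repeats=2, seed=0)
        )
        chosen = res.extra["chosen_variants"]
        assert len(chosen) == 2 * 5
        # the informative variant should dominate the selections
        assert chosen.count("AUTO_SHAPE") > len(chosen) / 2
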
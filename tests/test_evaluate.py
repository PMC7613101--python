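"""Bootstrap protocol, AUC computations, group statistics, clinical relate."""

import numpy as np
import pandas as pd
import pytest

import tractnorm as tn
from tractnorm.exceptions import (
    CohortSizeError,
    InsufficientDataError,
    ParameterError,
)


class TestAucs:
    def test_perfectly_ordered_scores(self):
        scores = np.arange(10.0)
        labels = np.array([0] * 5 + [1] * 5)
        assert tn.roc_auc(scores, labels) == 1.0

    def test_roc_matches_concordant_pair_count(self, rng):
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]  # ensure both classes
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = sum(
            1.0 if p > n_ else 0.5 if p == n_ else 0.0
            for p in pos for n_ in neg
        )
        brute = pairs / (len(pos) * len(neg))
        assert tn.roc_auc(scores, labels) == pytest.approx(brute)

    def test_pr_baseline_equals_prevalence(self, rng):
        labels = np.array([1] * 8 + [0] * 90)
        # uninformative scores: all ties
        assert tn.pr_auc(np.zeros(98), labels) == pytest.approx(8 / 98)

    def test_roc_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = tn.roc_auc(scores, labels)
        assert tn.roc_auc(np.exp(3 * scores), labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            tn.roc_auc(np.arange(4.0), np.zeros(4))


class TestGroupStats:
    def test_identical_groups(self, rng):
        x = rng.normal(size=12)
        gs = tn.group_stats(x, x.copy())
        assert gs.cohens_d == 0.0
        assert gs.test_name == "t"

    def test_unbalanced_uses_ks_and_disjoint_supports(self):
        gs = tn.group_stats(np.array([1.0, 2, 3]), np.array([4.0, 5, 6, 7]))
        assert gs.test_name == "ks"
        assert gs.statistic == 1.0

    def test_cohens_d_recovers_unit_effect(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 20)
        gs = tn.group_stats(a, b)
        assert gs.cohens_d == pytest.approx(1.0, abs=0.35)
        # pooled-sd oracle
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert gs.cohens_d == pytest.approx(
            abs(a.mean() - b.mean()) / pooled)

    def test_too_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            tn.group_stats(np.array([1.0]), np.array([1.0, 2.0]))


class TestRelate:
    def test_monotone_transform_gives_rho_one(self):
        a = np.array([0.1, 0.5, 0.3, 0.9, 0.7, 0.2])
        rho, _ = tn.relate(a, np.exp(a))
        assert rho == pytest.approx(1.0)
        rho, _ = tn.relate(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_tie_aware_matches_rank_then_pearson(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        c = np.array([2.0, 2, 5, 4, 9, 7, 8, 8])  # ties in clinical
        rho, _ = tn.relate(a, c)
        ra = pd.Series(a).rank().to_numpy()
        rc = pd.Series(c).rank().to_numpy()
        pearson = np.corrcoef(ra, rc)[0, 1]
        assert rho == pytest.approx(pearson)

    def test_pairwise_exclusion_and_minimum_n(self):
        a = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        c = pd.Series([1.0, np.nan, 3, 4, np.nan, 6], index=list("abcdef"))
        with pytest.raises(InsufficientDataError):
            tn.relate(a, c)  # only 4 complete pairs

    def test_constant_clinical_rejected(self):
        with pytest.raises(InsufficientDataError):
            tn.relate(np.arange(6.0), np.full(6, 3.0))


class TestBootstrap:
    def test_determinism_same_seed_same_auc_sequence(self, small_cohort):
        plan = tn.BootstrapPlan(n_iterations=5, seed=3)
        _, r1 = tn.run_bootstrap(small_cohort.dataset,
                                 small_cohort.demographics, "RISH0",
                                 "zscore", plan)
        _, r2 = tn.run_bootstrap(small_cohort.dataset,
                                 small_cohort.demographics, "RISH0",
                                 "zscore", plan)
        np.testing.assert_array_equal(r1.iteration_aucs, r2.iteration_aucs)

    def test_validation_composition_and_training_controls_only(self, small_cohort):
        results, report = tn.run_bootstrap(
            small_cohort.dataset, small_cohort.demographics, "RISH0",
            "zscore", tn.BootstrapPlan(n_iterations=10, seed=1),
        )
        by_id = {r.subject_id: r for r in results}
        # patients scored in every iteration
        for i in range(1, 5):
            assert by_id[f"pat-{i:03d}"].n_scored == 10
        # controls scored at most n_iterations times
        for r in results:
            if r.subject_id.startswith("ctrl"):
                assert r.n_scored <= 10
        assert 0.0 <= report.mean_auc <= 1.0
        assert report.pr_baseline == pytest.approx(0.5)

    def test_patient_features_never_leak_into_training(self, small_cohort):
        """Corrupting every patient's features leaves all control scores
        untouched: detectors are fit on controls only."""
        plan = tn.BootstrapPlan(n_iterations=8, seed=5)
        res_a, _ = tn.run_bootstrap(small_cohort.dataset,
                                    small_cohort.demographics, "RISH0",
                                    "zscore", plan)
        frames = {m: df.copy() for m, df in small_cohort.dataset.frames.items()}
        pat_rows = [s for s in frames["RISH0"].index if s.startswith("pat")]
        frames["RISH0"].loc[pat_rows] = 999.0
        corrupted = tn.TractometryDataset(frames)
        res_b, _ = tn.run_bootstrap(corrupted, small_cohort.demographics,
                                    "RISH0", "zscore", plan)
        ctrl_a = {r.subject_id: r.score_mean for r in res_a
                  if r.subject_id.startswith("ctrl")}
        ctrl_b = {r.subject_id: r.score_mean for r in res_b
                  if r.subject_id.startswith("ctrl")}
        assert ctrl_a == ctrl_b

    def test_too_few_controls_rejected(self):
        spec = tn.CohortSpec(n_controls=9, n_patients=4, seed=0)
        cohort = tn.generate_cohort(spec)
        with pytest.raises(CohortSizeError):
            tn.run_bootstrap(cohort.dataset, cohort.demographics, "RISH0",
                             "zscore", tn.BootstrapPlan(n_iterations=2))

    def test_score_convergence_with_iterations(self, small_cohort):
        """Patient mean scores stabilise as iterations grow."""
        plan_a = tn.BootstrapPlan(n_iterations=4, seed=11)
        plan_b = tn.BootstrapPlan(n_iterations=40, seed=11)
        res_a, _ = tn.run_bootstrap(small_cohort.dataset,
                                    small_cohort.demographics, "RISH0",
                                    "zscore", plan_a)
        res_b, _ = tn.run_bootstrap(small_cohort.dataset,
                                    small_cohort.demographics, "RISH0",
                                    "zscore", plan_b)
        sd_a = np.mean([r.score_sd / np.sqrt(r.n_scored) for r in res_a
                        if r.subject_id.startswith("pat")])
        sd_b = np.mean([r.score_sd / np.sqrt(r.n_scored) for r in res_b
                        if r.subject_id.startswith("pat")])
        assert sd_b < sd_a
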
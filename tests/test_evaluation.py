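"""Folds, augmentation, metrics, clustered bootstrap, cohort summary."""

import itertools

import numpy as np
import pytest
from scipy import stats

from glaucroi.evaluation import (
    WaldResult,
    adjusted_auroc,
    al_category,
    augment_minority,
    auprc,
    auroc,
    cluster_bootstrap,
    cohort_summary,
    make_folds,
    sens_at_spec,
    wald_auroc_diff,
)
from glaucroi.types import EyeRecord


def _record(pid, eye, diagnosis, al=24.0, lat="OD"):
    return EyeRecord(pid, eye, lat, diagnosis, 50.0, al, 80.0)


def _toy_manifest(n_per_class=10, eyes_per_patient=1):
    records = []
    k = 0
    for d in ("healthy", "glaucoma"):
        for i in range(n_per_class):
            k += 1
            pid = f"P{k:03d}"
            for e, lat in enumerate(("OD", "OS")[:eyes_per_patient]):
                records.append(_record(pid, f"{pid}-{lat}", d, lat=lat))
    return records


class TestFolds:
    def test_ten_patients_two_per_fold(self):
        records = _toy_manifest(n_per_class=5)
        fa = make_folds(records, k=5, seed=1)
        counts = {f: 0 for f in range(1, 6)}
        for pid, f in fa.mapping.items():
            counts[f] += 1
        assert all(v == 2 for v in counts.values())

    def test_two_eye_patient_shares_fold(self):
        records = _toy_manifest(n_per_class=6, eyes_per_patient=2)
        fa = make_folds(records, k=5, seed=3)
        for r in records:
            assert fa.fold_of(r.patient_id) == fa.mapping[r.patient_id]

    def test_union_of_test_folds_is_partition(self):
        records = _toy_manifest(n_per_class=8, eyes_per_patient=2)
        fa = make_folds(records, k=5, seed=2)
        seen = []
        for f in range(1, 6):
            seen += [r.eye_id for r in records if fa.fold_of(r.patient_id) == f]
        assert sorted(seen) == sorted(r.eye_id for r in records)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            make_folds(_toy_manifest(n_per_class=3), k=5, seed=0)


class TestAugmentMinority:
    def test_balancing_arithmetic(self, rng):
        images = [rng.random((8, 8)) for _ in range(100)]
        labels = [0] * 60 + [1] * 40
        pids = [f"P{i}" for i in range(100)]
        out_imgs, out_labels, out_pids, flags = augment_minority(images, labels, pids)
        assert out_labels.count(0) == 60 and out_labels.count(1) == 60
        assert sum(flags) == 20
        assert all(p in pids for p in out_pids)

    def test_balanced_input_unchanged(self, rng):
        images = [rng.random((4, 4)) for _ in range(6)]
        out_imgs, out_labels, _, flags = augment_minority(images, [0, 0, 0, 1, 1, 1])
        assert len(out_imgs) == 6 and not any(flags)

    def test_mirroring_is_involution(self, rng):
        img = rng.random((8, 8))
        out_imgs, *_ = augment_minority([img, img, rng.random((8, 8))], [1, 0, 0])
        mirrored = out_imgs[-1]
        assert np.array_equal(np.fliplr(mirrored), img)


class TestAUROC:
    def test_exhaustive_pair_counting_all_small_sets(self):
        """AUROC equals (concordant + 0.5 ties) / (n_pos * n_neg) for every
        score set of size 2..6 over a 3-level score grid."""
        grid = [0.0, 0.5, 1.0]
        for n in range(2, 7):
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                for scores in itertools.product(grid, repeat=n):
                    pos = [s for s, l in zip(scores, labels) if l == 1]
                    neg = [s for s, l in zip(scores, labels) if l == 0]
                    num = sum(
                        1.0 if p > q else (0.5 if p == q else 0.0)
                        for p in pos
                        for q in neg
                    )
                    expected = num / (len(pos) * len(neg))
                    assert auroc(list(scores), list(labels)) == pytest.approx(expected)

    def test_hand_example(self):
        assert auroc([3, 1, 2, 0], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_separation_and_ties(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestAUPRC:
    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(25):
            n = rng.integers(4, 40)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=n)
            assert auprc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )

    def test_perfect_separation_gives_one(self):
        assert auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


class TestSensAtSpec:
    def test_separable_toy_set_is_one_at_both_specs(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [0, 0, 0, 1, 1, 1]
        assert sens_at_spec(scores, labels, 0.80) == 1.0
        assert sens_at_spec(scores, labels, 0.95) == 1.0

    def test_hand_enumerated_overlap_example(self):
        """negatives 1..10, positives 6..15: the smallest cut with
        specificity >= 0.8 is 8, leaving positives 9..15 -> 0.7."""
        scores = list(range(1, 11)) + list(range(6, 16))
        labels = [0] * 10 + [1] * 10
        assert sens_at_spec(scores, labels, 0.80) == pytest.approx(0.7)

    def test_full_specificity_with_overlapping_max(self):
        scores = [1, 2, 3, 3]
        labels = [0, 0, 1, 1]
        # spec=1.0 requires the cut at the top negative (2): sens = 1.0
        assert sens_at_spec(scores, labels, 1.0) == 1.0
        # degenerate: negatives hold the maximum, cut above all scores
        assert sens_at_spec([1, 5, 2, 3], [0, 0, 1, 1], 1.0) == 0.0


class TestClusterBootstrap:
    def test_constant_metric_zero_width_ci(self):
        scores = np.array([0.0, 0.0, 1.0, 1.0] * 10)
        labels = np.array([0, 0, 1, 1] * 10)
        pids = [f"P{i}" for i in range(40)]
        res = cluster_bootstrap(auroc, scores, labels, pids, n_boot=200, seed=9)
        assert res.ci["metric"] == (1.0, 1.0)

    def test_seed_fixes_result_exactly(self, rng):
        scores = rng.random(30)
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        pids = [f"P{i // 2}" for i in range(30)]
        a = cluster_bootstrap(auroc, scores, labels, pids, n_boot=150, seed=4)
        b = cluster_bootstrap(auroc, scores, labels, pids, n_boot=150, seed=4)
        assert a.ci == b.ci
        assert np.array_equal(a.draws["metric"], b.draws["metric"])

    def test_degenerate_replicates_redrawn_and_counted(self, rng):
        # one glaucoma patient only: many resamples miss the positive class
        scores = rng.random(12)
        labels = np.r_[np.zeros(10, int), np.ones(2, int)]
        pids = [f"P{i}" for i in range(10)] + ["P10", "P10"]
        res = cluster_bootstrap(auroc, scores, labels, pids, n_boot=100, seed=2)
        assert res.n_redrawn > 0
        assert np.isfinite(res.draws["metric"]).all()

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            cluster_bootstrap(auroc, [1.0, 0.0], [1, 0], ["a", "b"], n_boot=10)


class TestWald:
    def test_identical_models_give_p_one(self, rng):
        draws = rng.random(200)
        res = wald_auroc_diff(draws, draws, 0.8, 0.8)
        assert res.delta == 0.0 and res.p == 1.0

    def test_known_gap_and_se_give_z5_tail(self, rng):
        # paired draws engineered so sd(a-b) ~= 0.02 with point gap 0.1
        base = rng.normal(0, 0.05, 400)
        a = base + rng.normal(0, 0.02 / np.sqrt(2), 400)
        b = base + rng.normal(0, 0.02 / np.sqrt(2), 400)
        res = wald_auroc_diff(a, b, 0.85, 0.75)
        assert res.p < 0.001

    def test_anticorrelated_draws_inflate_se(self, rng):
        z = rng.normal(0, 0.05, 500)
        res_anti = wald_auroc_diff(z, -z, 0.1, 0.0)
        res_ind = wald_auroc_diff(z, rng.permutation(z), 0.1, 0.0)
        assert res_anti.se > res_ind.se  # Var(a-b) = Va + Vb - 2Cov

    def test_zero_se_nonzero_delta_flagged(self):
        draws = np.full(250, 0.8)
        res = wald_auroc_diff(draws, draws, 0.9, 0.8)
        assert res.degenerate_se
        assert res.p == pytest.approx(1 / 250)


class TestAdjustedAUROC:
    def test_constant_covariates_equal_unadjusted(self, rng):
        scores = rng.random(60)
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        cov = np.ones((60, 2))
        assert adjusted_auroc(scores, labels, cov) == pytest.approx(auroc(scores, labels))

    def test_independent_covariates_close_to_unadjusted(self, rng):
        n = 400
        labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        scores = rng.normal(0, 1, n) + labels
        cov = rng.normal(0, 1, (n, 3))
        assert adjusted_auroc(scores, labels, cov) == pytest.approx(auroc(scores, labels), abs=0.05)

    def test_pure_confounding_removed(self, rng):
        """Scores determined by age; cases are just older. Conditional on
        age the classes are identical, so the adjusted AUROC is ~0.5 while
        the crude AUROC is far above it."""
        n = 500
        labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        age = rng.normal(50, 5, n) + 9 * labels
        scores = 0.1 * age + rng.normal(0, 0.05, n)
        crude = auroc(scores, labels)
        adj = adjusted_auroc(scores, labels, age)
        assert crude > 0.8
        assert adj == pytest.approx(0.5, abs=0.08)

    def test_incomplete_covariates_rejected(self, rng):
        cov = np.array([1.0, np.nan, 2.0, 3.0])
        with pytest.raises(ValueError):
            adjusted_auroc([1, 2, 3, 4], [0, 0, 1, 1], cov)


class TestCohortSummary:
    def _manifest_from_counts(self, counts_healthy, counts_glaucoma):
        """Build a manifest realising printed per-category eye counts."""
        reps = {"emmetropic_mild": 23.5, "moderate": 25.0, "high": 27.0}
        records = []
        k = 0
        for d, counts in (("healthy", counts_healthy), ("glaucoma", counts_glaucoma)):
            for cat, n in zip(("emmetropic_mild", "moderate", "high"), counts):
                for _ in range(n):
                    k += 1
                    records.append(_record(f"P{k:04d}", f"E{k:04d}", d, al=reps[cat]))
        return records

    def test_reproduces_printed_column_percentages(self):
        """Counts 112/105/51 of 268 healthy and 49/68/68 of 185 glaucoma
        give the published 41.79% emmetropic-mild and 36.75% highly myopic
        column percentages."""
        summary = cohort_summary(self._manifest_from_counts([112, 105, 51], [49, 68, 68]))
        t = summary.table
        assert t.loc["emmetropic_mild", "pct_healthy"] == pytest.approx(100 * 112 / 268, abs=1e-9)
        assert round(t.loc["emmetropic_mild", "pct_healthy"], 2) == 41.79
        # 68/185 = 36.7568%; the published table truncates this to 36.75
        assert t.loc["high", "pct_glaucoma"] == pytest.approx(100 * 68 / 185, abs=1e-9)
        assert t.loc["moderate", "pct_healthy"] == pytest.approx(100 * 105 / 268, abs=1e-9)
        assert t["n_healthy"].sum() == 268 and t["n_glaucoma"].sum() == 185

    def test_single_category_is_hundred_percent(self):
        summary = cohort_summary(self._manifest_from_counts([10, 0, 0], [5, 0, 0]))
        assert summary.table.loc["emmetropic_mild", "pct_healthy"] == pytest.approx(100.0)

    def test_boundaries_are_half_open(self):
        assert al_category(24.49) == "emmetropic_mild"
        assert al_category(24.5) == "moderate"
        assert al_category(26.0) == "moderate"
        assert al_category(26.01) == "high"

    def test_proportion_tests_flag_imbalanced_category(self):
        summary = cohort_summary(self._manifest_from_counts([112, 105, 51], [49, 68, 68]))
        assert summary.table.loc["emmetropic_mild", "p_proportion"] < 0.001
        assert summary.overall_chi2_p < 0.001
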
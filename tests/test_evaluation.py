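"""Cross-validation protocols, ranking metrics and case-study ranking."""

import numpy as np
import pytest

from ddaskf import (
    AssociationMatrix,
    Dataset,
    PredictionMatrix,
    aupr,
    auroc,
    make_folds,
    mask_fold,
    orphan_predict,
    run_cv,
    threshold_metrics,
    top_k_candidates,
)
from .oracles import (
    aupr_brute,
    auroc_pair_counting,
    exhaustive_threshold_metrics,
)


def make_A(values):
    values = np.asarray(values)
    return AssociationMatrix(
        values,
        [f"p{i}" for i in range(values.shape[0])],
        [f"d{j}" for j in range(values.shape[1])],
    )


def random_instance(rng, n=30):
    """Scores drawn from a small discrete set to exercise tie handling."""
    scores = rng.choice(np.linspace(0, 1, 11), size=n)
    labels = np.zeros(n, dtype=np.int8)
    labels[rng.choice(n, size=max(2, n // 4), replace=False)] = 1
    return scores, labels


class TestMakeFolds:
    def test_balanced_cell_partition(self):
        A = make_A(np.eye(10, dtype=int))
        spec = make_folds(A, "association_cv", 5, seed=3)
        assert [len(f) for f in spec.folds] == [2] * 5
        stacked = np.vstack(spec.folds)
        assert len(np.unique(stacked, axis=0)) == 10  # a partition, no repeats

    def test_deterministic_from_seed(self):
        A = make_A((np.arange(72).reshape(8, 9) % 3 == 0).astype(int))
        a = make_folds(A, "association_cv", 4, seed=11)
        b = make_folds(A, "association_cv", 4, seed=11)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_drug_fold_sizes_for_593_drugs(self):
        values = np.zeros((4, 593), dtype=int)
        values[0, :] = 1
        A = make_A(values)
        spec = make_folds(A, "drug_cv", 10, seed=0)
        assert sorted({len(f) for f in spec.folds}) == [59, 60]
        assert sum(len(f) for f in spec.folds) == 593

    def test_too_many_folds_rejected(self):
        A = make_A(np.eye(3, dtype=int))
        with pytest.raises(ValueError, match="folds"):
            make_folds(A, "association_cv", 4, seed=0)


class TestMaskFold:
    def test_cells_are_zeroed_original_untouched(self):
        A = make_A(np.ones((2, 3), dtype=int))
        fold = np.array([[0, 0], [1, 2]])
        masked = mask_fold(A, fold)
        assert masked.values[0, 0] == 0 and masked.values[1, 2] == 0
        assert masked.values.sum() == 4
        assert A.values.sum() == 6

    def test_masking_every_positive_gives_zero_matrix(self):
        A = make_A(np.eye(3, dtype=int))
        masked = mask_fold(A, A.positives())
        assert masked.values.sum() == 0

    def test_empty_fold_is_identity(self):
        A = make_A(np.eye(3, dtype=int))
        masked = mask_fold(A, np.empty((0, 2), dtype=int))
        np.testing.assert_array_equal(masked.values, A.values)

    def test_column_masking(self):
        A = make_A(np.ones((2, 4), dtype=int))
        masked = mask_fold(A, np.array([1, 3]))
        assert masked.values[:, [1, 3]].sum() == 0
        assert masked.values[:, [0, 2]].sum() == 4


class TestRankingMetrics:
    def test_perfect_and_inverted_separation(self):
        labels = np.array([1, 1, 0, 0])
        assert auroc([4, 3, 2, 1], labels) == 1.0
        assert auroc([1, 2, 3, 4], labels) == 0.0

    def test_six_item_example_matches_pair_counting(self):
        scores = np.array([6, 5, 4, 3, 2, 1], dtype=float)
        labels = np.array([1, 0, 1, 0, 0, 0])
        assert auroc(scores, labels) == pytest.approx(
            auroc_pair_counting(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            auroc([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="classes"):
            aupr([1.0, 2.0], [0, 0])

    def test_metrics_match_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            scores, labels = random_instance(rng)
            assert auroc(scores, labels) == pytest.approx(
                auroc_pair_counting(scores, labels), abs=1e-10
            )
            assert aupr(scores, labels) == pytest.approx(
                aupr_brute(scores, labels), abs=1e-10
            )

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        for _ in range(25):
            scores, labels = random_instance(rng, n=60)
            assert auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-10
            )
            assert aupr(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-10
            )


class TestThresholdMetrics:
    def test_perfect_separation_all_ones(self):
        report = threshold_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        for value in (report.sen, report.spe, report.pre, report.acc,
                      report.f1, report.mcc):
            assert value == 1.0

    def test_chosen_threshold_is_globally_f1_optimal(self, rng):
        for _ in range(100):
            scores, labels = random_instance(rng)
            report = threshold_metrics(scores, labels)
            best = exhaustive_threshold_metrics(scores, labels)
            assert report.f1 == pytest.approx(best["f1"], abs=1e-10)
            assert report.threshold == pytest.approx(best["threshold"])
            for key in ("sen", "spe", "pre", "acc", "mcc"):
                assert getattr(report, key) == pytest.approx(best[key], abs=1e-10)

    def test_f1_consistent_with_sen_and_pre(self, rng):
        scores, labels = random_instance(rng, n=40)
        report = threshold_metrics(scores, labels)
        expected = 2 * report.pre * report.sen / (report.pre + report.sen)
        assert report.f1 == pytest.approx(expected)

    def test_mcc_zero_denominator_warns(self):
        # every candidate threshold leaves a degenerate confusion row
        with pytest.warns(UserWarning, match="MCC"):
            report = threshold_metrics([0.5, 0.5, 0.5], [1, 0, 0])
        assert report.mcc == 0.0


class TestRunCV:
    def test_repeatable_and_summary_shapes(self, default_dataset):
        kwargs = dict(scheme="association_cv", n_folds=5, n_repeats=2, seed=7)
        res1 = run_cv(default_dataset, **kwargs)
        res2 = run_cv(default_dataset, **kwargs)
        assert len(res1.reports) == 2
        for r1, r2 in zip(res1.reports, res2.reports):
            assert r1.as_dict() == r2.as_dict()
        assert set(res1.summary) >= {"auroc", "aupr", "f1", "mcc"}

    def test_single_repeat_sd_is_zero(self, default_dataset):
        res = run_cv(default_dataset, n_folds=5, n_repeats=1, seed=3)
        assert all(sd == 0.0 for _, sd in res.summary.values())

    def test_per_fold_pooling_emits_fold_reports(self, default_dataset):
        res = run_cv(default_dataset, n_folds=5, n_repeats=1, seed=3,
                     pooling="per_fold")
        assert len(res.reports) == 5
        assert {r.fold for r in res.reports} == {"0", "1", "2", "3", "4"}

    def test_drug_cv_runs_and_ranks_better_than_chance(self, default_dataset):
        res = run_cv(default_dataset, scheme="drug_cv", n_folds=5,
                     n_repeats=1, seed=5)
        assert res.summary["auroc"][0] > 0.6

    def test_training_kernels_blind_to_held_out_cells(self, default_dataset):
        """Flipping a held-out cell in the original matrix cannot reach the
        training-side kernels: masking wipes the cell either way."""
        from ddaskf import gip_kernel

        A = default_dataset.association
        spec = make_folds(A, "association_cv", 5, seed=2)
        fold = spec.folds[0]
        flipped = A.copy()
        i, j = fold[0]
        flipped.values[i, j] = 1 - flipped.values[i, j]
        for space in ("drug", "disease"):
            K_ref = gip_kernel(mask_fold(A, fold), space).values
            K_flip = gip_kernel(mask_fold(flipped, fold), space).values
            np.testing.assert_array_equal(K_ref, K_flip)


class TestTopK:
    def make_pred(self, col_scores):
        scores = np.asarray(col_scores, dtype=float).reshape(-1, 1)
        ids = [f"p{i}" for i in range(scores.shape[0])]
        return PredictionMatrix(scores, ids, ["d0"])

    def test_known_pairs_excluded_and_sorted(self):
        F = self.make_pred([0.9, 0.2, 0.7])
        A = make_A([[0], [1], [0]])
        ranked = top_k_candidates(F, A, axis="drug", entity_id="d0", k=5)
        assert ranked == [("p0", 0.9), ("p2", 0.7)]

    def test_all_known_gives_empty_list(self):
        F = self.make_pred([0.9, 0.2])
        A = make_A([[1], [1]])
        assert top_k_candidates(F, A, axis="drug", entity_id="d0", k=3) == []

    def test_ties_break_by_partner_id(self):
        F = self.make_pred([0.5, 0.5, 0.5])
        A = make_A([[0], [0], [0]])
        ranked = top_k_candidates(F, A, axis="drug", entity_id="d0", k=3)
        assert [p for p, _ in ranked] == ["p0", "p1", "p2"]

    def test_unknown_entity_rejected(self):
        F = self.make_pred([0.5])
        A = make_A([[0]])
        with pytest.raises(KeyError, match="nope"):
            top_k_candidates(F, A, axis="drug", entity_id="nope", k=1)


class TestOrphanPredict:
    def test_candidates_include_no_known_and_cover_all_diseases(self, default_dataset):
        drug = default_dataset.association.drug_ids[0]
        ranked = orphan_predict(default_dataset, drug, k=40)
        # the orphan column is fully masked, so every disease is a candidate
        assert len(ranked) == default_dataset.association.n_diseases

    def test_recovers_true_association_in_top_20(self, default_dataset):
        A = default_dataset.association
        j = int(np.argmax(A.values.sum(axis=0)))  # best-annotated drug
        drug = A.drug_ids[j]
        true_diseases = {A.disease_ids[i] for i in np.flatnonzero(A.values[:, j])}
        ranked = orphan_predict(default_dataset, drug, k=20)
        assert {d for d, _ in ranked} & true_diseases
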
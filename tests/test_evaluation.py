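import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import corescan as cs
from corescan.data_model import ValidationError
from helpers import brute_auc, brute_spearman


class TestMakeFolds:
    def test_even_split_sizes(self, toy_dataset):
        # 6 peptides, k=3 -> three folds of 2
        folds = cs.make_folds(toy_dataset, k=3, seed=0)
        sizes = sorted(len(folds.test_sequences(f)) for f in range(3))
        assert sizes == [2, 2, 2]

    def test_uneven_split_differs_by_at_most_one(self, bench_dataset):
        ds = cs.AffinityDataset(bench_dataset.allele, bench_dataset.records[:11], "synthetic")
        folds = cs.make_folds(ds, k=5, seed=1)
        sizes = sorted(len(folds.test_sequences(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 3]

    def test_same_seed_reproduces_assignment(self, toy_dataset):
        a = cs.make_folds(toy_dataset, k=3, seed=5)
        b = cs.make_folds(toy_dataset, k=3, seed=5)
        assert a.assignment == b.assignment

    def test_folds_partition_the_dataset(self, bench_dataset):
        folds = cs.make_folds(bench_dataset, k=5, seed=2)
        union = [s for f in range(5) for s in folds.test_sequences(f)]
        assert sorted(union) == sorted(bench_dataset.sequences)

    @pytest.mark.parametrize("k", [1, 7])
    def test_invalid_k_rejected(self, toy_dataset, k):
        with pytest.raises(ValidationError):
            cs.make_folds(toy_dataset, k=k, seed=0)


class _ConstantPredictor:
    method = "constant"

    def predict_many(self, peptides):
        return [cs.PredictionRecord(p, 100.0, 0, self.method) for p in peptides]


class _ConstantTrainer:
    method = "constant"

    def fit(self, dataset):
        return _ConstantPredictor()


class TestCrossValidate:
    def test_every_peptide_predicted_exactly_once(self, bench_dataset, bench_folds):
        small = cs.AffinityDataset(bench_dataset.allele, bench_dataset.records[:120], "synthetic")
        folds = cs.make_folds(small, k=5, seed=0)
        preds = cs.cross_validate(cs.BaselineTrainer(), small, folds)
        assert [p.sequence for p in preds] == small.sequences
        # each prediction's fold matches the assignment: blinded by construction
        for p in preds:
            assert p.fold == folds.fold_of(p.sequence)

    def test_constant_score_trainer_gives_auc_half(self, toy_dataset):
        folds = cs.make_folds(toy_dataset, k=3, seed=0)
        preds = cs.cross_validate(_ConstantTrainer(), toy_dataset, folds)
        scores = [p.score for p in preds]
        assert cs.roc_auc(scores, toy_dataset.labels).auc == pytest.approx(0.5)

    def test_incomplete_fold_assignment_rejected(self, toy_dataset):
        folds = cs.make_folds(toy_dataset, k=3, seed=0)
        del folds.assignment[toy_dataset.sequences[0]]
        with pytest.raises(ValidationError, match="cover"):
            cs.cross_validate(_ConstantTrainer(), toy_dataset, folds)


class TestROCAUC:
    def test_perfect_separation_is_one(self):
        curve = cs.roc_auc([1, 2, 3, 4], [True, True, False, False])
        assert curve.auc == 1.0

    def test_interleaved_scores_give_three_quarters(self):
        # binders at 1, 3; non-binders at 2, 4; 3 of 4 pairs concordant
        curve = cs.roc_auc([1, 3, 2, 4], [True, True, False, False])
        assert curve.auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        curve = cs.roc_auc([5.0] * 10, [True] * 5 + [False] * 5)
        assert curve.auc == pytest.approx(0.5)

    def test_curve_anchored_and_monotone(self, bench_dataset):
        rng = np.random.default_rng(0)
        scores = rng.random(100)
        labels = rng.random(100) < 0.5
        curve = cs.roc_auc(scores, labels)
        assert tuple(curve.points[0]) == (0.0, 0.0)
        assert tuple(curve.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.points[:, 0]) >= 0)
        assert np.all(np.diff(curve.points[:, 1]) >= 0)

    def test_orientation_flip_complements_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = np.arange(50) < 20
        a = cs.roc_auc(scores, labels, "lower-is-better").auc
        b = cs.roc_auc(scores, labels, "higher-is-better").auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            cs.roc_auc([1, 2, 3], [True, True, True])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 120), tie_prob=st.floats(0, 0.8))
    def test_matches_mann_whitney_bruteforce(self, seed, n, tie_prob):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, max(2, int(n * (1 - tie_prob))), n).astype(float)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = cs.roc_auc(scores, labels).auc
        assert auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(60)
        labels = np.arange(60) < 25
        base = cs.roc_auc(scores, labels).auc
        for transform in (np.exp, lambda x: 3 * x + 1, lambda x: x**3):
            assert cs.roc_auc(transform(scores), labels).auc == pytest.approx(base)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = np.round(rng.random(300), 2)  # rounding creates ties
        labels = rng.random(300) < 0.4
        ours = cs.roc_auc(scores, labels, "lower-is-better").auc
        theirs = roc_auc_score(labels, -scores)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestSpearman:
    def test_identical_vectors_give_one(self):
        assert cs.spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        assert cs.spearman_rho([4, 3, 2, 1], [1, 2, 3, 4]) == pytest.approx(-1.0)

    def test_five_point_hand_example(self):
        pred = [10.0, 30.0, 20.0, 50.0, 40.0]
        meas = [100.0, 200.0, 400.0, 300.0, 500.0]
        assert cs.spearman_rho(pred, meas) == pytest.approx(brute_spearman(pred, meas))

    def test_orientation_flag_flips_sign(self):
        pred = [1.0, 2.0, 3.0, 4.0]
        meas = [10.0, 20.0, 30.0, 40.0]
        lo = cs.spearman_rho(pred, meas, "lower-is-better")
        hi = cs.spearman_rho(pred, meas, "higher-is-better")
        assert lo == pytest.approx(-hi)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            cs.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ties_use_average_ranks(self):
        pred = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        meas = [5.0, 6.0, 7.0, 8.0, 8.0, 9.0]
        assert cs.spearman_rho(pred, meas) == pytest.approx(brute_spearman(pred, meas))


class TestFixedMethodEvaluation:
    def test_truth_matrix_on_noiseless_data_is_perfect(self):
        world = cs.SyntheticWorld(seed=3, noise_sigma=0.0)
        ds = cs.simulate_dataset(world, 200)
        row = cs.evaluate_fixed_method(cs.MatrixPredictor(world.truth, "truth"), ds)
        assert row.auc == pytest.approx(1.0)

    def test_all_ones_matrix_is_random_on_synthetic_data(self, bench_dataset):
        flat = cs.ScoringMatrix("X", np.ones((9, 20)))
        row = cs.evaluate_fixed_method(cs.MatrixPredictor(flat, "flat"), bench_dataset)
        assert row.auc == pytest.approx(0.5)  # all scores tie at 1.0
        assert np.isnan(row.rho)  # rank correlation undefined on constants

    def test_unavailable_method_reported_blank_not_zero(self):
        rows = [
            cs.EvalRow("HLA-A", "m1", "ALL", 100, 0.9, 0.8),
            cs.unavailable_row("HLA-B", "m1"),
        ]
        table = cs.summarize_report(rows)
        blank = table[table.allele == "HLA-B"].iloc[0]
        assert np.isnan(blank.auc) and np.isnan(blank.rho)
        # the average skips the blank cell instead of counting it as zero
        assert table[table.allele == "Average"].iloc[0].auc == pytest.approx(0.9)

    def test_report_summary_rows_are_arithmetic_means(self):
        rows = [
            cs.EvalRow("HLA-A", "m", "ALL", 10, 0.8124, 0.7),
            cs.EvalRow("HLA-B", "m", "ALL", 10, 0.9, 0.8),
        ]
        table = cs.summarize_report(rows)
        avg = table[table.allele == "Average"].iloc[0]
        assert avg.auc == pytest.approx(round((0.8124 + 0.9) / 2, 3))
        assert table[table.allele == "Min"].iloc[0].auc == pytest.approx(0.812)


class TestSPImpact:
    def test_no_homologs_means_zero_auc_difference(self):
        """With no similar peptides SR == ALL, so the paired AUCs are equal."""
        world = cs.SyntheticWorld(seed=9, mix=cs.HomologMix(1, 0, 0, 0))
        ds = cs.simulate_dataset(world, 150)
        assert cs.singular_peptides(ds) == ds.sequences
        result = cs.sp_impact_analysis(cs.BaselineTrainer(), ds, k=5, seed=0)
        row = result.table.iloc[0]
        assert row.auc_reduction == 0.0
        assert row.n_all == row.n_sr == row.n_sp == 150

    def test_report_shape_and_peptide_reduction_columns(self):
        """Reduction columns: |ALL| - |SP| and its fraction of |ALL|."""
        world = cs.SyntheticWorld(seed=10)
        ds = cs.simulate_dataset(world, 300)
        result = cs.sp_impact_analysis(cs.BaselineTrainer(), ds, k=5, seed=1)
        assert list(result.table.columns) == [
            "allele", "auc_sr", "auc_all", "auc_reduction",
            "n_all", "n_sr", "n_sp", "peptide_reduction", "pct_peptide_reduction",
        ]
        row = result.table.iloc[0]
        assert row.peptide_reduction == row.n_all - row.n_sp
        assert row.pct_peptide_reduction == pytest.approx(1 - row.n_sp / row.n_all)
        assert row.auc_reduction == pytest.approx(row.auc_all - row.auc_sr)
        assert row.n_sp < row.n_sr < row.n_all  # homologs were injected

    def test_single_class_sp_set_skipped_with_warning(self):
        records = [
            cs.AffinityRecord("HLA-X", s, 100.0)  # all binders
            for s in ["ACDEFGHIKLMNPQR", "WYWYWYWYWYWYWYW", "KLKLKLKLKLKLKLK"] * 7
        ]
        ds = cs.AffinityDataset.from_records("HLA-X", records)
        result = cs.sp_impact_analysis(cs.BaselineTrainer(), ds)
        assert result.skipped == ["HLA-X"]
        assert result.table.empty

    def test_paired_ttest_over_multiple_alleles(self):
        datasets = {}
        for i, seed in enumerate((21, 22, 23)):
            world = cs.SyntheticWorld(seed=seed, allele=f"SYN-{i}")
            datasets[f"SYN-{i}"] = cs.simulate_dataset(world, 200)
        result = cs.sp_impact_analysis(cs.BaselineTrainer(), datasets, k=5, seed=0)
        assert len(result.table) == 3
        diffs = result.table.auc_reduction
        if np.allclose(diffs, diffs.iloc[0]):
            assert np.isnan(result.p_value)
        else:
            assert 0.0 <= result.p_value <= 1.0
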
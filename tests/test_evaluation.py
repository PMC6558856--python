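"""Metrics arithmetic, CV protocol, paired tests, ablation and cross runs."""

import math

import numpy as np
import pytest
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from stackppi import evaluation, synthetic
from stackppi.evaluation import (
    ConfusionCounts,
    compute_metrics,
    cross_train_test,
    fold_assignment_hash,
    make_fold_assignments,
    paired_ttest,
    stratified_repeated_cv,
)
from stackppi.io import PpiDataset

from conftest import fast_config


def counts_to_vectors(c: ConfusionCounts):
    y_true = [1] * c.tp + [0] * c.tn + [0] * c.fp + [1] * c.fn
    y_pred = [1] * c.tp + [0] * c.tn + [1] * c.fp + [0] * c.fn
    return np.array(y_true), np.array(y_pred)


class TestComputeMetrics:
    def test_hand_worked_counts(self):
        rep = compute_metrics(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert rep.tpr == pytest.approx(9 / 11)
        assert rep.fpr == pytest.approx(1 / 9)
        assert rep.precision == pytest.approx(0.9)
        assert rep.accuracy == pytest.approx(17 / 20)
        assert rep.mcc == pytest.approx(70 / math.sqrt(9900))

    def test_perfect_classifier(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        rep = compute_metrics(
            ConfusionCounts(tp=2, tn=2, fp=0, fn=0), scores=scores, labels=labels
        )
        for m in ("tpr", "precision", "accuracy", "f_score", "mcc", "auc"):
            assert getattr(rep, m) == pytest.approx(1.0)
        assert rep.fpr == 0.0

    def test_constant_scores_give_half_auc(self):
        rep = compute_metrics(
            ConfusionCounts(tp=0, tn=3, fp=0, fn=3),
            scores=np.full(6, 0.7), labels=np.array([1, 1, 1, 0, 0, 0]),
        )
        assert rep.auc == pytest.approx(0.5)

    def test_undefined_ratios_flagged_not_fatal(self):
        rep = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert rep.precision == 0.0 and rep.tpr == 0.0
        assert "precision_undefined" in rep.flags

    def test_matches_sklearn_oracle_on_random_counts(self, rng):
        """1,000 random confusion tuples against the sklearn implementations."""
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 20, size=4))
            if tp + fn == 0 or tn + fp == 0 or tp + fp == 0 or tn + fn == 0:
                continue
            c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
            rep = compute_metrics(c)
            y_true, y_pred = counts_to_vectors(c)
            assert rep.accuracy == pytest.approx(accuracy_score(y_true, y_pred), abs=1e-9)
            assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-9)
            assert rep.tpr == pytest.approx(recall_score(y_true, y_pred), abs=1e-9)
            assert rep.precision == pytest.approx(precision_score(y_true, y_pred), abs=1e-9)
            assert rep.f_score == pytest.approx(f1_score(y_true, y_pred), abs=1e-9)
            tn_, fp_, fn_, tp_ = confusion_matrix(y_true, y_pred).ravel()
            assert rep.fpr == pytest.approx(fp_ / (fp_ + tn_), abs=1e-9)

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)
        c = ConfusionCounts(1, 1, 1, 1)
        a1 = compute_metrics(c, scores=scores, labels=labels).auc
        a2 = compute_metrics(c, scores=np.exp(3 * scores) + 5, labels=labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestFoldAssignments:
    def test_stratification_preserves_class_ratio(self):
        labels = [1] * 50 + [0] * 50
        assignments = make_fold_assignments(labels, repeats=1, folds=10, seed=0)
        for _, test_idx in assignments[0]:
            arr = np.array(labels)[test_idx]
            assert arr.sum() == 5 and len(arr) == 10

    def test_repeats_differ_and_are_seeded(self):
        labels = [1] * 20 + [0] * 20
        a1 = make_fold_assignments(labels, 2, 5, seed=3)
        a2 = make_fold_assignments(labels, 2, 5, seed=3)
        assert fold_assignment_hash(a1) == fold_assignment_hash(a2)
        assert fold_assignment_hash([a1[0]]) != fold_assignment_hash([a1[1]])

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            make_fold_assignments([1] * 5 + [0] * 50, 1, 10, seed=0)


class TestPairedTTest:
    def test_identical_series_not_significant(self):
        t, p, sig = paired_ttest([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert p == 1.0 and not sig

    def test_shift_much_larger_than_noise_significant(self, rng):
        a = rng.normal(0.9, 0.01, size=10)
        b = a - 0.5 + rng.normal(0.0, 0.01, size=10)
        t, p, sig = paired_ttest(a, b)
        assert sig and p < 1e-6

    def test_matches_closed_form(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a, b = rng.normal(size=n), rng.normal(size=n)
            d = a - b
            if np.isclose(d.std(ddof=1), 0):
                continue
            t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            t, p, _ = paired_ttest(a, b)
            assert t == pytest.approx(t_expected, rel=1e-9)
            assert 0.0 <= p <= 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_ttest([1.0, 2.0], [1.0])


@pytest.fixture(scope="module")
def tiny_dataset():
    return synthetic.generate_dataset(
        synthetic.SyntheticConfig(
            seed=4, n_proteins=40, n_pairs=60, seq_length_range=(30, 60),
            ontologies=("BP",),
        )
    )


def protocol_config(**overrides):
    """Minimal-cost configuration for exercising the CV bookkeeping."""
    return fast_config(
        feature_blocks=("F2",), base_classifiers=("nb", "knn"),
        internal_folds=2, svm_c_grid=(1.0,), meta_cv_folds=2, **overrides,
    )


class TestCvProtocol:
    def test_three_by_ten_produces_thirty_reports(self, tiny_dataset):
        res = stratified_repeated_cv(
            tiny_dataset, protocol_config(seed=4), repeats=3, folds=10
        )
        assert len(res.reports) == 30
        assert {(r.repeat, r.fold) for r in res.reports} == {
            (r, f) for r in range(3) for f in range(10)
        }
        # pooled mean is the average of the per-run reports
        assert res.pooled_mean["auc"] == pytest.approx(
            float(np.mean(res.metric_series("auc")))
        )

    def test_every_pair_predicted_once_per_repeat(self, tiny_dataset):
        res = stratified_repeated_cv(
            tiny_dataset, protocol_config(seed=4), repeats=2, folds=5
        )
        assert len(res.predictions) == 2 * len(tiny_dataset.pairs)


class TestAblation:
    def test_seven_rows_with_paired_folds(self, tiny_dataset):
        results = evaluation.ablation_run(
            tiny_dataset, protocol_config(seed=4), folds=3
        )
        assert len(results) == 7
        hashes = {res.fold_hash for res in results.values()}
        assert len(hashes) == 1
        assert ("F1", "F2", "F3") in results

    def test_empty_subset_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            evaluation.ablation_run(tiny_dataset, protocol_config(), subsets=[()])


class TestCrossTrainTest:
    def test_self_test_pathway_runs_and_is_deterministic(self, tiny_dataset):
        """train = test exercises the same code path as a cross run."""
        r1 = cross_train_test(tiny_dataset, tiny_dataset, protocol_config(seed=4))
        r2 = cross_train_test(tiny_dataset, tiny_dataset, protocol_config(seed=4))
        assert r1.values() == r2.values()
        assert all(0.0 <= r1.values()[m] <= 1.0 for m in r1.values())

    def test_unseen_test_proteins_degrade_gracefully(self, tiny_dataset):
        other = synthetic.generate_dataset(
            synthetic.SyntheticConfig(
                seed=11, n_proteins=30, n_pairs=40, ontologies=("BP",),
            )
        )
        # evaluate on pairs of proteins the training network never saw,
        # but within the training ontology
        test_ds = PpiDataset(
            sequences=other.sequences,
            dags=tiny_dataset.dags,
            annotations={
                "BP": {
                    p: set(np.random.default_rng(0).choice(
                        sorted(tiny_dataset.dags["BP"].terms), size=2))
                    for p in other.sequences
                }
            },
            pairs=other.pairs,
        )
        rep = cross_train_test(
            tiny_dataset, test_ds, protocol_config(seed=4)
        )
        assert 0.0 <= rep.auc <= 1.0

    def test_two_species_from_shared_world_transfer(self):
        """Training on one species generalizes to another sharing the ontology."""
        cfg = protocol_config(seed=6)
        a, b = synthetic.generate_related_datasets(
            synthetic.SyntheticConfig(
                seed=6, n_proteins=40, n_pairs=60, ontologies=("BP",)
            )
        )
        cross_rep = cross_train_test(a, b, cfg)
        assert cross_rep.auc > 0.7  # the conserved-module signal transfers
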
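"""Stacked generalization: meta-data, fitting, symmetry, leakage, round-trip."""

import numpy as np
import pytest

from stackppi import stacking, synthetic
from stackppi.io import PpiDataset
from stackppi.stacking import build_meta_data, _select_tau, _binary_mcc

from conftest import fast_config


def gaussian_instances(rng, n_pairs=30, shift=5.0):
    """Trivially separable instance rows: two rows per pair, labels balanced."""
    X, y, pair_index = [], [], []
    for i in range(n_pairs):
        label = i % 2
        center = shift if label else -shift
        for _ in range(2):
            X.append(rng.normal(loc=center, size=4))
            y.append(label)
            pair_index.append(i)
    return np.array(X), np.array(y), np.array(pair_index)


class TestBuildMetaData:
    def test_shape_is_rows_by_bases(self, rng):
        X, y, idx = gaussian_instances(rng)
        cfg = fast_config()
        meta = build_meta_data(X, y, idx, cfg, seed=0)
        assert meta.shape == (len(y), len(cfg.base_classifiers))
        assert np.all((meta >= 0) & (meta <= 1))

    def test_separable_data_gives_confident_meta_features(self, rng):
        X, y, idx = gaussian_instances(rng, shift=8.0)
        meta = build_meta_data(X, y, idx, fast_config(), seed=0)
        assert meta[y == 1].mean() > 0.8
        assert meta[y == 0].mean() < 0.2

    def test_rows_of_one_pair_share_fold(self, rng):
        """Duplicate rows of one pair get identical out-of-fold predictions."""
        X, y, idx = gaussian_instances(rng)
        X[1::2] = X[0::2]  # make both rows of each pair identical
        meta = build_meta_data(X, y, idx, fast_config(), seed=0)
        assert np.allclose(meta[0::2], meta[1::2])

    def test_stratification_failure_reported(self, rng):
        X, y, idx = gaussian_instances(rng, n_pairs=4)
        with pytest.raises(ValueError, match="stratification"):
            build_meta_data(X, y, idx, fast_config(internal_folds=5), seed=0)


class TestTauSelection:
    def test_tau_is_mcc_argmax(self, rng):
        probs = rng.random(60)
        labels = (probs + rng.normal(scale=0.2, size=60) > 0.5).astype(int)
        tau = _select_tau(probs, labels)
        mcc_at_tau = _binary_mcc(labels, (probs >= tau).astype(int))
        for cut in np.linspace(0.05, 0.95, 19):
            assert mcc_at_tau >= _binary_mcc(labels, (probs >= cut).astype(int)) - 1e-12

    def test_ties_prefer_smaller_threshold(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        # midpoints 0.5 and 0.85 both separate perfectly; the smaller wins
        assert _select_tau(probs, labels) == pytest.approx(0.5)


class TestFit:
    def test_model_training_mcc_at_tau_beats_default_cut(self, small_model, small_dataset):
        model, ds = small_model, small_dataset
        pairs = [(a, b) for a, b, _ in ds.pairs]
        probs, _ = model.predict_pairs(ds, pairs)
        labels = np.array(ds.labels)
        mcc_tau = _binary_mcc(labels, (probs >= model.tau).astype(int))
        mcc_half = _binary_mcc(labels, (probs >= 0.5).astype(int))
        assert mcc_tau >= mcc_half - 1e-12

    def test_refit_same_seed_reproduces_tau(self, small_dataset):
        m1 = stacking.fit(small_dataset, fast_config(seed=7))
        m2 = stacking.fit(small_dataset, fast_config(seed=7))
        assert m1.tau == m2.tau
        assert m1.meta_c == m2.meta_c

    def test_single_class_training_rejected(self, small_dataset):
        ds = PpiDataset(
            sequences=small_dataset.sequences,
            dags=small_dataset.dags,
            annotations=small_dataset.annotations,
            pairs=[p for p in small_dataset.pairs if p[2] == 1],
        )
        with pytest.raises(ValueError, match="both classes"):
            stacking.fit(ds, fast_config())

    @pytest.mark.parametrize(
        "blocks", [("F1",), ("F2",), ("F1", "F2", "F3")],
        ids=["F1", "F2", "F1F2F3"],
    )
    def test_feature_ablation_configs_fit(self, small_dataset, blocks):
        model = stacking.fit(small_dataset, fast_config(feature_blocks=blocks))
        a, b, _ = small_dataset.pairs[0]
        prob, label = model.predict_pair(small_dataset, a, b)
        assert 0.0 <= prob <= 1.0 and label in (0, 1)

    def test_single_base_classifier_degenerates_gracefully(self, small_dataset):
        model = stacking.fit(
            small_dataset, fast_config(base_classifiers=("nb",))
        )
        a, b, _ = small_dataset.pairs[0]
        prob, _ = model.predict_pair(small_dataset, a, b)
        assert 0.0 <= prob <= 1.0

    def test_manifest_records_fitted_statistics(self, small_model):
        man = small_model.manifest
        assert man["n_training_instances"] == 2 * man["n_training_pairs"]
        assert set(man["f2_feature_counts"]) == {"BP", "CC", "MF"}
        assert man["theta_r"] is not None and man["tau"] == small_model.tau


class TestPredict:
    def test_prediction_symmetry_is_exact(self, small_model, small_dataset):
        for a, b, _ in small_dataset.pairs[:10]:
            pab, lab = small_model.predict_pair(small_dataset, a, b)
            pba, lba = small_model.predict_pair(small_dataset, b, a)
            assert pab == pba and lab == lba

    def test_probabilities_in_unit_interval(self, small_model, small_dataset):
        pairs = [(a, b) for a, b, _ in small_dataset.pairs]
        probs, _ = small_model.predict_pairs(small_dataset, pairs)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_unknown_protein_degrades_to_zero_features(self, small_model, small_dataset):
        prob, label = small_model.predict_pair(small_dataset, "NOVEL1", "NOVEL2")
        assert 0.0 <= prob <= 1.0 and label in (0, 1)

    def test_heldout_accuracy_on_separable_data(self):
        ds = synthetic.generate_dataset(
            synthetic.SyntheticConfig(
                seed=1, n_pairs=200, signal=1.0, motif_rate=1.0,
                annotation_noise=0.0,
            )
        )
        n = len(ds.pairs)
        rng = np.random.default_rng(0)
        order = rng.permutation(n)
        train_idx, test_idx = order[: int(0.8 * n)], order[int(0.8 * n):]
        model = stacking.fit(ds.subset(train_idx), fast_config())
        test_pairs = [(ds.pairs[i][0], ds.pairs[i][1]) for i in test_idx]
        probs, preds = model.predict_pairs(ds, test_pairs)
        truth = np.array([ds.pairs[i][2] for i in test_idx])
        assert (preds == truth).mean() > 0.95


class TestLeakageAndPersistence:
    def test_fitting_ignores_pairs_outside_training_split(self, small_dataset):
        """Adding unseen extra pairs to the container must not change the fit."""
        ds = small_dataset
        extra = synthetic.generate_dataset(
            synthetic.SyntheticConfig(seed=9, n_proteins=40, n_pairs=40)
        )
        combined = PpiDataset(
            sequences={**ds.sequences, **{f"X{p}": s for p, s in extra.sequences.items()}},
            dags=ds.dags,
            annotations=ds.annotations,
            pairs=ds.pairs + [(f"X{a}", f"X{b}", y) for a, b, y in extra.pairs],
        )
        train_idx = list(range(len(ds.pairs)))
        m1 = stacking.fit(ds, fast_config(seed=3))
        m2 = stacking.fit(combined.subset(train_idx), fast_config(seed=3))
        pairs = [(a, b) for a, b, _ in ds.pairs]
        p1, _ = m1.predict_pairs(ds, pairs)
        p2, _ = m2.predict_pairs(ds, pairs)
        assert np.array_equal(p1, p2)
        assert m1.tau == m2.tau

    def test_save_load_round_trip(self, small_model, small_dataset, tmp_path):
        path = tmp_path / "model.joblib"
        small_model.save(path)
        loaded = stacking.StackedModel.load(path)
        pairs = [(a, b) for a, b, _ in small_dataset.pairs[:5]]
        p1, _ = small_model.predict_pairs(small_dataset, pairs)
        p2, _ = loaded.predict_pairs(small_dataset, pairs)
        assert np.array_equal(p1, p2)

    def test_stack_not_much_worse_than_best_base(self, small_model, small_dataset):
        """Soft synergy property on the meta-training data."""
        model, ds = small_model, small_dataset
        labels = np.array(ds.labels)
        pairs = [(a, b) for a, b, _ in ds.pairs]
        meta = model._meta_rows(ds, pairs)
        base_mccs = []
        for j in range(meta.shape[1]):
            probs = 0.5 * (meta[0::2, j] + meta[1::2, j])
            base_mccs.append(_binary_mcc(labels, (probs >= 0.5).astype(int)))
        probs, _ = model.predict_pairs(ds, pairs)
        stack_mcc = _binary_mcc(labels, (probs >= model.tau).astype(int))
        assert stack_mcc >= max(base_mccs) - 0.1
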
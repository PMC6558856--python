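"""Two-level stacked generalization for PPI prediction.

Level one trains four base classifiers (random forest, Gaussian naive
Bayes, a single-hidden-layer neural network, and k-nearest neighbors) on
protein-pair feature vectors [F1 || F2 || F3]; their out-of-fold predicted
interacting-class probabilities form the meta-data on which a level-two
RBF-kernel SVM is trained.  Every training-derived statistic (feature
normalizers, the GO DAG partition, the IC table, the similarity network and
its threshold, the decision threshold tau) is fitted strictly inside the
training split.

Each pair contributes two training instances, one per concatenation order
of the F1 block; prediction feeds both orders through the stack and
averages the two meta probabilities, which makes predictions exactly
symmetric under argument swap.  The decision threshold tau on the averaged
meta probability is the value maximizing the Matthews correlation
coefficient on the training pairs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import physchem, semnet
from .go_features import GoDag, LcaPartition, encode_pair, partition_dag
from .io import PpiDataset, RunConfig
from .physchem import AcConfig, Normalizer, PhyschemScaleTable, ProteinRecord
from .semnet import IcTable

logger = logging.getLogger("stackppi")

BASE_CLASSIFIER_NAMES = ("rf", "nb", "ann", "knn")


def _mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _binary_mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return _mcc(tp, tn, fp, fn)


# ---------------------------------------------------------------------------
# featurization


class PairFeaturizer:
    """Fits the three feature blocks on a training split and encodes pairs.

    F1: per-protein AC vectors (normalized), paired in both orders.
    F2: per-ontology LCA-cluster encodings, concatenated across ontologies.
    F3: the five topology features on the thresholded similarity network.
    F2 and F3 pass through the same fit-on-train standardize+min-max scaling
    as F1; both are identical for the two orders of a pair.
    """

    def __init__(self, config: RunConfig, scale_table: PhyschemScaleTable | None = None):
        self.config = config
        self.table = scale_table or PhyschemScaleTable.default()
        self.use_f1 = "F1" in config.feature_blocks
        self.use_f2 = "F2" in config.feature_blocks
        self.use_f3 = "F3" in config.feature_blocks

    # -- fitting ------------------------------------------------------------

    def fit(self, dataset: PpiDataset) -> "PairFeaturizer":
        train_proteins = dataset.pair_proteins()
        self.ontologies_: tuple[str, ...] = tuple(
            o for o in (self.config.ontologies or sorted(dataset.dags))
            if o in dataset.dags
        )
        if self.use_f1:
            self._fit_f1(dataset, train_proteins)
        if self.use_f2:
            self._fit_f2(dataset)
        if self.use_f3:
            self._fit_f3(dataset, train_proteins)
        return self

    def _fit_f1(self, dataset: PpiDataset, train_proteins: Sequence[str]) -> None:
        lengths = [
            len(dataset.sequences[p]) for p in train_proteins if p in dataset.sequences
        ]
        if not lengths:
            raise ValueError("F1 enabled but no training protein has a sequence")
        gap = min(self.config.ac_max_gap, max(min(lengths) - 1, 1))
        if gap < self.config.ac_max_gap:
            logger.warning(
                "max AC gap capped at %d (min training sequence length %d)",
                gap, min(lengths),
            )
        self.ac_config_ = AcConfig(max_gap=gap)
        vectors = {}
        for pid in train_proteins:
            seq = dataset.sequences.get(pid)
            if seq:
                rec = ProteinRecord(pid, seq)
                vectors[pid] = physchem.encode_protein(rec, self.table, self.ac_config_).values
        self.f1_normalizer_ = Normalizer().fit(np.array(list(vectors.values())))
        self._f1_cache = {
            pid: self.f1_normalizer_.transform(v) for pid, v in vectors.items()
        }

    def _fit_f2(self, dataset: PpiDataset) -> None:
        self.partitions_: dict[str, LcaPartition] = {}
        for ont in self.ontologies_:
            per_protein = dataset.annotations.get(ont, {})
            pair_terms = [
                (per_protein.get(a, set()), per_protein.get(b, set()))
                for a, b, _ in dataset.pairs
            ]
            try:
                self.partitions_[ont] = partition_dag(dataset.dags[ont], pair_terms)
            except ValueError:
                logger.warning("no computable LCA in ontology %s; block skipped", ont)
        if not self.partitions_:
            raise ValueError("F2 enabled but no ontology produced a partition")
        raw = np.array([
            self._raw_f2(dataset, a, b) for a, b, _ in dataset.pairs
        ])
        self.f2_normalizer_ = Normalizer().fit(raw)

    def _raw_f2(self, dataset: PpiDataset, a: str, b: str) -> np.ndarray:
        blocks = []
        for ont, partition in self.partitions_.items():
            per_protein = dataset.annotations.get(ont, {})
            blocks.append(
                encode_pair(
                    partition, dataset.dags[ont],
                    per_protein.get(a, set()), per_protein.get(b, set()),
                )
            )
        return np.concatenate(blocks).astype(float)

    def _fit_f3(self, dataset: PpiDataset, train_proteins: Sequence[str]) -> None:
        train_set = set(train_proteins)
        self.ic_tables_ = {
            ont: IcTable(
                dataset.dags[ont],
                {
                    p: ts
                    for p, ts in dataset.annotations.get(ont, {}).items()
                    if p in train_set
                },
            )
            for ont in self.ontologies_
        }
        sims = semnet.all_pair_similarities(
            list(train_proteins), self.ic_tables_, dataset.annotations
        )
        n_s = semnet.build_reference_network(
            train_proteins, [(a, b) for a, b, y in dataset.pairs if y == 1]
        )
        self.theta_ = semnet.select_threshold(sims, n_s)
        self.network_ = semnet.build_similarity_network(
            list(train_proteins), sims, self.theta_
        )
        self.reference_network_ = n_s
        raw = np.array([
            semnet.topology_features(self.network_, a, b) for a, b, _ in dataset.pairs
        ])
        self.f3_normalizer_ = Normalizer().fit(raw)

    # -- encoding -----------------------------------------------------------

    def _f1_vector(self, dataset: PpiDataset, pid: str) -> np.ndarray:
        if pid in self._f1_cache:
            return self._f1_cache[pid]
        seq = dataset.sequences.get(pid)
        if not seq:
            logger.warning("protein %r has no sequence; F1 block zeroed", pid)
            return np.zeros(self.f1_normalizer_.n_features)
        rec = ProteinRecord(pid, seq)
        vec = physchem.encode_protein(rec, self.table, self.ac_config_).values
        return self.f1_normalizer_.transform(vec)

    def shared_blocks(self, dataset: PpiDataset, a: str, b: str) -> np.ndarray:
        """The order-independent [F2 || F3] part of a pair's features."""
        blocks = []
        if self.use_f2:
            blocks.append(self.f2_normalizer_.transform(self._raw_f2(dataset, a, b)))
        if self.use_f3:
            blocks.append(
                self.f3_normalizer_.transform(
                    semnet.topology_features(self.network_, a, b)
                )
            )
        return np.concatenate(blocks) if blocks else np.empty(0)

    def pair_rows(
        self, dataset: PpiDataset, a: str, b: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Both concatenation-order instances of a pair: (row_ab, row_ba)."""
        shared = self.shared_blocks(dataset, a, b)
        if self.use_f1:
            va, vb = self._f1_vector(dataset, a), self._f1_vector(dataset, b)
            ab, ba = physchem.pair_vectors(va, vb)
            return np.concatenate([ab, shared]), np.concatenate([ba, shared])
        return shared.copy(), shared.copy()

    def f2_feature_counts(self) -> dict[str, int]:
        if not self.use_f2:
            return {}
        return {o: p.n_features for o, p in self.partitions_.items()}


# ---------------------------------------------------------------------------
# base classifiers and meta-data


def make_base_classifier(name: str, config: RunConfig, seed: int, n_samples: int):
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=config.rf_n_estimators, random_state=seed, n_jobs=1
        )
    if name == "nb":
        return GaussianNB()
    if name == "ann":
        # early stopping needs a meaningful validation split; below 100
        # samples the 10% holdout is too small to steer it
        return MLPClassifier(
            hidden_layer_sizes=(config.ann_hidden_units,),
            early_stopping=n_samples >= 100,
            max_iter=config.ann_max_iter,
            random_state=seed,
        )
    if name == "knn":
        return KNeighborsClassifier(
            n_neighbors=min(config.knn_neighbors, max(n_samples - 1, 1)),
            weights="distance",
        )
    raise ValueError(f"unknown base classifier {name!r}")


def _positive_proba(estimator, X: np.ndarray) -> np.ndarray:
    proba = estimator.predict_proba(X)
    classes = list(estimator.classes_)
    if 1 not in classes:
        return np.zeros(X.shape[0])
    return proba[:, classes.index(1)]


def _pair_folds(labels: np.ndarray, n_folds: int, seed: int):
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratification failure: class counts {counts.tolist()} cannot "
            f"fill {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def build_meta_data(
    X: np.ndarray,
    y: np.ndarray,
    pair_index: np.ndarray,
    config: RunConfig,
    seed: int,
) -> np.ndarray:
    """Out-of-fold base-classifier probabilities for every training instance.

    Folds are assigned at the pair level (both concatenation orders of a
    pair land in the same fold), stratified by label, so no base model ever
    scores an instance it was trained on.
    """
    n_pairs = int(pair_index.max()) + 1
    pair_labels = np.zeros(n_pairs, dtype=int)
    pair_labels[pair_index] = y
    folds = _pair_folds(pair_labels, config.internal_folds, seed)
    meta = np.zeros((X.shape[0], len(config.base_classifiers)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_pairs, val_pairs in folds:
            train_rows = np.isin(pair_index, train_pairs)
            val_rows = np.isin(pair_index, val_pairs)
            for j, name in enumerate(config.base_classifiers):
                est = make_base_classifier(name, config, seed, int(train_rows.sum()))
                est.fit(X[train_rows], y[train_rows])
                meta[val_rows, j] = _positive_proba(est, X[val_rows])
    return meta


def _select_meta_svm(
    meta: np.ndarray, y: np.ndarray, config: RunConfig, seed: int
) -> tuple[float, object]:
    """Grid search (C, gamma) for the meta SVM by internal CV MCC."""
    best = None
    counts = np.bincount(y, minlength=2)
    n_folds = min(config.meta_cv_folds, int(counts.min()))
    if n_folds < 2:
        raise ValueError("too few instances per class for meta-SVM selection")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(meta, y))
    for c in config.svm_c_grid:
        for gamma in config.svm_gamma_grid:
            scores = []
            for tr, va in splits:
                est = SVC(C=c, gamma=gamma, kernel="rbf")
                est.fit(meta[tr], y[tr])
                scores.append(_binary_mcc(y[va], est.predict(meta[va])))
            score = float(np.mean(scores))
            if best is None or score > best[0]:
                best = (score, c, gamma)
    return best[1], best[2]


def _select_tau(probs: np.ndarray, labels: np.ndarray) -> float:
    """Training-MCC-maximizing threshold on the meta probability.

    Candidates are the midpoints between consecutive unique training
    probabilities (plus the minimum itself, i.e. predict-all-positive):
    every achievable training confusion is covered, while the chosen cut
    sits centered between the two classes instead of exactly on an observed
    training score.  Ties in MCC prefer the smaller threshold (higher
    sensitivity).
    """
    uniq = np.unique(probs)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0])
    best_tau, best_mcc = 0.5, -2.0
    for tau in candidates:
        mcc = _binary_mcc(labels, (probs >= tau).astype(int))
        if mcc > best_mcc:
            best_tau, best_mcc = float(tau), mcc
    return best_tau


# ---------------------------------------------------------------------------
# the stacked model


@dataclass
class StackedModel:
    """A fully fitted two-level stack plus its training-derived statistics."""

    config: RunConfig
    featurizer: PairFeaturizer
    base_models: dict[str, object]
    meta_model: CalibratedClassifierCV
    tau: float
    meta_c: float
    meta_gamma: object
    seed: int
    manifest: dict = field(default_factory=dict)

    def _meta_rows(self, dataset: PpiDataset, pairs: Sequence[tuple[str, str]]):
        rows = []
        for a, b in pairs:
            ab, ba = self.featurizer.pair_rows(dataset, a, b)
            rows.extend([ab, ba])
        X = np.array(rows)
        meta = np.column_stack(
            [_positive_proba(self.base_models[n], X) for n in self.config.base_classifiers]
        )
        return meta

    def predict_pairs(
        self, dataset: PpiDataset, pairs: Sequence[tuple[str, str]]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Averaged interacting-class probability and label for each pair."""
        if not pairs:
            return np.empty(0), np.empty(0, dtype=int)
        meta = self._meta_rows(dataset, pairs)
        row_probs = self.meta_model.predict_proba(meta)
        classes = list(self.meta_model.classes_)
        pos = row_probs[:, classes.index(1)]
        probs = 0.5 * (pos[0::2] + pos[1::2])
        return probs, (probs >= self.tau).astype(int)

    def predict_pair(self, dataset: PpiDataset, a: str, b: str) -> tuple[float, int]:
        probs, labels = self.predict_pairs(dataset, [(a, b)])
        return float(probs[0]), int(labels[0])

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "StackedModel":
        return joblib.load(path)


def fit(dataset: PpiDataset, config: RunConfig | None = None, seed: int | None = None) -> StackedModel:
    """Fit the full pipeline on a training dataset.

    Order: feature normalizers -> DAG partition -> IC/network/theta ->
    out-of-fold meta-data -> base refits -> meta SVM grid search -> tau.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    labels = np.array(dataset.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")

    featurizer = PairFeaturizer(config).fit(dataset)

    rows, y_rows, pair_index = [], [], []
    for i, (a, b, label) in enumerate(dataset.pairs):
        ab, ba = featurizer.pair_rows(dataset, a, b)
        rows.extend([ab, ba])
        y_rows.extend([label, label])
        pair_index.extend([i, i])
    X = np.array(rows)
    y = np.array(y_rows)
    pair_index = np.array(pair_index)

    meta = build_meta_data(X, y, pair_index, config, seed)

    base_models = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for name in config.base_classifiers:
            est = make_base_classifier(name, config, seed, X.shape[0])
            est.fit(X, y)
            base_models[name] = est

        meta_c, meta_gamma = _select_meta_svm(meta, y, config, seed)
        # sigmoid-calibrated RBF SVM so the meta decision is probabilistic
        calib_folds = min(5, int(np.bincount(y, minlength=2).min()))
        meta_model = CalibratedClassifierCV(
            SVC(C=meta_c, gamma=meta_gamma, kernel="rbf"),
            method="sigmoid", cv=calib_folds, ensemble=False,
        )
        meta_model.fit(meta, y)

    # tau on the training pairs' averaged meta probabilities
    classes = list(meta_model.classes_)
    row_probs = meta_model.predict_proba(meta)[:, classes.index(1)]
    pair_probs = 0.5 * (row_probs[0::2] + row_probs[1::2])
    tau = _select_tau(pair_probs, labels)

    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "n_training_pairs": len(dataset.pairs),
        "n_training_instances": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "meta_svm": {"C": meta_c, "gamma": meta_gamma},
        "tau": tau,
        "f2_feature_counts": featurizer.f2_feature_counts(),
        "theta_r": getattr(featurizer, "theta_", None),
        "ac_max_gap": featurizer.ac_config_.max_gap if featurizer.use_f1 else None,
    }
    return StackedModel(
        config=config,
        featurizer=featurizer,
        base_models=base_models,
        meta_model=meta_model,
        tau=tau,
        meta_c=meta_c,
        meta_gamma=meta_gamma,
        seed=seed,
        manifest=manifest,
    )
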
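"""Evaluation protocol: seven metrics, repeated stratified CV, paired t-tests,
feature-ablation and cross-dataset drivers.

Thresholded metrics (TPR, FPR, precision, accuracy, F-score, MCC) are exact
confusion-count arithmetic; AUC is the rank-based (Mann-Whitney, tie
corrected) ROC area computed from the continuous scores.  Cross-validation
is stratified k-fold repeated with seeds seed, seed+1, ...; every
training-derived artifact is refitted inside each training split.  Pooled
results are the mean of per-run metrics (primary) with metrics of the
pooled predictions emitted as a secondary diagnostic.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import stacking
from .io import PpiDataset, RunConfig

logger = logging.getLogger("stackppi")

METRIC_NAMES = ("tpr", "fpr", "precision", "accuracy", "f_score", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricReport:
    tpr: float
    fpr: float
    precision: float
    accuracy: float
    f_score: float
    mcc: float
    auc: float
    repeat: int | None = None
    fold: int | None = None
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def values(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"{name}_undefined")
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    repeat: int | None = None,
    fold: int | None = None,
) -> MetricReport:
    """The seven performance measures from counts plus (for AUC) raw scores.

    Undefined ratios (e.g. no predicted positives) are reported as 0 with a
    flag rather than aborting the run.
    """
    flags: list[str] = []
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    tpr = _ratio(tp, tp + fn, "tpr", flags)
    fpr = _ratio(fp, fp + tn, "fpr", flags)
    precision = _ratio(tp, tp + fp, "precision", flags)
    accuracy = _ratio(tp + tn, counts.total, "accuracy", flags)
    f_score = _ratio(2 * tpr * precision, tpr + precision, "f_score", flags)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.append("mcc_undefined")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    if scores is None or labels is None:
        flags.append("auc_not_computed")
        auc = 0.0
    else:
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            flags.append("auc_undefined")
            auc = 0.0
        else:
            auc = float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
    return MetricReport(
        tpr=tpr, fpr=fpr, precision=precision, accuracy=accuracy,
        f_score=f_score, mcc=mcc, auc=auc, repeat=repeat, fold=fold,
        flags=tuple(flags),
    )


def evaluate_predictions(
    y_true: np.ndarray,
    scores: np.ndarray,
    tau: float,
    repeat: int | None = None,
    fold: int | None = None,
) -> MetricReport:
    y_pred = (np.asarray(scores) >= tau).astype(int)
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    return compute_metrics(counts, scores=scores, labels=y_true, repeat=repeat, fold=fold)


# ---------------------------------------------------------------------------
# cross-validation protocol


def make_fold_assignments(
    labels: Sequence[int], repeats: int, folds: int, seed: int
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified fold index sets; repeat r uses seed + r."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"class counts {counts.tolist()} too small to stratify into {folds} folds"
        )
    assignments = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        assignments.append(list(skf.split(np.zeros(len(labels)), labels)))
    return assignments


def fold_assignment_hash(assignments) -> str:
    h = hashlib.sha256()
    for repeat in assignments:
        for train_idx, test_idx in repeat:
            h.update(np.asarray(train_idx, dtype=np.int64).tobytes())
            h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
    return h.hexdigest()


@dataclass
class CvResult:
    reports: list[MetricReport]
    pooled_mean: dict[str, float]
    pooled_prediction: MetricReport
    fold_hash: str
    predictions: list[tuple[int, float, int]] = field(repr=False, default_factory=list)

    def metric_series(self, metric: str) -> np.ndarray:
        return np.array([getattr(r, metric) for r in self.reports])


def stratified_repeated_cv(
    dataset: PpiDataset,
    config: RunConfig | None = None,
    repeats: int | None = None,
    folds: int | None = None,
    seed: int | None = None,
    assignments=None,
) -> CvResult:
    """Repeated stratified k-fold CV of the full pipeline.

    Every artifact (normalizers, partition, network, theta, tau, meta
    hyperparameters) is refitted inside each training split; the per-fold
    reports are pooled by averaging (primary) and by metrics of the pooled
    predictions (secondary diagnostic).
    """
    config = config or RunConfig()
    repeats = config.cv_repeats if repeats is None else repeats
    folds = config.cv_folds if folds is None else folds
    seed = config.seed if seed is None else seed
    labels = np.array(dataset.labels)
    if assignments is None:
        assignments = make_fold_assignments(labels, repeats, folds, seed)
    reports: list[MetricReport] = []
    all_pred: list[tuple[int, float, int]] = []
    for r, repeat_folds in enumerate(assignments):
        for f, (train_idx, test_idx) in enumerate(repeat_folds):
            train_ds = dataset.subset(train_idx)
            model = stacking.fit(train_ds, config, seed=seed + r)
            test_pairs = [(dataset.pairs[i][0], dataset.pairs[i][1]) for i in test_idx]
            probs, preds = model.predict_pairs(dataset, test_pairs)
            y_true = labels[test_idx]
            reports.append(
                evaluate_predictions(y_true, probs, model.tau, repeat=r, fold=f)
            )
            all_pred.extend(
                (int(t), float(p), int(hp))
                for t, p, hp in zip(y_true, probs, preds)
            )
    pooled_mean = {
        m: float(np.mean([getattr(rep, m) for rep in reports])) for m in METRIC_NAMES
    }
    yt = np.array([t for t, _, _ in all_pred])
    ps = np.array([p for _, p, _ in all_pred])
    hp = np.array([h for _, _, h in all_pred])
    pooled_prediction = compute_metrics(
        ConfusionCounts.from_predictions(yt, hp), scores=ps, labels=yt
    )
    return CvResult(
        reports=reports,
        pooled_mean=pooled_mean,
        pooled_prediction=pooled_prediction,
        fold_hash=fold_assignment_hash(assignments),
        predictions=all_pred,
    )


def paired_ttest(
    series_a: Sequence[float], series_b: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sided paired t-test on equal-length metric series.

    Returns (t statistic, p value, significant at alpha).  Zero-variance
    difference series yield p = 1 with t = 0 (flagged by the caller via the
    degenerate p).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        logger.warning("paired t-test on zero-variance differences; p set to 1")
        return 0.0, 1.0, False
    t_stat, p_value = stats.ttest_rel(a, b)
    return float(t_stat), float(p_value), bool(p_value < alpha)


def ablation_run(
    dataset: PpiDataset,
    config: RunConfig | None = None,
    subsets: Sequence[tuple[str, ...]] | None = None,
    repeats: int = 1,
    folds: int = 10,
    seed: int | None = None,
) -> dict[tuple[str, ...], CvResult]:
    """CV once per feature subset, with identical fold assignments throughout,
    so the per-fold series are directly comparable in paired tests."""
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    if subsets is None:
        subsets = [
            ("F1",), ("F2",), ("F3",),
            ("F1", "F2"), ("F1", "F3"), ("F2", "F3"),
            ("F1", "F2", "F3"),
        ]
    if any(not s for s in subsets):
        raise ValueError("feature subsets must be non-empty")
    assignments = make_fold_assignments(dataset.labels, repeats, folds, seed)
    results = {}
    for subset in subsets:
        sub_config = RunConfig(**{**config.to_dict(), "feature_blocks": tuple(subset)})
        results[tuple(subset)] = stratified_repeated_cv(
            dataset, sub_config, repeats=repeats, folds=folds, seed=seed,
            assignments=assignments,
        )
    return results


def cross_train_test(
    train_dataset: PpiDataset,
    test_dataset: PpiDataset,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> MetricReport:
    """Fit wholly on one dataset and evaluate once on another.

    Both datasets must share the feature configuration (e.g. a common
    ontology restriction for cross-species runs); test proteins absent from
    the training network degrade to zero F3 features.
    """
    config = config or RunConfig()
    onts = config.ontologies or tuple(sorted(train_dataset.dags))
    if any(o not in test_dataset.dags for o in onts) and ("F2" in config.feature_blocks
                                                          or "F3" in config.feature_blocks):
        raise ValueError("train and test datasets have disjoint ontologies")
    model = stacking.fit(train_dataset, config, seed=seed)
    pairs = [(a, b) for a, b, _ in test_dataset.pairs]
    probs, _ = model.predict_pairs(test_dataset, pairs)
    return evaluate_predictions(np.array(test_dataset.labels), probs, model.tau)
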
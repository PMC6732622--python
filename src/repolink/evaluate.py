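"""Negative sampling, cross-validation, classifiers, metrics and ranking.

Positive samples are the known drug-disease associations; an equal number of
negatives is drawn uniformly without replacement from the unobserved cells.
The balanced set is split into k stratified folds; each fold's model trains
on the remaining folds and scores the held-out pairs. Classification metrics
follow the standard confusion-matrix definitions; AUC is the Mann-Whitney
statistic (ties counted one half). The leave-disease-out protocol removes
every association of a target disease, retrains, and ranks all drugs for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from . import fusion, gip, semantic
from .autoencoder import encode_all, train_autoencoder
from .config import RunConfig
from .io import AssociationMatrix, FingerprintMatrix, SemanticSimilarityMatrix

__all__ = [
    "PairDataset",
    "ConfusionCounts",
    "FoldMetrics",
    "MetricsReport",
    "RankedPredictions",
    "sample_negatives",
    "assign_folds",
    "train_random_forest",
    "train_svm",
    "predict_scores",
    "confusion",
    "metrics",
    "roc_auc",
    "cross_validate",
    "score_distribution",
    "rank_drugs_for_disease",
]


@dataclass
class PairDataset:
    """Balanced labelled (drug, disease) pairs with optional fold assignment."""

    positives: list[tuple[int, int]]
    negatives: list[tuple[int, int]]
    fold_assignment: dict[tuple[int, int, int], int] = field(default_factory=dict)
    # key = (drug, disease, label), fold ids are 1-based

    def samples(self) -> list[tuple[int, int, int]]:
        return [(u, d, 1) for u, d in self.positives] + [(u, d, 0) for u, d in self.negatives]

    def fold_of(self, sample: tuple[int, int, int]) -> int:
        return self.fold_assignment[sample]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class FoldMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class MetricsReport:
    """Per-fold confusion metrics, their mean/std, per-fold AUC and pooled ROC."""

    folds: list[FoldMetrics]
    fold_aucs: list[float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds], dtype=float)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self._values(name)))

    def std(self, name: str) -> float:
        return float(np.nanstd(self._values(name)))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


@dataclass
class RankedPredictions:
    """Descending score ranking of every candidate drug for one disease."""

    disease_id: str
    ranked: list[tuple[str, float]]  # (drug_id, score), score desc then drug_id asc


def sample_negatives(assoc: AssociationMatrix, seed: int) -> PairDataset:
    """Uniform draw without replacement from the zero cells, one per positive."""
    pos = [tuple(map(int, p)) for p in np.argwhere(assoc.A == 1)]
    zeros = np.argwhere(assoc.A == 0)
    if len(zeros) < len(pos):
        raise ValueError(
            f"only {len(zeros)} unobserved cells available for {len(pos)} negatives"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zeros), size=len(pos), replace=False)
    neg = [tuple(map(int, zeros[i])) for i in pick]
    return PairDataset(pos, neg)


def assign_folds(dataset: PairDataset, k: int, seed: int) -> PairDataset:
    """Random stratified partition into k folds with total sizes differing by <= 1.

    Positives and negatives are each dealt round-robin after shuffling; the
    negative deal starts where the positive remainder left off so the
    oversized folds of the two classes do not coincide.
    """
    n = len(dataset.positives) + len(dataset.negatives)
    if not 2 <= k <= n:
        raise ValueError(f"fold count {k} out of range for {n} samples")
    rng = np.random.default_rng(seed)
    assignment: dict[tuple[int, int, int], int] = {}
    offset = 0
    for label, pairs in ((1, dataset.positives), (0, dataset.negatives)):
        order = rng.permutation(len(pairs))
        for pos_in_deal, idx in enumerate(order):
            u, d = pairs[idx]
            assignment[(u, d, label)] = (pos_in_deal + offset) % k + 1
        offset = (offset + len(pairs)) % k
    dataset.fold_assignment = assignment
    return dataset


def train_random_forest(
    features: np.ndarray, labels: np.ndarray, cfg: RunConfig | None = None
):
    """Seeded random forest; prediction is the majority vote of the trees."""
    cfg = cfg or RunConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features="sqrt",
        random_state=cfg.stage_seed("random_forest"),
        n_jobs=1,
    )
    clf.fit(np.asarray(features, dtype=float), labels.astype(int))
    return clf


def train_svm(features: np.ndarray, labels: np.ndarray, cfg: RunConfig | None = None):
    """RBF-kernel SVM comparator with Platt-scaled probability scores."""
    cfg = cfg or RunConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(
        kernel="rbf",
        C=cfg.svm_c,
        gamma=cfg.svm_gamma,
        probability=True,
        random_state=cfg.stage_seed("svm"),
    )
    clf.fit(np.asarray(features, dtype=float), labels.astype(int))
    return clf


def predict_scores(classifier, features: np.ndarray) -> np.ndarray:
    """Score in [0, 1] for the positive class.

    For a random forest this is the fraction of trees voting positive, so
    thresholding at 0.5 reproduces the ensemble's majority vote; other
    classifiers use their probability estimate.
    """
    X = np.asarray(features, dtype=float)
    if isinstance(classifier, RandomForestClassifier):
        votes = np.stack([tree.predict(X) for tree in classifier.estimators_])
        return (votes == 1).mean(axis=0)
    pos_col = int(np.flatnonzero(classifier.classes_ == 1)[0])
    return classifier.predict_proba(X)[:, pos_col]


def confusion(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Tally the confusion matrix; score >= threshold predicts positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int((pred & pos).sum()),
        FP=int((pred & ~pos).sum()),
        TN=int((~pred & ~pos).sum()),
        FN=int((~pred & pos).sum()),
    )


def metrics(c: ConfusionCounts) -> FoldMetrics:
    """Accuracy, precision, recall and F1; zero-denominator metrics are NaN."""
    if c.total == 0:
        raise ValueError("cannot compute metrics with no evaluated samples")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return FoldMetrics(
        accuracy=(c.TP + c.TN) / c.total,
        precision=ratio(c.TP, c.TP + c.FP),
        recall=ratio(c.TP, c.TP + c.FN),
        f1=ratio(2 * c.TP, 2 * c.TP + c.FN + c.FP),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """ROC points by threshold sweep and AUC as the Mann-Whitney statistic."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(y, s)
    return (fpr, tpr, thr), float(roc_auc_score(y, s))


def _masked_assoc(assoc: AssociationMatrix, hidden: Sequence[tuple[int, int]]) -> AssociationMatrix:
    A = assoc.A.copy()
    for u, d in hidden:
        A[u, d] = 0
    return AssociationMatrix(list(assoc.drug_ids), list(assoc.disease_ids), A)


def _build_feature_space(
    assoc_for_kernels: AssociationMatrix,
    fg,
    ds_r: SemanticSimilarityMatrix,
    cfg: RunConfig,
):
    """Descriptor matrices from an association matrix and a fixed fingerprint code."""
    k_dis = gip.disease_gip(assoc_for_kernels, cfg)
    k_drug = gip.drug_gip(assoc_for_kernels, cfg)
    net = semantic.build_sharing_network(assoc_for_kernels)
    clusters = semantic.cluster_one(net, cfg)
    ds = semantic.boost_semantic(ds_r, clusters)
    no_profile = assoc_for_kernels.A.sum(axis=0) == 0
    disease_desc = fusion.fuse_disease_similarity(k_dis, ds, no_profile)
    drug_desc = fusion.build_drug_descriptors(k_drug, fg)
    return drug_desc, disease_desc


_TRAINERS = {"rf": train_random_forest, "svm": train_svm}


def _fit_and_score(
    train_samples, test_samples, drug_desc, disease_desc, cfg: RunConfig, classifier: str
):
    train_pairs = fusion.assemble_pairs(train_samples, drug_desc, disease_desc)
    test_pairs = fusion.assemble_pairs(test_samples, drug_desc, disease_desc)
    if cfg.use_refiner:
        refiner = fusion.train_refiner(train_pairs, cfg)
        X_train = fusion.refine(train_pairs, refiner)
        X_test = fusion.refine(test_pairs, refiner)
    else:
        X_train = np.stack([p.vector for p in train_pairs])
        X_test = np.stack([p.vector for p in test_pairs])
    y_train = np.array([p.label for p in train_pairs])
    clf = _TRAINERS[classifier](X_train, y_train, cfg)
    return predict_scores(clf, X_test)


def cross_validate(
    assoc: AssociationMatrix,
    fingerprints: FingerprintMatrix,
    ds_r: SemanticSimilarityMatrix,
    cfg: RunConfig | None = None,
    classifier: Literal["rf", "svm"] = "rf",
    dataset: PairDataset | None = None,
) -> MetricsReport:
    """k-fold cross-validation of the full pipeline.

    Negative sampling happens once for the whole experiment; the autoencoder
    is trained once on the label-free fingerprint matrix. In ``full_matrix``
    mode the interaction-profile kernels come from the complete association
    matrix; in ``train_only`` mode each fold recomputes them from a copy with
    the held-out positives zeroed. A pre-built ``dataset`` (e.g. with
    permuted labels) may be supplied instead of sampling.
    """
    cfg = cfg or RunConfig()
    if dataset is None:
        dataset = sample_negatives(assoc, cfg.stage_seed("negative_sampling"))
    if not dataset.fold_assignment:
        dataset = assign_folds(dataset, cfg.cv_folds, cfg.stage_seed("fold_assignment"))

    ae = train_autoencoder(fingerprints, cfg)
    fg = encode_all(fingerprints, ae)

    shared_space = None
    if cfg.gip_leakage_mode == "full_matrix":
        shared_space = _build_feature_space(assoc, fg, ds_r, cfg)

    folds: list[FoldMetrics] = []
    fold_aucs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    all_samples = dataset.samples()
    for fold_id in range(1, cfg.cv_folds + 1):
        test = [s for s in all_samples if dataset.fold_of(s) == fold_id]
        train = [s for s in all_samples if dataset.fold_of(s) != fold_id]
        if shared_space is not None:
            drug_desc, disease_desc = shared_space
        else:
            hidden = [(u, d) for u, d, y in test if y == 1]
            drug_desc, disease_desc = _build_feature_space(
                _masked_assoc(assoc, hidden), fg, ds_r, cfg
            )
        scores = _fit_and_score(train, test, drug_desc, disease_desc, cfg, classifier)
        y_test = np.array([s[2] for s in test])
        folds.append(metrics(confusion(scores, y_test, cfg.decision_threshold)))
        _, auc = roc_auc(scores, y_test)
        fold_aucs.append(auc)
        pooled_scores.append(scores)
        pooled_labels.append(y_test)

    s_all = np.concatenate(pooled_scores)
    y_all = np.concatenate(pooled_labels)
    (fpr, tpr, thr), _ = roc_auc(s_all, y_all)
    return MetricsReport(folds, fold_aucs, fpr, tpr, thr, s_all, y_all)


def score_distribution(
    scores: Sequence[float], labels: Sequence[int], bin_width: float = 0.1
) -> dict[int, np.ndarray]:
    """Per-class proportions over score bins [0, w), [w, 2w), ..., [1-w, 1].

    Returns ``{label: proportions}`` with each class's proportions summing
    to 1; mirrors the usual predicted-score histogram read-out.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size == 0:
        raise ValueError("empty score list")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out: dict[int, np.ndarray] = {}
    for label in (0, 1):
        cls = s[y == label]
        if cls.size == 0:
            continue
        counts, _ = np.histogram(cls, bins=edges)
        out[label] = counts / cls.size
    return out


def rank_drugs_for_disease(
    disease_id: str,
    assoc: AssociationMatrix,
    fingerprints: FingerprintMatrix,
    ds_r: SemanticSimilarityMatrix,
    cfg: RunConfig | None = None,
    classifier: Literal["rf", "svm"] = "rf",
) -> RankedPredictions:
    """Leave-disease-out ranking of all drugs for one target disease.

    Every known association of the target disease is removed before any
    stage sees the data; the model trains on the remaining positives plus an
    equal-size negative sample drawn outside the target column, then scores
    all (drug, target) pairs.
    """
    cfg = cfg or RunConfig()
    if disease_id not in assoc.disease_ids:
        raise KeyError(f"unknown disease ID {disease_id!r}")
    target = assoc.disease_ids.index(disease_id)

    A = assoc.A.copy()
    A[:, target] = 0
    masked = AssociationMatrix(list(assoc.drug_ids), list(assoc.disease_ids), A)

    pos = [tuple(map(int, p)) for p in np.argwhere(masked.A == 1)]
    zeros = [
        tuple(map(int, z)) for z in np.argwhere(masked.A == 0) if int(z[1]) != target
    ]
    if len(zeros) < len(pos):
        raise ValueError("not enough unobserved cells outside the target disease")
    rng = np.random.default_rng(cfg.stage_seed("rank_negatives"))
    pick = rng.choice(len(zeros), size=len(pos), replace=False)
    neg = [zeros[i] for i in pick]

    ae = train_autoencoder(fingerprints, cfg)
    fg = encode_all(fingerprints, ae)
    drug_desc, disease_desc = _build_feature_space(masked, fg, ds_r, cfg)

    train = [(u, d, 1) for u, d in pos] + [(u, d, 0) for u, d in neg]
    candidates = [(u, target, 0) for u in range(masked.n_drugs)]
    scores = _fit_and_score(train, candidates, drug_desc, disease_desc, cfg, classifier)

    order = sorted(
        zip(assoc.drug_ids, scores), key=lambda t: (-t[1], t[0])
    )
    return RankedPredictions(disease_id, [(d, float(s)) for d, s in order])
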
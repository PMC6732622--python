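"""Similarity fusion, pair-feature assembly and optional BN+FC+ReLU refinement.

Disease descriptor: the interaction-profile kernel entry where it is nonzero,
semantic similarity elsewhere. Drug descriptor: the drug kernel row
concatenated with the autoencoded fingerprint code. A (drug, disease) sample
is the concatenation of the two descriptor rows. The optional refinement
stage standardises features with training-fold batch statistics, maps them
through one fully-connected ReLU layer trained with a logistic head on the
training labels, and hands the hidden activations to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .autoencoder import EncodedFeatures
from .config import RunConfig
from .gip import KernelMatrix
from .semantic import BoostedSemanticMatrix

__all__ = [
    "DiseaseDescriptorMatrix",
    "DrugDescriptorMatrix",
    "PairFeature",
    "RefinerParams",
    "fuse_disease_similarity",
    "build_drug_descriptors",
    "assemble_pairs",
    "fit_batch_norm",
    "apply_batch_norm",
    "relu",
    "train_refiner",
    "refine",
]

BN_EPS = 1e-8


@dataclass
class DiseaseDescriptorMatrix:
    disease_ids: list[str]
    Sim: np.ndarray


@dataclass
class DrugDescriptorMatrix:
    drug_ids: list[str]
    R: np.ndarray  # n_drugs x (n_drugs + hidden_dim)


@dataclass
class PairFeature:
    drug_index: int
    disease_index: int
    label: int
    vector: np.ndarray


@dataclass
class RefinerParams:
    """Batch-norm statistics plus the trained FC layer (logistic head kept for audit)."""

    bn_mean: np.ndarray
    bn_var: np.ndarray
    bn_epsilon: float
    W_fc: np.ndarray  # fc_width x input_dim
    b_fc: np.ndarray  # fc_width
    w_head: np.ndarray  # fc_width
    b_head: float
    training_curve: list[float]


def fuse_disease_similarity(
    gip_dis: KernelMatrix,
    ds: BoostedSemanticMatrix,
    no_profile: np.ndarray | None = None,
) -> DiseaseDescriptorMatrix:
    """Kernel entry where the pair has one, boosted semantic similarity otherwise.

    A pair "has" a profile-kernel similarity when the stored entry is nonzero
    and, if ``no_profile`` is given, neither disease is flagged there. A
    disease with no known associations has no interaction profile, so its
    Gaussian row is a bandwidth artifact rather than a similarity; callers
    that know the association matrix pass ``no_profile`` (empty columns) so
    such diseases fall back to semantic similarity.
    """
    if gip_dis.entity_ids != ds.disease_ids:
        raise ValueError("disease orderings of kernel and semantic matrix differ")
    K, S = gip_dis.K, ds.DS
    if K.shape != S.shape:
        raise ValueError("dimension mismatch between kernel and semantic matrix")
    has_gip = K != 0.0
    if no_profile is not None:
        no_profile = np.asarray(no_profile, dtype=bool)
        pair_missing = no_profile[:, None] | no_profile[None, :]
        has_gip = has_gip & ~pair_missing
    Sim = np.where(has_gip, K, S)
    Sim = (Sim + Sim.T) / 2.0
    np.fill_diagonal(Sim, 1.0)
    return DiseaseDescriptorMatrix(list(ds.disease_ids), Sim)


def build_drug_descriptors(
    gip_drug: KernelMatrix, fg: EncodedFeatures
) -> DrugDescriptorMatrix:
    """Row-wise concatenation [kernel row || fingerprint code row]."""
    if gip_drug.entity_ids != fg.drug_ids:
        raise ValueError("drug orderings of kernel and encoded features differ")
    if gip_drug.K.shape[0] != fg.FG.shape[0]:
        raise ValueError("dimension mismatch between kernel and encoded features")
    return DrugDescriptorMatrix(list(fg.drug_ids), np.hstack([gip_drug.K, fg.FG]))


def assemble_pairs(
    samples: Sequence[tuple[int, int, int]],
    drugs: DrugDescriptorMatrix,
    diseases: DiseaseDescriptorMatrix,
) -> list[PairFeature]:
    """Concatenate drug and disease descriptor rows for each labelled sample."""
    n_u, n_d = drugs.R.shape[0], diseases.Sim.shape[0]
    out = []
    for u, d, y in samples:
        if not (0 <= u < n_u and 0 <= d < n_d):
            raise IndexError(f"sample index out of range: drug {u}, disease {d}")
        out.append(PairFeature(u, d, int(y), np.concatenate([drugs.R[u], diseases.Sim[d]])))
    return out


def fit_batch_norm(train_vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and population (biased) variance from training data only."""
    X = np.asarray(train_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("batch norm needs at least two training vectors")
    return X.mean(axis=0), X.var(axis=0)


def apply_batch_norm(
    vectors: np.ndarray, bn_mean: np.ndarray, bn_var: np.ndarray, eps: float = BN_EPS
) -> np.ndarray:
    """(x - mean) / sqrt(var + eps); constant features map to zero."""
    return (np.asarray(vectors, dtype=float) - bn_mean) / np.sqrt(bn_var + eps)


def relu(x):
    return np.maximum(0.0, np.asarray(x, dtype=float))


def _stack(pairs: Sequence[PairFeature]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.vector for p in pairs])
    y = np.array([p.label for p in pairs], dtype=float)
    return X, y


def train_refiner(train_pairs: Sequence[PairFeature], cfg: RunConfig | None = None) -> RefinerParams:
    """Fit batch-norm statistics and the FC+ReLU layer on training pairs only.

    The layer is trained through a logistic output head on the binary
    cross-entropy of the training labels by seeded full-batch gradient
    descent; downstream consumers use the hidden activations, the head is
    retained only so the training objective is auditable.
    """
    cfg = cfg or RunConfig()
    X, y = _stack(train_pairs)
    if len(np.unique(y)) < 2:
        raise ValueError("refiner training needs both classes present")
    bn_mean, bn_var = fit_batch_norm(X)
    Xn = apply_batch_norm(X, bn_mean, bn_var)

    n, d = Xn.shape
    h = cfg.fc_width
    rng = cfg.stage_rng("refiner")
    r = np.sqrt(6.0 / (d + h))
    W = rng.uniform(-r, r, size=(h, d))
    b = np.zeros(h)
    w_out = rng.uniform(-r, r, size=h)
    b_out = 0.0
    lr = cfg.refiner_learning_rate
    curve: list[float] = []
    for _ in range(cfg.refiner_epochs):
        Z = Xn @ W.T + b
        H = np.maximum(0.0, Z)
        p = expit(H @ w_out + b_out)
        eps = 1e-12
        curve.append(float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))
        dlogit = (p - y) / n
        g_w_out = H.T @ dlogit
        g_b_out = dlogit.sum()
        dH = np.outer(dlogit, w_out) * (Z > 0)
        gW = dH.T @ Xn
        gb = dH.sum(axis=0)
        W -= lr * gW
        b -= lr * gb
        w_out -= lr * g_w_out
        b_out -= lr * g_b_out
    return RefinerParams(bn_mean, bn_var, BN_EPS, W, b, w_out, float(b_out), curve)


def refine(pairs: Sequence[PairFeature] | np.ndarray, params: RefinerParams) -> np.ndarray:
    """ReLU hidden activations of the refinement layer, one row per pair."""
    X = pairs if isinstance(pairs, np.ndarray) else _stack(pairs)[0]
    Xn = apply_batch_norm(X, params.bn_mean, params.bn_var, params.bn_epsilon)
    return np.maximum(0.0, Xn @ params.W_fc.T + params.b_fc)
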
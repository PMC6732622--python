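"""Cluster-boosted disease semantic similarity.

Diseases that share associated drugs form a weighted sharing network
(edge weight = number of drugs associated with both endpoints). Cohesive
modules of that network are found by greedy cluster growth maximising

    f(K) = C_in(K) / (C_in(K) + C_bound(K) + P(K)),

where ``C_in`` is the total edge weight inside the vertex set K, ``C_bound``
the weight crossing its boundary and ``P(K) = p * |K|`` a per-vertex penalty
discouraging tiny accidental clusters. Semantic similarity of two diseases
co-resident in a cluster is boosted to ``(1 + f(K)) * DS_r`` and any
off-diagonal value reaching 1 is capped at 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import RunConfig
from .io import AssociationMatrix, SemanticSimilarityMatrix

__all__ = [
    "SharingNetwork",
    "ClusterSet",
    "BoostedSemanticMatrix",
    "build_sharing_network",
    "cohesiveness",
    "cluster_one",
    "boost_semantic",
]

CAP = 0.99


@dataclass
class SharingNetwork:
    """Weighted disease-sharing graph as a dense symmetric matrix, zero diagonal."""

    disease_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.disease_ids)
        if self.W.shape != (n, n):
            raise ValueError("sharing-network shape does not match disease IDs")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("sharing network must be symmetric")
        if (self.W < 0).any():
            raise ValueError("edge weights must be nonnegative")
        np.fill_diagonal(self.W, 0.0)

    @property
    def n(self) -> int:
        return len(self.disease_ids)

    def weighted_degree(self) -> np.ndarray:
        return self.W.sum(axis=1)


@dataclass
class ClusterSet:
    """Possibly overlapping vertex sets with their cohesiveness scores."""

    clusters: list[tuple[frozenset[int], float]]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class BoostedSemanticMatrix:
    disease_ids: list[str]
    DS: np.ndarray


def build_sharing_network(assoc: AssociationMatrix) -> SharingNetwork:
    """W[i, j] = number of drugs associated with both disease i and disease j."""
    A = assoc.A.astype(float)
    W = A.T @ A
    np.fill_diagonal(W, 0.0)
    return SharingNetwork(list(assoc.disease_ids), W)


def cohesiveness(
    K: Iterable[int], net: SharingNetwork, penalty_per_node: float = 2.0
) -> float:
    """f(K) = C_in / (C_in + C_bound + p*|K|); 0 when all terms vanish."""
    members = sorted(set(K))
    if not members:
        raise ValueError("cluster must be non-empty")
    if members[0] < 0 or members[-1] >= net.n:
        raise IndexError("cluster vertex index out of range")
    mask = np.zeros(net.n, dtype=bool)
    mask[members] = True
    inside = net.W[np.ix_(mask, mask)]
    c_in = inside.sum() / 2.0
    c_bound = net.W[np.ix_(mask, ~mask)].sum()
    denom = c_in + c_bound + penalty_per_node * len(members)
    if denom == 0.0:
        return 0.0
    return float(c_in / denom)


def _grow_cluster(
    seed: int, W: np.ndarray, degree: np.ndarray, penalty: float
) -> tuple[frozenset[int], float]:
    """Greedy growth from a seed vertex; strict-improvement single moves only.

    State is tracked incrementally: ``w_in[v]`` is the total weight from v
    into the current cluster, so each candidate move is scored in O(1) and
    an accepted move updates state in O(n).
    """
    n = W.shape[0]
    in_K = np.zeros(n, dtype=bool)
    in_K[seed] = True
    size = 1
    w_in = W[seed].copy()  # weight from each vertex into K
    c_in = 0.0
    c_bound = float(degree[seed])

    def score(ci: float, cb: float, sz: int) -> float:
        den = ci + cb + penalty * sz
        return ci / den if den > 0 else 0.0

    current = score(c_in, c_bound, size)
    while True:
        best_gain = 0.0
        best_move: tuple[str, int, float, float] | None = None
        # additions: only vertices touching K can raise C_in; scan those first,
        # fall back to any outside vertex (they never strictly improve f).
        outside = np.flatnonzero(~in_K)
        for v in outside:
            ci = c_in + w_in[v]
            cb = c_bound - w_in[v] + (degree[v] - w_in[v])
            f = score(ci, cb, size + 1)
            if f > current + 1e-12 and (best_move is None or f - current > best_gain + 1e-12):
                best_gain = f - current
                best_move = ("add", int(v), ci, cb)
        if size > 1:
            for v in np.flatnonzero(in_K):
                ci = c_in - w_in[v]
                cb = c_bound + w_in[v] - (degree[v] - w_in[v])
                f = score(ci, cb, size - 1)
                if f > current + 1e-12 and (best_move is None or f - current > best_gain + 1e-12):
                    best_gain = f - current
                    best_move = ("remove", int(v), ci, cb)
        if best_move is None:
            break
        kind, v, c_in, c_bound = best_move
        if kind == "add":
            in_K[v] = True
            size += 1
            w_in += W[v]
        else:
            in_K[v] = False
            size -= 1
            w_in -= W[v]
        current = score(c_in, c_bound, size)
    return frozenset(np.flatnonzero(in_K).tolist()), current


def _overlap_score(a: frozenset[int], b: frozenset[int]) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def cluster_one(net: SharingNetwork, cfg: RunConfig | None = None) -> ClusterSet:
    """Greedy cohesive clustering of the sharing network.

    Seeds are chosen by descending weighted degree among vertices not yet in
    any cluster (lowest index wins ties); each cluster is grown to a strict
    local optimum of f under single add/remove moves; highly overlapping
    clusters (overlap score > ``cluster_overlap_merge``) are merged at the
    end; vertices still uncovered when no positive-degree seed remains become
    singleton clusters.
    """
    cfg = cfg or RunConfig()
    penalty = cfg.cluster_penalty_per_node
    W = net.W
    degree = net.weighted_degree()
    processed = np.zeros(net.n, dtype=bool)
    clusters: list[tuple[frozenset[int], float]] = []

    while True:
        candidates = np.flatnonzero(~processed & (degree > 0))
        if candidates.size == 0:
            break
        seed = int(candidates[np.argmax(degree[candidates])])  # argmax keeps lowest index on ties
        K, f = _grow_cluster(seed, W, degree, penalty)
        clusters.append((K, f))
        # growth may eject the seed itself; mark it processed regardless so
        # the outer loop always makes progress
        processed[seed] = True
        processed[list(K)] = True

    # vertices with no edges never seed a growth; they become f=0 singletons
    # (themselves trivially local-optimal, unlike forced singletons of
    # positive-degree vertices would be)
    for v in np.flatnonzero(~processed & (degree == 0)):
        clusters.append((frozenset([int(v)]), cohesiveness([int(v)], net, penalty)))

    # distinct seeds may converge to the same vertex set; keep one copy
    seen: set[frozenset[int]] = set()
    unique: list[tuple[frozenset[int], float]] = []
    for K, f in clusters:
        if K not in seen:
            seen.add(K)
            unique.append((K, f))
    clusters = unique

    # merge pass: repeatedly fuse the first pair exceeding the overlap threshold
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if _overlap_score(clusters[i][0], clusters[j][0]) > cfg.cluster_overlap_merge:
                    union = clusters[i][0] | clusters[j][0]
                    f_union = cohesiveness(union, net, penalty)
                    clusters[i] = (union, f_union)
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return ClusterSet(clusters)


def boost_semantic(
    ds_r: SemanticSimilarityMatrix, clusters: ClusterSet
) -> BoostedSemanticMatrix:
    """Boost within-cluster pairs to (1 + f(K*)) * DS_r, cap off-diagonal at 0.99.

    K* is the highest-cohesiveness cluster containing both diseases; pairs
    sharing no cluster keep their original similarity.
    """
    n = len(ds_r.disease_ids)
    best_f = np.zeros((n, n))
    for K, f in clusters:
        idx = sorted(K)
        if idx and (idx[0] < 0 or idx[-1] >= n):
            raise IndexError("cluster vertex index out of range for the semantic matrix")
        block = np.ix_(idx, idx)
        best_f[block] = np.maximum(best_f[block], f)
    DS = ds_r.S * (1.0 + best_f)
    off = ~np.eye(n, dtype=bool)
    DS[off & (DS >= 1.0)] = CAP
    np.fill_diagonal(DS, ds_r.S.diagonal())
    DS = (DS + DS.T) / 2.0
    return BoostedSemanticMatrix(list(ds_r.disease_ids), DS)
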
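"""Gaussian interaction profile (GIP) kernel similarities.

The similarity between two entities is a Gaussian radial basis function of
the squared Euclidean distance between their binary interaction profiles,

    K[x, y] = exp(-b * ||Y_x - Y_y||^2),

with the bandwidth ``b`` normalised by the mean squared profile norm,

    b = gamma' / ((1/n) * sum_i ||Y_i||^2).

For binary profiles ``||Y_i||^2`` is the number of known associations of
entity ``i``, so the bandwidth adapts to the density of the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import RunConfig
from .io import AssociationMatrix

__all__ = [
    "KernelMatrix",
    "DegenerateBandwidthError",
    "compute_bandwidth",
    "gip_kernel",
    "disease_gip",
    "drug_gip",
]


class DegenerateBandwidthError(ValueError):
    """Every profile is all-zero: the entity set has no known associations."""


@dataclass
class KernelMatrix:
    """Square symmetric Gaussian-kernel similarity with unit diagonal."""

    entity_ids: list[str]
    K: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.entity_ids)
        if self.K.shape != (n, n):
            raise ValueError("kernel matrix shape does not match entity IDs")


def compute_bandwidth(profiles: np.ndarray | Sequence[Sequence[int]], gamma_prime: float) -> float:
    """Normalised bandwidth: gamma' divided by the mean squared profile norm.

    Raises :class:`DegenerateBandwidthError` when every profile is all-zero
    (the mean norm vanishes and the kernel is undefined).
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D array (one row per entity)")
    if gamma_prime < 0:
        raise ValueError("gamma_prime must be nonnegative")
    mean_sq_norm = float((P**2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise DegenerateBandwidthError(
            "all interaction profiles are zero; no associations to normalise by"
        )
    return gamma_prime / mean_sq_norm


def gip_kernel(
    profiles: np.ndarray | Sequence[Sequence[int]],
    gamma_prime: float,
    entity_ids: Sequence[str] | None = None,
) -> KernelMatrix:
    """Gaussian interaction profile kernel over a set of binary profiles."""
    P = np.asarray(profiles, dtype=float)
    b = compute_bandwidth(P, gamma_prime)
    # ||Y_x - Y_y||^2 via the Gram expansion; exact for 0/1 profiles.
    sq = (P**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-b * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    ids = list(entity_ids) if entity_ids is not None else [str(i) for i in range(len(P))]
    return KernelMatrix(ids, K, b)


def disease_gip(assoc: AssociationMatrix, cfg: RunConfig | None = None) -> KernelMatrix:
    """Kernel over disease profiles (columns of the association matrix)."""
    cfg = cfg or RunConfig()
    return gip_kernel(assoc.A.T, cfg.gamma_prime_disease, assoc.disease_ids)


def drug_gip(assoc: AssociationMatrix, cfg: RunConfig | None = None) -> KernelMatrix:
    """Kernel over drug profiles (rows of the association matrix)."""
    cfg = cfg or RunConfig()
    return gip_kernel(assoc.A, cfg.gamma_prime_drug, assoc.drug_ids)
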
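"""Run configuration shared by every pipeline stage.

A single :class:`RunConfig` carries all tunables and one master seed; each
stochastic stage derives its own independent stream from that seed, so two
runs with equal configuration are bit-identical end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters with defaults reproducing the reference setup.

    Parameters
    ----------
    gamma_prime_drug, gamma_prime_disease
        Normalised Gaussian-kernel bandwidth parameters (dimensionless).
        0.5 on both sides; the drug side's 0.5 follows the source method,
        the disease side mirrors it for symmetry.
    ae_hidden_dim, ae_epochs, ae_learning_rate
        Autoencoder bottleneck width, full-batch gradient-descent epochs and
        step size for fingerprint compression.
    fc_width, refiner_epochs, refiner_learning_rate, use_refiner
        Width and training schedule of the batch-norm + fully-connected +
        ReLU feature refinement stage; ``use_refiner=False`` feeds the raw
        fused pair features to the classifier.
    n_trees
        Number of trees in the random-forest ensemble.
    cv_folds
        Number of cross-validation folds.
    decision_threshold
        Score cut-off for calling a pair positive.
    rng_seed
        Master seed; every stage derives a child stream from it.
    gip_leakage_mode
        ``"full_matrix"`` computes interaction-profile kernels once from the
        complete association matrix (faithful to the reference protocol but
        lets test-fold positives influence the kernels); ``"train_only"``
        zeroes held-out positives before computing kernels each fold.
    cluster_penalty_per_node
        Per-vertex penalty ``p`` in the cohesiveness denominator,
        ``P(K) = p * |K|``.
    cluster_overlap_merge
        Overlap score above which two clusters are merged,
        ``|Ki ∩ Kj|^2 / (|Ki| * |Kj|)``.
    svm_c, svm_gamma
        RBF-SVM comparator hyperparameters (``"scale"`` = 1/(d * var)).
    """

    gamma_prime_drug: float = 0.5
    gamma_prime_disease: float = 0.5
    ae_hidden_dim: int = 64
    ae_epochs: int = 200
    ae_learning_rate: float = 0.1
    fc_width: int = 128
    refiner_epochs: int = 50
    refiner_learning_rate: float = 0.05
    use_refiner: bool = True
    n_trees: int = 100
    cv_folds: int = 10
    decision_threshold: float = 0.5
    rng_seed: int = 0
    gip_leakage_mode: str = "full_matrix"
    cluster_penalty_per_node: float = 2.0
    cluster_overlap_merge: float = 0.8
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if self.gamma_prime_drug < 0 or self.gamma_prime_disease < 0:
            raise ValueError("bandwidth parameters must be nonnegative")
        if self.ae_hidden_dim < 1 or self.ae_epochs < 1 or self.ae_learning_rate <= 0:
            raise ValueError("invalid autoencoder configuration")
        if self.fc_width < 1:
            raise ValueError("fc_width must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")
        if self.gip_leakage_mode not in ("full_matrix", "train_only"):
            raise ValueError("gip_leakage_mode must be 'full_matrix' or 'train_only'")
        if self.cluster_penalty_per_node < 0:
            raise ValueError("cluster_penalty_per_node must be nonnegative")
        if not 0.0 < self.cluster_overlap_merge <= 1.0:
            raise ValueError("cluster_overlap_merge must lie in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed (< 2**31) from the master seed."""
        stage_id = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
        ss = np.random.SeedSequence([int(self.rng_seed) & 0x7FFFFFFF, stage_id])
        return int(ss.generate_state(1)[0] % (2**31))

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.stage_seed(stage))

    def to_dict(self) -> dict:
        return asdict(self)
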
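"""Seeded synthetic inputs with planted drug/disease module structure.

Drugs and diseases are assigned uniformly to modules. Associations are
Bernoulli(p_in) within a module and Bernoulli(p_out) across, fingerprints
are noisy copies of a per-module prototype bit-vector, and semantic
similarity is high within modules and low across (plus jitter). The planted
modules give every pipeline stage a recoverable signal, so the end-to-end
method can be exercised and benchmarked without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, FingerprintMatrix, SemanticSimilarityMatrix

__all__ = ["SynthSpec", "ModuleLabels", "generate", "default_fixture"]


@dataclass
class SynthSpec:
    n_drugs: int = 100
    n_diseases: int = 60
    n_modules: int = 5
    p_in: float = 0.35
    p_out: float = 0.02
    fp_bits: int = 64
    fp_flip_noise: float = 0.05
    ds_in: float = 0.6
    ds_out: float = 0.1
    ds_jitter: float = 0.05
    seed: int = 20190827

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_diseases, self.n_modules, self.fp_bits) < 1:
            raise ValueError("counts must be positive")
        for p in (self.p_in, self.p_out, self.fp_flip_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not (0.0 <= self.ds_out <= self.ds_in <= 1.0):
            raise ValueError("need 0 <= ds_out <= ds_in <= 1")
        if self.ds_jitter < 0:
            raise ValueError("ds_jitter must be nonnegative")
        if self.expected_positives() <= 0:
            raise ValueError("expected positive count must be positive")

    def expected_positives(self) -> float:
        m = self.n_modules
        per_cell = self.p_in / m + self.p_out * (m - 1) / m
        return self.n_drugs * self.n_diseases * per_cell


@dataclass
class ModuleLabels:
    """Ground-truth module assignment of every drug and disease."""

    drug_modules: np.ndarray
    disease_modules: np.ndarray


def _generate_once(spec: SynthSpec, seed: int):
    rng = np.random.default_rng(seed)
    drug_mod = rng.integers(spec.n_modules, size=spec.n_drugs)
    dis_mod = rng.integers(spec.n_modules, size=spec.n_diseases)

    same = drug_mod[:, None] == dis_mod[None, :]
    p = np.where(same, spec.p_in, spec.p_out)
    A = (rng.random((spec.n_drugs, spec.n_diseases)) < p).astype(np.int8)

    prototypes = (rng.random((spec.n_modules, spec.fp_bits)) < 0.5).astype(np.int8)
    F = prototypes[drug_mod]
    flips = rng.random(F.shape) < spec.fp_flip_noise
    F = np.where(flips, 1 - F, F).astype(np.int8)

    same_d = dis_mod[:, None] == dis_mod[None, :]
    base = np.where(same_d, spec.ds_in, spec.ds_out)
    jitter = rng.normal(0.0, 1.0, base.shape) * spec.ds_jitter
    S = np.clip(base + jitter, 0.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return A, F, S, drug_mod, dis_mod


def generate(
    spec: SynthSpec,
) -> tuple[AssociationMatrix, FingerprintMatrix, SemanticSimilarityMatrix, ModuleLabels]:
    """Draw one synthetic triple; retries once with seed+1 if every drug or
    disease profile came out empty (which would make the kernel bandwidth
    degenerate)."""
    for attempt_seed in (spec.seed, spec.seed + 1):
        A, F, S, drug_mod, dis_mod = _generate_once(spec, attempt_seed)
        if A.sum() > 0:
            break
    drug_ids = [f"drug{u:04d}" for u in range(spec.n_drugs)]
    disease_ids = [f"disease{d:04d}" for d in range(spec.n_diseases)]
    assoc = AssociationMatrix(drug_ids, disease_ids, A)
    fp = FingerprintMatrix(list(drug_ids), F)
    sem = SemanticSimilarityMatrix(list(disease_ids), S)
    return assoc, fp, sem, ModuleLabels(drug_mod, dis_mod)


def default_fixture():
    """The standard test triple: 100 drugs x 60 diseases, 5 planted modules."""
    return generate(SynthSpec())
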
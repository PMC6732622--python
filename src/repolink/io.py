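"""Reading, validation and writing of the three input matrices and result artifacts.

All matrices travel as ID-labelled TSV (CSV via ``dialect="csv"``): first row
holds column IDs, first column holds row IDs, body cells are numeric. Entity
orderings are reconciled against the association matrix on load, so any
row/column permutation of the input files yields identical downstream state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AssociationMatrix",
    "FingerprintMatrix",
    "SemanticSimilarityMatrix",
    "MatrixFormatError",
    "AlignmentError",
    "read_association_matrix",
    "read_fingerprint_matrix",
    "read_semantic_matrix",
    "read_aligned_matrices",
    "write_matrix",
    "write_report",
    "read_report",
    "write_roc_points",
    "write_ranking",
    "write_config",
]


class MatrixFormatError(ValueError):
    """A cell or header of an input matrix violates the format contract."""


class AlignmentError(ValueError):
    """Entity ID sets of the three input matrices do not coincide."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixFormatError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    if not ids:
        raise MatrixFormatError(f"no {what} IDs present")
    return ids


def _check_binary(M: np.ndarray, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
    bad = ~np.isin(M, (0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise MatrixFormatError(
            f"non-binary cell at row {rows[r]!r}, column {cols[c]!r}: {M[r, c]!r}"
        )
    return M.astype(np.int8)


@dataclass
class AssociationMatrix:
    """Binary drug x disease adjacency; source of profiles and labels."""

    drug_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray  # n_drugs x n_diseases, {0,1}

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise MatrixFormatError("association matrix shape does not match ID counts")
        self.A = _check_binary(self.A, self.drug_ids, self.disease_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positives(self) -> int:
        return int(self.A.sum())


@dataclass
class FingerprintMatrix:
    """Binary drug x substructure-bit matrix; row order matches the associations."""

    drug_ids: list[str]
    F: np.ndarray  # n_drugs x n_bits, {0,1}

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.F = np.asarray(self.F)
        if self.F.ndim != 2 or self.F.shape[0] != len(self.drug_ids) or self.F.shape[1] < 1:
            raise MatrixFormatError("fingerprint matrix shape does not match drug IDs")
        bit_ids = [f"bit{j}" for j in range(self.F.shape[1])]
        self.F = _check_binary(self.F, self.drug_ids, bit_ids)

    @property
    def n_bits(self) -> int:
        return self.F.shape[1]


@dataclass
class SemanticSimilarityMatrix:
    """Precomputed disease x disease semantic similarity in [0, 1], unit diagonal."""

    disease_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.disease_ids)
        if self.S.shape != (n, n):
            raise MatrixFormatError("semantic matrix must be square over the disease IDs")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise MatrixFormatError("semantic matrix must be symmetric")
        if (self.S < -1e-12).any() or (self.S > 1 + 1e-12).any():
            raise MatrixFormatError("semantic similarities must lie in [0, 1]")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-9):
            raise MatrixFormatError("semantic matrix diagonal must be 1 before boosting")
        self.S = np.clip(self.S, 0.0, 1.0)


_SEPS = {"tsv": "\t", "csv": ","}


def _read_frame(path: str | Path, dialect: str) -> pd.DataFrame:
    if dialect not in _SEPS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_SEPS[dialect], index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def read_association_matrix(path: str | Path, dialect: str = "tsv") -> AssociationMatrix:
    """Read a drug x disease binary matrix (rows = drugs, columns = diseases)."""
    df = _read_frame(path, dialect)
    return AssociationMatrix(list(df.index), list(df.columns), df.to_numpy())


def read_fingerprint_matrix(path: str | Path, dialect: str = "tsv") -> FingerprintMatrix:
    df = _read_frame(path, dialect)
    return FingerprintMatrix(list(df.index), df.to_numpy())


def read_semantic_matrix(path: str | Path, dialect: str = "tsv") -> SemanticSimilarityMatrix:
    df = _read_frame(path, dialect)
    if list(df.index) != list(df.columns):
        df = df.loc[:, df.index]  # reorder columns to row order if same ID set
    return SemanticSimilarityMatrix(list(df.index), df.to_numpy())


def read_aligned_matrices(
    assoc_path: str | Path,
    fingerprint_path: str | Path,
    semantic_path: str | Path,
    dialect: str = "tsv",
) -> tuple[AssociationMatrix, FingerprintMatrix, SemanticSimilarityMatrix]:
    """Read all three inputs and reorder fingerprints/semantic to the association order.

    Raises :class:`AlignmentError` listing the offending IDs when the entity
    sets differ.
    """
    assoc = read_association_matrix(assoc_path, dialect)
    fp_df = _read_frame(fingerprint_path, dialect)
    sem_df = _read_frame(semantic_path, dialect)

    fp_ids, drug_ids = set(map(str, fp_df.index)), set(assoc.drug_ids)
    if fp_ids != drug_ids:
        missing = sorted(drug_ids - fp_ids)
        extra = sorted(fp_ids - drug_ids)
        raise AlignmentError(
            f"fingerprint drug IDs differ from association drug IDs; "
            f"missing={missing}, extra={extra}"
        )
    sem_ids, disease_ids = set(map(str, sem_df.index)), set(assoc.disease_ids)
    if sem_ids != disease_ids or set(map(str, sem_df.columns)) != disease_ids:
        missing = sorted(disease_ids - sem_ids)
        extra = sorted(sem_ids - disease_ids)
        raise AlignmentError(
            f"semantic disease IDs differ from association disease IDs; "
            f"missing={missing}, extra={extra}"
        )

    fp_df.index = fp_df.index.map(str)
    sem_df.index = sem_df.index.map(str)
    sem_df.columns = sem_df.columns.map(str)
    fp = FingerprintMatrix(assoc.drug_ids, fp_df.loc[assoc.drug_ids].to_numpy())
    sem = SemanticSimilarityMatrix(
        assoc.disease_ids,
        sem_df.loc[assoc.disease_ids, assoc.disease_ids].to_numpy(),
    )
    return assoc, fp, sem


def write_matrix(
    M: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
    dialect: str = "tsv",
    float_format: str | None = None,
) -> None:
    """Write an ID-labelled matrix; inverse of the readers above."""
    df = pd.DataFrame(np.asarray(M), index=list(row_ids), columns=list(col_ids))
    df.to_csv(Path(path), sep=_SEPS[dialect], float_format=float_format)


_REPORT_COLS = ["fold", "accuracy", "precision", "recall", "f1", "auc"]


def write_report(report, path: str | Path) -> None:
    """Write per-fold metrics plus a mean +/- std summary row as TSV.

    ``report`` is a :class:`repolink.evaluate.MetricsReport`. Undefined
    metrics (zero denominators) are written as NaN.
    """
    if not report.folds:
        raise ValueError("cannot write an empty report")
    rows = []
    for i, fm in enumerate(report.folds, start=1):
        rows.append([str(i), fm.accuracy, fm.precision, fm.recall, fm.f1, report.fold_aucs[i - 1]])
    means = [report.mean("accuracy"), report.mean("precision"), report.mean("recall"),
             report.mean("f1"), report.mean_auc]
    stds = [report.std("accuracy"), report.std("precision"), report.std("recall"),
            report.std("f1"), float(np.std(report.fold_aucs))]
    df = pd.DataFrame(rows, columns=_REPORT_COLS)
    df.loc[len(df)] = ["mean", *means]
    df.loc[len(df)] = ["std", *stds]
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.6f")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report` (fold rows + summary)."""
    return pd.read_csv(Path(path), sep="\t")


def write_roc_points(fpr, tpr, thresholds, path: str | Path) -> None:
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}).to_csv(
        Path(path), sep="\t", index=False, float_format="%.6f"
    )


def write_ranking(ranking, path: str | Path) -> None:
    """Write a ranked-prediction table (rank, drug_id, score)."""
    rows = [(r + 1, drug, score) for r, (drug, score) in enumerate(ranking.ranked)]
    pd.DataFrame(rows, columns=["rank", "drug_id", "score"]).to_csv(
        Path(path), sep="\t", index=False, float_format="%.6f"
    )


def write_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
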
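"""Dataset containers and disk I/O for drug-disease benchmark bundles.

A benchmark bundle is the triple used throughout drug-repositioning link
prediction: a drug-drug similarity matrix ``S_D`` (m x m), a disease-disease
similarity matrix ``S_d`` (n x n) and a binary drug-disease interaction
matrix ``I`` (m x n), together with the ordered drug and disease identifier
lists that give the matrices their row/column meaning.

Two on-disk dialects are supported:

``fdataset_layout``
    Plain tab-delimited numeric matrices without headers
    (``drug_similarity.tsv``, ``disease_similarity.tsv``,
    ``interactions.tsv``) plus one-ID-per-line sidecar files
    (``drugs.txt``, ``diseases.txt``).

``generic_tsv``
    The three matrices carry a header row and an index column of IDs;
    no sidecar files are needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EntityIndex",
    "SimilarityMatrix",
    "InteractionMatrix",
    "BenchmarkDataset",
    "DatasetSummary",
    "ValidationError",
    "load_benchmark",
    "save_benchmark",
    "summarize",
]

logger = logging.getLogger(__name__)

#: absolute tolerance for symmetry and unit-diagonal checks
SYMMETRY_ATOL = 1e-10

_FDATASET_FILES = {
    "drug_sim": "drug_similarity.tsv",
    "disease_sim": "disease_similarity.tsv",
    "interactions": "interactions.tsv",
    "drugs": "drugs.txt",
    "diseases": "diseases.txt",
}


class ValidationError(ValueError):
    """An input matrix or index violates a structural invariant."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, duplicate-free list of entity identifiers.

    The order of ``ids`` is the row/column order of every matrix that
    references this index; IDs (DrugBank accessions, OMIM-style disease
    codes, ...) are the only external coordinates.
    """

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("entity identifiers contain duplicates")

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "EntityIndex":
        return cls(tuple(str(i) for i in ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def position(self, entity_id: str) -> int:
        """0-based position of ``entity_id``; raises ``KeyError`` if absent."""
        try:
            return self.ids.index(entity_id)
        except ValueError:
            raise KeyError(f"unknown entity id: {entity_id!r}") from None

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.ids


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix with unit diagonal and entries in [0, 1].

    Out-of-range entries (rounding artifacts in real deposits) are clipped
    with a logged warning; asymmetry or a non-unit diagonal beyond
    ``SYMMETRY_ATOL`` is an error.
    """

    values: np.ndarray
    index: EntityIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got {v.shape}")
        if v.shape[0] == 0:
            raise ValidationError("similarity matrix must be non-empty")
        if v.shape[0] != len(self.index):
            raise ValidationError(
                f"similarity matrix size {v.shape[0]} != index length {len(self.index)}"
            )
        if not np.allclose(v, v.T, atol=SYMMETRY_ATOL, rtol=0.0):
            raise ValidationError("similarity matrix is asymmetric beyond tolerance")
        if not np.allclose(np.diag(v), 1.0, atol=SYMMETRY_ATOL, rtol=0.0):
            raise ValidationError("similarity matrix diagonal is not 1")
        if v.min() < 0.0 or v.max() > 1.0:
            logger.warning(
                "similarity entries outside [0, 1] (min=%g, max=%g); clipping",
                v.min(),
                v.max(),
            )
            v = np.clip(v, 0.0, 1.0)
        # exact symmetry and diagonal from here on
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class InteractionMatrix:
    """Binary m x n drug-disease interaction matrix.

    Rows are drugs, columns diseases; entry (i, j) is 1 iff drug i is known
    to be associated with disease j.  Rows are the drug interaction profiles
    and columns the disease interaction profiles.
    """

    values: np.ndarray
    rows: EntityIndex
    cols: EntityIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError("interaction matrix must be 2-D")
        if v.shape != (len(self.rows), len(self.cols)):
            raise ValidationError(
                f"interaction matrix shape {v.shape} != index lengths "
                f"({len(self.rows)}, {len(self.cols)})"
            )
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise ValidationError("interaction matrix entries must be 0 or 1")
        self.values = v.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_interactions(self) -> int:
        return int(self.values.sum())

    def drug_profiles(self) -> np.ndarray:
        """Per-drug interaction profiles (rows of I), shape (m, n)."""
        return self.values.astype(np.float64)

    def disease_profiles(self) -> np.ndarray:
        """Per-disease interaction profiles (columns of I), shape (n, m)."""
        return self.values.T.astype(np.float64)


@dataclass
class BenchmarkDataset:
    """The (S_D, S_d, I) bundle plus its drug/disease indices."""

    drug_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    interactions: InteractionMatrix
    drugs: EntityIndex = field(init=False)
    diseases: EntityIndex = field(init=False)

    def __post_init__(self) -> None:
        if self.drug_sim.index != self.interactions.rows:
            raise ValidationError("drug similarity index != interaction row index")
        if self.disease_sim.index != self.interactions.cols:
            raise ValidationError("disease similarity index != interaction column index")
        self.drugs = self.interactions.rows
        self.diseases = self.interactions.cols

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def with_interactions(self, values: np.ndarray) -> "BenchmarkDataset":
        """Same similarities/indices with a replaced interaction matrix.

        Used by cross-validation to mask test-fold interactions out of the
        training view of the data.
        """
        return BenchmarkDataset(
            drug_sim=self.drug_sim,
            disease_sim=self.disease_sim,
            interactions=InteractionMatrix(values, self.drugs, self.diseases),
        )


@dataclass(frozen=True)
class DatasetSummary:
    n_drugs: int
    n_diseases: int
    n_interactions: int
    density: float


def summarize(ds: BenchmarkDataset) -> DatasetSummary:
    """Counts of drugs, diseases and known interactions, and the density of I."""
    m, n = ds.interactions.shape
    k = ds.interactions.n_interactions
    return DatasetSummary(m, n, k, k / (m * n))


def _read_ids(path: Path) -> EntityIndex:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return EntityIndex.from_iterable(ids)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required dataset file is missing: {path}")
    return path


def load_benchmark(directory: str | Path, dialect: str = "fdataset_layout") -> BenchmarkDataset:
    """Read a benchmark bundle from ``directory`` and validate it.

    Parameters
    ----------
    directory:
        Directory containing the three matrix files (and, for the
        ``fdataset_layout`` dialect, the two ID sidecar files).
    dialect:
        ``"fdataset_layout"`` (headerless matrices + ID sidecars) or
        ``"generic_tsv"`` (matrices with ID header row and index column).
    """
    directory = Path(directory)
    if dialect == "fdataset_layout":
        drug_ids = _read_ids(_require(directory / _FDATASET_FILES["drugs"]))
        disease_ids = _read_ids(_require(directory / _FDATASET_FILES["diseases"]))
        sd = np.loadtxt(_require(directory / _FDATASET_FILES["drug_sim"]), ndmin=2)
        sdis = np.loadtxt(_require(directory / _FDATASET_FILES["disease_sim"]), ndmin=2)
        inter = np.loadtxt(_require(directory / _FDATASET_FILES["interactions"]), ndmin=2)
    elif dialect == "generic_tsv":
        def _read(name: str) -> pd.DataFrame:
            return pd.read_csv(_require(directory / name), sep="\t", index_col=0)

        sd_df = _read(_FDATASET_FILES["drug_sim"])
        sdis_df = _read(_FDATASET_FILES["disease_sim"])
        inter_df = _read(_FDATASET_FILES["interactions"])
        drug_ids = EntityIndex.from_iterable(inter_df.index)
        disease_ids = EntityIndex.from_iterable(inter_df.columns)
        sd = sd_df.loc[list(drug_ids), list(drug_ids)].to_numpy(dtype=np.float64)
        sdis = sdis_df.loc[list(disease_ids), list(disease_ids)].to_numpy(dtype=np.float64)
        inter = inter_df.to_numpy()
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    return BenchmarkDataset(
        drug_sim=SimilarityMatrix(sd, drug_ids),
        disease_sim=SimilarityMatrix(sdis, disease_ids),
        interactions=InteractionMatrix(inter, drug_ids, disease_ids),
    )


def save_benchmark(ds: BenchmarkDataset, directory: str | Path) -> None:
    """Write ``ds`` in the ``fdataset_layout`` dialect.

    Matrices round-trip through :func:`load_benchmark` bit-identically for
    the binary interaction matrix and to better than 1e-12 for similarities
    (full-precision ``%.17g`` text).
    """
    if ds.n_drugs == 0 or ds.n_diseases == 0:
        raise ValidationError("refusing to save an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / _FDATASET_FILES["drug_sim"], ds.drug_sim.values,
               fmt="%.17g", delimiter="\t")
    np.savetxt(directory / _FDATASET_FILES["disease_sim"], ds.disease_sim.values,
               fmt="%.17g", delimiter="\t")
    np.savetxt(directory / _FDATASET_FILES["interactions"], ds.interactions.values,
               fmt="%d", delimiter="\t")
    (directory / _FDATASET_FILES["drugs"]).write_text("\n".join(ds.drugs) + "\n")
    (directory / _FDATASET_FILES["diseases"]).write_text("\n".join(ds.diseases) + "\n")
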
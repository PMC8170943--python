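"""Gaussian interaction profile kernels, representation fusion, truncated
SVD reduction, and per-pair feature assembly.

The Gaussian interaction profile (GIP) kernel encodes the assumption that
entities with similar interaction patterns behave similarly towards new
partners.  For two diseases with interaction profiles y_i, y_j (columns of
the binary interaction matrix I),

    K(i, j) = exp(-alpha * ||y_i - y_j||^2),

with the bandwidth normalised by the mean squared profile norm:

    alpha = alpha' / ( (1/n) * sum_i ||y_i||^2 ),

so the kernel scale adapts to the overall density of known interactions
(alpha' defaults to 0.5).  The same construction applies along the drug
axis (rows of I).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .datasets import BenchmarkDataset, InteractionMatrix, SimilarityMatrix

__all__ = [
    "GipBandwidth",
    "FeatureConfig",
    "PairFeatureTable",
    "gip_bandwidth",
    "gip_kernel",
    "disease_representation",
    "drug_representation",
    "tsvd_reduce",
    "TruncatedSVDReducer",
    "assemble_pairs",
]

Axis = Literal["drugs", "diseases"]


@dataclass(frozen=True)
class GipBandwidth:
    """GIP bandwidth: the raw alpha' and the profile-normalised alpha."""

    alpha_prime: float
    alpha: float
    n_entities: int

    def __post_init__(self) -> None:
        if not (self.alpha_prime > 0 and np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError("bandwidth must be positive and finite")


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-construction settings.

    ``disease_fusion_weight`` w blends the disease GIP kernel with the
    phenotype similarity (w=1 pure GIP, w=0 pure phenotype); ``tsvd_dim``
    is the truncated-SVD target dimension applied, by default, to the
    assembled pair-feature matrix (``tsvd_stage="pairs"``); set
    ``tsvd_stage="representations"`` to reduce the drug and disease
    representations separately before pairing, or ``None`` to skip.
    """

    tsvd_dim: int = 64
    disease_fusion_weight: float = 0.5
    use_drug_gip: bool = False
    tsvd_stage: Optional[Literal["pairs", "representations"]] = "pairs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tsvd_dim < 1:
            raise ValueError("tsvd_dim must be >= 1")
        if not 0.0 <= self.disease_fusion_weight <= 1.0:
            raise ValueError("disease_fusion_weight must be in [0, 1]")


def _axis_profiles(I: InteractionMatrix, axis: Axis) -> np.ndarray:
    if axis == "drugs":
        return I.drug_profiles()
    if axis == "diseases":
        return I.disease_profiles()
    raise ValueError(f"axis must be 'drugs' or 'diseases', got {axis!r}")


def gip_bandwidth(I: InteractionMatrix, axis: Axis, alpha_prime: float = 0.5) -> GipBandwidth:
    """Bandwidth alpha = alpha' / mean squared profile norm along ``axis``.

    Raises if the interaction matrix is all-zero: without any known
    interaction every profile is empty and the kernel is undefined.
    """
    profiles = _axis_profiles(I, axis)
    mean_sq = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError(
            "GIP bandwidth undefined: the interaction matrix has no known interactions"
        )
    return GipBandwidth(alpha_prime, alpha_prime / mean_sq, profiles.shape[0])


def gip_kernel(I: InteractionMatrix, axis: Axis, alpha_prime: float = 0.5) -> SimilarityMatrix:
    """Gaussian interaction profile kernel along one axis of I.

    K[i, j] = exp(-alpha * ||y_i - y_j||^2); symmetric, unit diagonal,
    entries in (0, 1], positive semidefinite.
    """
    bw = gip_bandwidth(I, axis, alpha_prime)
    profiles = _axis_profiles(I, axis)
    sq = (profiles ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-bw.alpha * d2)
    np.fill_diagonal(K, 1.0)
    index = I.rows if axis == "drugs" else I.cols
    return SimilarityMatrix(K, index)


def profile_cosine_similarity(I: InteractionMatrix, axis: Axis) -> SimilarityMatrix:
    """Cosine similarity of interaction profiles along one axis of I.

    For drugs, entry (i, j) is |y_i ∩ y_j| / (‖y_i‖·‖y_j‖) over the binary
    profiles — the standard shared-partner similarity of a bipartite
    network.  Entities with empty profiles get zero similarity to everyone
    (diagonal still 1).
    """
    profiles = _axis_profiles(I, axis)
    norms = np.linalg.norm(profiles, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    C = (profiles @ profiles.T) / np.outer(safe, safe)
    np.clip(C, 0.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    index = I.rows if axis == "drugs" else I.cols
    return SimilarityMatrix(C, index)


def disease_representation(
    ds: BenchmarkDataset, K_gip: SimilarityMatrix, w: float
) -> np.ndarray:
    """Per-disease feature rows: w * GIP kernel row + (1-w) * phenotype row."""
    if K_gip.index != ds.diseases:
        raise ValueError("GIP kernel index does not match the disease index")
    if not 0.0 <= w <= 1.0:
        raise ValueError("fusion weight must be in [0, 1]")
    return w * K_gip.values + (1.0 - w) * ds.disease_sim.values


def drug_representation(
    ds: BenchmarkDataset,
    S_boosted: SimilarityMatrix,
    use_drug_gip: bool = False,
    alpha_prime: float = 0.5,
) -> np.ndarray:
    """Per-drug feature rows: the (boosted) similarity row, optionally
    concatenated with the drug-axis GIP kernel row."""
    if S_boosted.index != ds.drugs:
        raise ValueError("boosted similarity index does not match the drug index")
    rows = S_boosted.values
    if use_drug_gip:
        K = gip_kernel(ds.interactions, "drugs", alpha_prime)
        rows = np.hstack([rows, K.values])
    return rows


def _svd_with_sign(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with a deterministic sign convention: the largest-magnitude
    component of each right singular vector is made positive."""
    U, s, Vt = scipy.linalg.svd(np.asarray(X, dtype=np.float64), full_matrices=False)
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U, s, Vt


def tsvd_reduce(X: np.ndarray, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Rank-k truncated SVD projection of the rows of X.

    Returns (U_k * diag(s_k), s_k) with columns ordered by descending
    singular value.  ``k`` beyond the numerical rank simply yields trailing
    zero columns; ``k`` beyond min(X.shape) is an error.  ``seed`` is
    accepted for interface uniformity; the decomposition is deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(X.shape)={min(X.shape)}")
    U, s, _ = _svd_with_sign(X)
    return U[:, :k] * s[:k], s[:k]


class TruncatedSVDReducer:
    """Fit a rank-k SVD basis on one matrix and project others onto it.

    Used in cross-validation so the basis is estimated from training rows
    only and test rows are projected, never refit.
    """

    def __init__(self, k: int):
        self.k = k
        self.components_: np.ndarray | None = None  # (k, n_features)
        self.singular_values_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "TruncatedSVDReducer":
        X = np.asarray(X, dtype=np.float64)
        if self.k > min(X.shape):
            raise ValueError(f"k={self.k} exceeds min(X.shape)={min(X.shape)}")
        _, s, Vt = _svd_with_sign(X)
        self.components_ = Vt[: self.k]
        self.singular_values_ = s[: self.k]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("reducer is not fitted")
        return np.asarray(X, dtype=np.float64) @ self.components_.T

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class PairFeatureTable:
    """One feature row per (drug, disease) pair.

    ``pair_indices`` holds 0-based (drug, disease) positions; ``drug_ids``
    and ``disease_ids`` the corresponding identifiers, row-aligned with
    ``features``.  ``labels`` (0/1), when present, come from the
    interaction matrix.
    """

    features: np.ndarray
    pair_indices: np.ndarray
    drug_ids: list[str]
    disease_ids: list[str]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.pair_indices = np.asarray(self.pair_indices, dtype=np.int64)
        n = self.features.shape[0]
        if self.pair_indices.shape != (n, 2):
            raise ValueError("pair_indices must be (n_rows, 2)")
        if len(self.drug_ids) != n or len(self.disease_ids) != n:
            raise ValueError("id lists must align with feature rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must align with feature rows")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def width(self) -> int:
        return self.features.shape[1]

    def with_features(self, features: np.ndarray) -> "PairFeatureTable":
        return PairFeatureTable(
            features, self.pair_indices, self.drug_ids, self.disease_ids, self.labels
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=[f"f{j}" for j in range(self.width)])
        df.insert(0, "disease_id", self.disease_ids)
        df.insert(0, "drug_id", self.drug_ids)
        if self.labels is not None:
            df["label"] = self.labels
        return df


def assemble_pairs(
    drug_repr: np.ndarray,
    disease_repr: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    ds: BenchmarkDataset,
    labels: Optional[np.ndarray] = None,
) -> PairFeatureTable:
    """Concatenate the drug row and the disease row for each pair.

    Row order follows ``pairs``; feature width is the sum of the two
    representation widths.
    """
    pairs_arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs_arr.size:
        if pairs_arr[:, 0].min() < 0 or pairs_arr[:, 0].max() >= drug_repr.shape[0]:
            raise IndexError("drug index out of range")
        if pairs_arr[:, 1].min() < 0 or pairs_arr[:, 1].max() >= disease_repr.shape[0]:
            raise IndexError("disease index out of range")
    feats = np.hstack([drug_repr[pairs_arr[:, 0]], disease_repr[pairs_arr[:, 1]]])
    return PairFeatureTable(
        features=feats,
        pair_indices=pairs_arr,
        drug_ids=[ds.drugs.ids[i] for i in pairs_arr[:, 0]],
        disease_ids=[ds.diseases.ids[j] for j in pairs_arr[:, 1]],
        labels=labels,
    )
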
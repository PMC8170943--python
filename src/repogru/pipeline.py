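"""End-to-end feature pipeline: similarity processing -> GIP kernels ->
representation fusion -> truncated SVD -> GRU scorer.

The central correctness concern is leakage control: the GIP kernels and the
cluster boosting are functions of the known interactions, so inside
cross-validation they must be recomputed from the *training* interactions
only, with the held-out positive cells zeroed.  Every function here
therefore takes the interaction matrix to condition on explicitly rather
than reading it from the dataset bundle.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import BenchmarkDataset, InteractionMatrix, SimilarityMatrix
from .features import (
    FeatureConfig,
    PairFeatureTable,
    TruncatedSVDReducer,
    assemble_pairs,
    disease_representation,
    drug_representation,
    gip_kernel,
    profile_cosine_similarity,
    tsvd_reduce,
)
from .gru import GruParameters, TrainConfig, predict, train
from .similarity import (
    ClusteringConfig,
    LogisticParams,
    boost_with_clusters,
    cluster_one,
    logistic_adjust,
)

__all__ = ["PipelineConfig", "FittedPipeline", "build_representations",
           "fit_pipeline", "derive_seed"]


def derive_seed(seed: int, label: str) -> int:
    """Deterministically derive a stage seed below 2**31 from a global seed.

    SHA-256 of ``"{seed}:{label}"`` reduced mod 2**31; stable across runs
    and platforms, so any stage can be re-run in isolation.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the prediction pipeline in one place."""

    logistic: LogisticParams = field(default_factory=LogisticParams)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    alpha_prime: float = 0.5
    use_cluster_boost: bool = True
    threshold: float = 0.5
    negative_ratio: float = 1.0
    n_folds: int = 10
    refit_per_fold: bool = True
    pooled_auc: bool = False


def build_representations(
    ds: BenchmarkDataset, I_train: np.ndarray, cfg: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-drug and per-disease representation rows, conditioned on
    ``I_train`` (the interactions the model is allowed to see).

    Drugs: logistic-adjusted chemical similarity, optionally boosted for
    pairs co-clustered in the drug-axis GIP graph of ``I_train``, optionally
    concatenated with the drug-axis GIP rows.  Diseases: convex blend of the
    disease-axis GIP kernel and the phenotype similarity.
    """
    I_view = InteractionMatrix(I_train, ds.drugs, ds.diseases)
    ds_view = ds.with_interactions(I_train)

    S_adj = logistic_adjust(ds.drug_sim, cfg.logistic)
    if cfg.use_cluster_boost:
        # drugs are grouped by their known associations: the shared-disease
        # cosine graph separates association modules far more sharply than
        # the distance-based GIP kernel does
        W_assoc = profile_cosine_similarity(I_view, "drugs")
        clusters = cluster_one(W_assoc, cfg.clustering)
        S_drug = boost_with_clusters(ds.drug_sim, S_adj, clusters)
    else:
        S_drug = S_adj

    drug_repr = drug_representation(
        ds_view, S_drug, cfg.features.use_drug_gip, cfg.alpha_prime
    )
    K_dis = gip_kernel(I_view, "diseases", cfg.alpha_prime)
    disease_repr = disease_representation(
        ds, K_dis, cfg.features.disease_fusion_weight
    )

    if cfg.features.tsvd_stage == "representations":
        k_d = min(cfg.features.tsvd_dim, *drug_repr.shape)
        k_s = min(cfg.features.tsvd_dim, *disease_repr.shape)
        drug_repr, _ = tsvd_reduce(drug_repr, k_d, cfg.features.seed)
        disease_repr, _ = tsvd_reduce(disease_repr, k_s, cfg.features.seed)
    return drug_repr, disease_repr


@dataclass
class FittedPipeline:
    """A trained scorer plus everything needed to score new pairs."""

    config: PipelineConfig
    ds: BenchmarkDataset
    drug_repr: np.ndarray
    disease_repr: np.ndarray
    reducer: Optional[TruncatedSVDReducer]
    params: GruParameters
    train_config: TrainConfig
    loss_history: list[float]

    def featurize(self, pairs: Sequence[tuple[int, int]],
                  labels: Optional[np.ndarray] = None) -> PairFeatureTable:
        table = assemble_pairs(self.drug_repr, self.disease_repr, pairs, self.ds, labels)
        if self.reducer is not None:
            table = table.with_features(self.reducer.transform(table.features))
        return table

    def score_pairs(self, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
        """Predicted interaction probability for each (drug, disease) pair."""
        return predict(self.params, self.featurize(pairs), self.train_config)


def fit_pipeline(
    ds: BenchmarkDataset,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    cfg: PipelineConfig,
    I_train: Optional[np.ndarray] = None,
) -> FittedPipeline:
    """Build representations from ``I_train`` (default: all interactions),
    featurize the training pairs, fit the reducer and train the classifier.

    The truncated-SVD dimension is capped at what the training matrix can
    support; the classifier's ``timesteps`` must divide the final width.
    """
    if I_train is None:
        I_train = ds.interactions.values
    drug_repr, disease_repr = build_representations(ds, I_train, cfg)
    table = assemble_pairs(drug_repr, disease_repr, train_pairs, ds, train_labels)

    reducer = None
    if cfg.features.tsvd_stage == "pairs":
        k = min(cfg.features.tsvd_dim, *table.features.shape)
        reducer = TruncatedSVDReducer(k).fit(table.features)
        table = table.with_features(reducer.transform(table.features))

    tcfg = cfg.train
    if table.width % tcfg.timesteps != 0:
        raise ValueError(
            f"feature width {table.width} is not divisible by "
            f"timesteps {tcfg.timesteps}"
        )
    params, history = train(table, tcfg)
    return FittedPipeline(
        config=cfg, ds=ds, drug_repr=drug_repr, disease_repr=disease_repr,
        reducer=reducer, params=params, train_config=tcfg, loss_history=history,
    )
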
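import numpy as np
import pytest

from repogru import (
    BenchmarkDataset,
    EntityIndex,
    FeatureConfig,
    InteractionMatrix,
    PipelineConfig,
    SimilarityMatrix,
    SyntheticConfig,
    TrainConfig,
    generate,
)
from repogru.similarity import ClusteringConfig


@pytest.fixture(scope="session")
def small_ds():
    """A small planted-block dataset shared across tests (read-only)."""
    ds, truth = generate(SyntheticConfig(m=60, n=40, k_blocks=3, seed=1))
    return ds, truth


@pytest.fixture
def fast_cfg():
    """Pipeline configuration scaled down for quick unit tests."""
    return PipelineConfig(
        features=FeatureConfig(tsvd_dim=16),
        train=TrainConfig(hidden=16, epochs=5, batch_size=32, seed=0),
        clustering=ClusteringConfig(),
    )


@pytest.fixture
def toy_ds():
    """A hand-written 3-drug x 2-disease dataset."""
    drugs = EntityIndex(("DB0001", "DB0002", "DB0003"))
    diseases = EntityIndex(("D100", "D200"))
    sd = np.array([[1.0, 0.6, 0.1], [0.6, 1.0, 0.2], [0.1, 0.2, 1.0]])
    sdis = np.array([[1.0, 0.3], [0.3, 1.0]])
    inter = np.array([[1, 0], [0, 1], [0, 0]])
    return BenchmarkDataset(
        drug_sim=SimilarityMatrix(sd, drugs),
        disease_sim=SimilarityMatrix(sdis, diseases),
        interactions=InteractionMatrix(inter, drugs, diseases),
    )
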
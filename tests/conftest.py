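import numpy as np
import pytest

from enhancerstate.cluster_model import (
    CLUSTERING_MARKS,
    FeatureMatrix,
    characterize_clusters,
    kmeans_cluster,
)
from enhancerstate.pipeline import build_matrices
from enhancerstate.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def study(default_config):
    """One fully simulated study at the default configuration."""
    return simulate_study(default_config)


@pytest.fixture(scope="session")
def study_matrices(study):
    """Per-mark signal matrices over all TFBSs of the default study."""
    return build_matrices(study.tfbs, study.tracks)


@pytest.fixture(scope="session")
def cluster_result(study, study_matrices):
    """K-means model and cluster signatures for the default study."""
    features = FeatureMatrix.from_matrices(
        [study_matrices[m] for m in CLUSTERING_MARKS]
    )
    model = kmeans_cluster(features, K=10, seed=0, n_restarts=10)
    signatures = characterize_clusters(model, study_matrices)
    return model, signatures


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
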
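import numpy as np
import pytest

from modflux.dynamics import InfluenceModel, TimeCourse, simulate_trajectory
from modflux.synthetic import make_truth


@pytest.fixture(scope="session")
def truth():
    """A small planted study: 10 clusters, sparse stable influences."""
    return make_truth(n_clusters=10, edge_density=0.1, seed=3,
                      sigma_obs=0.0, sigma_gene=0.0)


@pytest.fixture(scope="session")
def noisefree_dataset(truth):
    from modflux.synthetic import generate_expression_dataset

    return generate_expression_dataset(truth)


@pytest.fixture(scope="session")
def lps_course(noisefree_dataset):
    _, _, _, profiles = noisefree_dataset
    return TimeCourse.from_profiles(profiles, "lps")


@pytest.fixture
def toy_model():
    """3 clusters with a couple of signed influences and fast/slow decay."""
    weights = np.array([[0.0, 0.5, 0.0],
                        [0.0, 0.0, -0.3],
                        [0.0, 0.0, 0.0]])
    return InfluenceModel.from_weights(
        weights, tau=np.array([10.0, 20.0, 40.0]), gene_counts=[5, 3, 2]
    )


@pytest.fixture
def toy_course(toy_model):
    times = np.array([3.0, 24.0, 72.0, 75.0, 96.0])
    init = np.array([1.0, -0.5, 0.8])
    traj = simulate_trajectory(toy_model, init, times)
    return TimeCourse("toy", times, traj.values)
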
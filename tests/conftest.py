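import numpy as np
import pytest

import rmtnet
from helpers import net_from_edges


@pytest.fixture(scope="session")
def community():
    """Default planted-block community: 4 blocks x 20 OTUs + 120 background,
    30 samples, within-block r = 0.9, seed 1."""
    return rmtnet.generate_community(seed=1)


@pytest.fixture(scope="session")
def community_std(community):
    return rmtnet.standardize_rows(community.table)


@pytest.fixture(scope="session")
def community_sim(community_std):
    return rmtnet.similarity_from_correlation(rmtnet.correlation_matrix(community_std))


@pytest.fixture(scope="session")
def community_scan(community_sim):
    return rmtnet.detect_threshold(community_sim)


@pytest.fixture(scope="session")
def community_net(community_sim, community_scan):
    return rmtnet.build_network(community_sim, community_scan.final_threshold)


@pytest.fixture
def triangle():
    return net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star4():
    return net_from_edges([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def path3():
    return net_from_edges([("1", "2"), ("2", "3")])


@pytest.fixture
def two_triangles():
    return net_from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture
def small_table():
    values = np.array([[2.0, 1.0, 4.0], [3.0, 1.0, 2.0], [5.0, 8.0, 4.0]])
    return rmtnet.AbundanceTable(["o1", "o2", "o3"], ["s1", "s2", "s3"], values)
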
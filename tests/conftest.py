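import numpy as np
import pytest

from apoescreen import datasets
from apoescreen.synthetic import PoseSpec, build_pose_complex


@pytest.fixture(scope="session")
def benchmark_matrix():
    return datasets.load_known_ligand_ranks()


@pytest.fixture(scope="session")
def benchmark_kd():
    return datasets.load_known_ligand_kd()


@pytest.fixture(scope="session")
def full_pose():
    """Toy pose with both Asp H-bonds, a parallel stack and a buried propyl."""
    return build_pose_complex(PoseSpec(
        hbond_requests=(("ASP35", 2.9), ("ASP153", 3.0)),
        pistack_request=(3.7, 10.0),
        occupancy_request=3,
        seed=11,
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
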
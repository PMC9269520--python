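import numpy as np
import pytest

from gaitgcn.graph import SkeletonGraph, kinect_v2_graph


@pytest.fixture(scope="session")
def kinect():
    return kinect_v2_graph()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree(rng: np.random.Generator, num_joints: int) -> SkeletonGraph:
    """Uniformly random labeled tree with a random center joint."""
    edges = [
        (int(rng.integers(0, i)), i) for i in range(1, num_joints)
    ]
    center = int(rng.integers(0, num_joints))
    return SkeletonGraph(
        num_joints=num_joints, edges=tuple(edges), center_joint=center
    )


@pytest.fixture
def random_tree_factory(rng):
    return lambda v: random_tree(rng, v)
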
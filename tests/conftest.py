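import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from scsc import AdjacencyMatrix, TrajectoryEnsemble  # noqa: E402


@pytest.fixture
def triangle_adjacency():
    """Three states with hand-checkable degrees (3, 4, 5)."""
    return AdjacencyMatrix([[0, 1, 2], [1, 0, 3], [2, 3, 0]])


@pytest.fixture
def pair_adjacency():
    """Two maximally simple states: eigenvalues {2, 0}."""
    return AdjacencyMatrix([[0, 1], [1, 0]])


def hierarchical_block_adjacency(
    block_size: int = 10, noise: float = 0.02, seed: int = 0
) -> tuple[AdjacencyMatrix, np.ndarray]:
    """Four planted blocks with hierarchically balanced dissimilarities.

    Within-block dissimilarity is weak; the block-level structure is
    {A,B} vs {C,D} (strong) above A vs B and C vs D (medium), so the
    four blocks resolve in exactly two bifurcation levels.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(4), block_size)
    n = labels.size
    base = np.array(
        [
            [0.1, 0.6, 1.0, 1.0],
            [0.6, 0.1, 1.0, 1.0],
            [1.0, 1.0, 0.1, 0.6],
            [1.0, 1.0, 0.6, 0.1],
        ]
    )
    values = base[np.ix_(labels, labels)] + noise * rng.random((n, n))
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return AdjacencyMatrix(values), labels


@pytest.fixture
def block_adjacency():
    return hierarchical_block_adjacency()


@pytest.fixture
def small_ensemble():
    """Two states, two samples, pair distances 1 then 3 (metric = sqrt2/2)."""
    positions = np.array([[[0.0, 0.0], [0.0, 0.0]], [[1.0, 0.0], [3.0, 0.0]]])
    return TrajectoryEnsemble(positions=positions, times=np.array([0.0, 1.0]))
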
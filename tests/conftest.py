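import numpy as np
import pytest

from orssg.core import Entity, SceneGraph, SceneSequence
from orssg.synthetic import SimConfig, simulate_timeline


@pytest.fixture
def small_graph() -> SceneGraph:
    g = SceneGraph(0)
    g.add_node(Entity("hs1", "head surgeon", centroid=(0.0, -0.6, 1.0)))
    g.add_node(Entity("p1", "patient", centroid=(0.2, 0.0, 1.0)))
    g.add_node(Entity("table", "operating table", centroid=(0.0, 0.0, 0.45)))
    g.add_edge("hs1", "Sawing", "p1")
    g.add_edge("p1", "LyingOn", "table")
    return g


@pytest.fixture
def small_sequence(small_graph) -> SceneSequence:
    graphs = []
    for i in range(5):
        g = small_graph.copy()
        g.frame_id = i
        graphs.append(g)
    return SceneSequence(take_id="t0", graphs=graphs, fps=1.0)


@pytest.fixture(scope="session")
def graph_take():
    """A cheap (no-render) simulated take shared across tests."""
    return simulate_timeline(SimConfig(seed=42, take_length_s=120.0, render=False))


@pytest.fixture(scope="session")
def rendered_take():
    """A short fully rendered take shared across tests."""
    return simulate_timeline(
        SimConfig(seed=7, take_length_s=24.0, render=True, points_per_entity=250)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
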
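import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from motifvar import SampledGraph, enumerate_connected_motifs, parse_motif_spec


@pytest.fixture(scope="session")
def catalog4():
    return enumerate_connected_motifs(4)


@pytest.fixture(scope="session")
def catalog_all():
    out = []
    for k in (3, 4, 5):
        out.extend(enumerate_connected_motifs(k))
    return tuple(out)


@pytest.fixture
def named():
    return {
        name: parse_motif_spec(name)
        for name in ("edge", "wedge", "triangle", "claw", "paw", "square",
                     "diamond", "k4", "bowtie", "path4")
    }


def graph_from_edges(n, edges):
    return SampledGraph(n=n, edges=np.array(sorted(edges), dtype=np.int64))


@pytest.fixture
def k4_graph():
    return graph_from_edges(4, [(a, b) for a in range(4) for b in range(a + 1, 4)])
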
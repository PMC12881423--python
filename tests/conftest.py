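import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from hyperdriver import PathwayCollection, build_hypergraph  # noqa: E402
from hyperdriver.synthetic import SyntheticSpec, generate_hypergraph, plant_drivers  # noqa: E402


@pytest.fixture
def toy_hypergraph():
    """3 genes, 2 pathways: A={g1,g2}, B={g2,g3}."""
    pc = PathwayCollection(
        pathways=[("A", frozenset({"G1", "G2"})), ("B", frozenset({"G2", "G3"}))]
    )
    return build_hypergraph(pc)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-driver benchmark shared across model/eval tests."""
    spec = SyntheticSpec(
        n_genes=400,
        n_pathways=50,
        edge_size_range=(5, 20),
        n_driver_pathways=8,
        n_cancer_types=4,
        samples_per_type=10,
        seed=11,
    )
    hg = generate_hypergraph(spec)
    labels, fm, omics = plant_drivers(hg, spec)
    return spec, hg, labels, fm, omics


def random_hypergraph(rng: np.random.Generator, n_max: int = 30, m_max: int = 10):
    """Random small hypergraph over an explicit universe (isolated genes allowed)."""
    from hyperdriver.hypergraph import hypergraph_from_memberships

    n = int(rng.integers(3, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    genes = [f"G{i:03d}" for i in range(n)]
    memberships = []
    for _ in range(m):
        size = int(rng.integers(1, n + 1))
        memberships.append(rng.choice(n, size=size, replace=False).tolist())
    hg = hypergraph_from_memberships(genes, [f"P{j}" for j in range(m)], memberships)
    hg.edge_weights = rng.uniform(0.1, 5.0, size=m)
    return hg
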
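import numpy as np
import pytest

from jointpwm import ContactModel, PWM, PWMDataset, SimilarityGraph


@pytest.fixture
def simple_model() -> ContactModel:
    """4 contacting DBD positions x 3 binding-site positions.

    Keys: position 0 for j=0, 1 for j=1, 2 for j=2; position 3 is a weak
    secondary contact only.
    """
    M = np.array(
        [
            [0.90, 0.10, 0.00],
            [0.30, 0.85, 0.20],
            [0.05, 0.30, 0.90],
            [0.20, 0.05, 0.30],
        ]
    )
    return ContactModel(M)


@pytest.fixture
def two_node_graph() -> SimilarityGraph:
    """Two cores joined by mutual unit-weight edges at position 0."""
    return SimilarityGraph(
        j=0,
        nodes=("AAAA", "CCCC"),
        edges={("AAAA", "CCCC"): 1.0, ("CCCC", "AAAA"): 1.0},
    )


@pytest.fixture
def one_hot_columns() -> dict[str, np.ndarray]:
    return {
        "AAAA": np.array([1.0, 0.0, 0.0, 0.0]),
        "CCCC": np.array([0.0, 1.0, 0.0, 0.0]),
    }


def random_columns(rng: np.random.Generator, nodes) -> dict[str, np.ndarray]:
    return {a: rng.dirichlet(np.ones(4)) for a in nodes}


def random_graph(
    rng: np.random.Generator, n_nodes: int, j: int = 0, out_degree: int = 3
) -> SimilarityGraph:
    """Random directed graph with normalized out-weights (possibly isolated nodes)."""
    nodes = tuple(f"N{i:04d}" for i in range(n_nodes))
    edges = {}
    for a in nodes:
        deg = int(rng.integers(0, out_degree + 1))
        if deg == 0 or n_nodes < 2:
            continue
        others = [b for b in nodes if b != a]
        targets = rng.choice(len(others), size=min(deg, len(others)), replace=False)
        raw = rng.uniform(0.1, 1.0, size=len(targets))
        raw /= raw.sum()
        for t, w in zip(targets, raw):
            edges[(a, others[t])] = float(w)
    return SimilarityGraph(j=j, nodes=nodes, edges=edges)


def random_dataset(rng: np.random.Generator, cores, k: int = 3) -> PWMDataset:
    entries = {
        a: PWM(np.column_stack([rng.dirichlet(np.ones(4)) for _ in range(k)]))
        for a in cores
    }
    return PWMDataset(entries, k=k)
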
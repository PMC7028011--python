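"""Per-position similarity graphs over core sequences.

For every binding-site position ``j`` we build a directed weighted graph
``G_j`` whose edge weight ``w_j(a, a')`` encodes the structural prior that
cores ``a`` and ``a'`` share specificity at position ``j``:

* pairs differing in more than ``max_mismatch`` base-contacting positions
  carry no expectation of similarity (weight 0 at every ``j``);
* a mismatch at the key position of ``j`` voids the prior at ``j``;
* otherwise the unnormalized weight is the product of ``1 - M[i, j]`` over
  the differing contacting positions ``i`` -- for the single-mismatch
  setting appropriate to C2H2 zinc fingers this is exactly ``1 - M[i, j]``
  for the one differing position, while ``max_mismatch = 4`` covers the
  homeodomain setting.

Weights are then normalized per node so that each node's outgoing weights
sum to 1; nodes with no positive-weight partner at ``j`` stay isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .interface_model import ContactModel
from .pwm_io import PWMDataset

logger = logging.getLogger(__name__)


class GraphError(ValueError):
    pass


@dataclass
class SimilarityGraph:
    """Directed weighted graph at one binding-site position.

    ``edges[(a, a')]`` holds the (normalized) weight of the edge a -> a';
    zero-weight pairs are absent rather than stored.
    """

    j: int
    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        node_set = set(self.nodes)
        for (a, b), w in self.edges.items():
            if a == b:
                raise GraphError(f"self-edge on {a} at position {self.j}")
            if a not in node_set or b not in node_set:
                raise GraphError(f"edge ({a}, {b}) references an unknown node")
            if not 0 < w <= 1 + 1e-9:
                raise GraphError(f"edge ({a}, {b}) weight {w} outside (0, 1]")

    def out_weights(self, a: str) -> dict[str, float]:
        return {b: w for (src, b), w in self.edges.items() if src == a}

    def out_degree(self, a: str) -> int:
        return sum(1 for (src, _b) in self.edges if src == a)

    @property
    def non_isolated(self) -> set[str]:
        """Nodes with at least one outgoing edge."""
        return {a for (a, _b) in self.edges}

    def to_sparse(self, order: Sequence[str]) -> sparse.csr_matrix:
        """Row-stochastic weight matrix W (rows without edges are all zero)."""
        index = {a: i for i, a in enumerate(order)}
        rows, cols, data = [], [], []
        for (a, b), w in self.edges.items():
            if a in index and b in index:
                rows.append(index[a])
                cols.append(index[b])
                data.append(w)
        n = len(order)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def pair_weights_unnormalized(
    a: str, a_prime: str, model: ContactModel, max_mismatch: int = 1
) -> np.ndarray:
    """Unnormalized weight vector (length k) for an ordered core pair.

    The vector is symmetric in ``(a, a')``; any asymmetry in the final graphs
    comes only from per-node normalization.
    """
    if a == a_prime:
        raise GraphError(f"pair weights are undefined for identical cores ({a})")
    n = model.n_contacting
    if len(a) != n or len(a_prime) != n:
        raise GraphError(
            f"cores must have length {n} (one residue per base-contacting position)"
        )
    if max_mismatch < 1:
        raise GraphError("max_mismatch must be a positive integer")
    diff_dbd = [
        model.base_contacting[p] for p in range(n) if a[p] != a_prime[p]
    ]
    k = model.k
    if len(diff_dbd) > max_mismatch:
        return np.zeros(k)
    w = np.zeros(k)
    for j in range(k):
        key = model.key_positions[j]
        if key is None or key in diff_dbd:
            continue
        w[j] = float(np.prod([1.0 - model.M[i, j] for i in diff_dbd]))
    return w


def build_graphs(
    cores: Iterable[str], model: ContactModel, max_mismatch: int = 1
) -> list[SimilarityGraph]:
    """Build one normalized similarity graph per binding-site position."""
    cores = list(cores)
    if len(set(cores)) != len(cores):
        raise GraphError("core sequences must be unique")
    k = model.k
    raw: list[dict[tuple[str, str], float]] = [dict() for _ in range(k)]
    for ia in range(len(cores)):
        for ib in range(ia + 1, len(cores)):
            a, b = cores[ia], cores[ib]
            w = pair_weights_unnormalized(a, b, model, max_mismatch)
            for j in np.flatnonzero(w > 0):
                raw[int(j)][(a, b)] = w[j]
                raw[int(j)][(b, a)] = w[j]
    graphs = []
    for j in range(k):
        out_sum: dict[str, float] = {}
        for (a, _b), w in raw[j].items():
            out_sum[a] = out_sum.get(a, 0.0) + w
        edges = {
            (a, b): w / out_sum[a] for (a, b), w in raw[j].items()
        }
        graphs.append(SimilarityGraph(j=j, nodes=tuple(cores), edges=edges))
    return graphs


def filter_isolated(dataset: PWMDataset, graphs: Sequence[SimilarityGraph]) -> PWMDataset:
    """Drop cores with no outgoing edge at any binding-site position.

    Such cores have no partner with a positive similarity prior, so joint
    inference would leave them untouched anyway; removing them mirrors the
    isolated-core filtering applied when preparing real datasets.
    """
    connected: set[str] = set()
    for g in graphs:
        connected |= g.non_isolated
    keep = [c for c in dataset.cores if c in connected]
    removed = len(dataset) - len(keep)
    if removed:
        logger.info(
            "filter_isolated: removed %d of %d cores with no similarity partner",
            removed,
            len(dataset),
        )
    return dataset.subset(keep)


def permute_nodes(
    graphs: Sequence[SimilarityGraph], seed: int, shared: bool = False
) -> list[SimilarityGraph]:
    """Randomize core-sequence relationships by relabelling graph nodes.

    One random bijection over the node set is drawn per graph (or a single
    shared bijection with ``shared=True``) and applied to the edge endpoints.
    The weight multiset and out-degree sequence are preserved, so this is the
    null in which graph topology is kept but its association with specific
    cores is destroyed.
    """
    rng = np.random.default_rng(seed)
    out = []
    shared_map: dict[str, str] | None = None
    for g in graphs:
        if shared and shared_map is not None:
            mapping = shared_map
        else:
            perm = rng.permutation(len(g.nodes))
            mapping = {a: g.nodes[p] for a, p in zip(g.nodes, perm)}
            if shared:
                shared_map = mapping
        edges = {(mapping[a], mapping[b]): w for (a, b), w in g.edges.items()}
        out.append(SimilarityGraph(j=g.j, nodes=g.nodes, edges=edges))
    return out


# ---------------------------------------------------------------------------
# edge-list TSV (binding-site positions are 1-based in files)


def write_graphs(graphs: Sequence[SimilarityGraph], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("j\tsource_core\ttarget_core\tweight\n")
        for g in graphs:
            for (a, b), w in sorted(g.edges.items()):
                fh.write(f"{g.j + 1}\t{a}\t{b}\t{w:.12g}\n")


def read_graphs(path: str | Path, nodes: Iterable[str] | None = None) -> list[SimilarityGraph]:
    """Read normalized edge lists; *nodes* may add isolated nodes."""
    path = Path(path)
    per_j: dict[int, dict[tuple[str, str], float]] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("j\t"):
            raise GraphError(f"{path}: missing edge-list header")
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise GraphError(f"{path}, line {ln}: expected 4 columns")
            j = int(parts[0]) - 1
            per_j.setdefault(j, {})[(parts[1], parts[2])] = float(parts[3])
    node_set: set[str] = set(nodes) if nodes is not None else set()
    for edges in per_j.values():
        for a, b in edges:
            node_set.add(a)
            node_set.add(b)
    order = tuple(sorted(node_set))
    k = max(per_j) + 1 if per_j else 0
    return [
        SimilarityGraph(j=j, nodes=order, edges=per_j.get(j, {})) for j in range(k)
    ]
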
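"""Weighted-graph utilities: density and Markov Chain Clustering (MCL).

MCL alternates expansion (matrix power) and inflation (elementwise power
with column renormalization) on a column-stochastic matrix until the matrix
stops changing, then reads clusters off the attractor structure. The dense
implementation is deliberate: the graphs this pipeline builds (CPs, CPCs,
motifs) have at most a few thousand nodes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)


class WeightedGraph:
    """Undirected weighted graph with hashable node ids and optional part
    labels enforcing multi-partite edge constraints."""

    def __init__(self) -> None:
        self.nodes: list[Hashable] = []
        self._index: dict[Hashable, int] = {}
        self.part: dict[Hashable, Hashable] = {}
        self.edges: dict[tuple[int, int], float] = {}

    def add_node(self, node: Hashable, part: Optional[Hashable] = None) -> None:
        if node not in self._index:
            self._index[node] = len(self.nodes)
            self.nodes.append(node)
        if part is not None:
            self.part[node] = part

    def add_edge(self, a: Hashable, b: Hashable, weight: float) -> None:
        if a == b:
            raise ValueError("self-loops not allowed")
        if weight <= 0:
            raise ValueError("edge weights must be strictly positive")
        if a in self.part and b in self.part and self.part[a] == self.part[b]:
            raise ValueError(f"edge within part {self.part[a]!r} violates multi-partite constraint")
        self.add_node(a)
        self.add_node(b)
        i, j = self._index[a], self._index[b]
        self.edges[(min(i, j), max(i, j))] = float(weight)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        n = self.n_nodes
        A = np.zeros((n, n))
        for (i, j), w in self.edges.items():
            A[i, j] = A[j, i] = w
        return A

    def to_edge_list(self) -> list[tuple[Hashable, Hashable, float]]:
        return [(self.nodes[i], self.nodes[j], w) for (i, j), w in sorted(self.edges.items())]

    @classmethod
    def from_edge_list(cls, edges: Iterable[tuple[Hashable, Hashable, float]]) -> "WeightedGraph":
        g = cls()
        for a, b, w in edges:
            g.add_edge(a, b, w)
        return g


def graph_density(g: WeightedGraph) -> Optional[float]:
    """2|E| / (|V| (|V|-1)); None when fewer than 2 nodes."""
    n = g.n_nodes
    if n < 2:
        return None
    return 2.0 * g.n_edges / (n * (n - 1))


@dataclass(frozen=True)
class MclConfig:
    inflation: float = 2.0
    expansion: int = 2
    pruning_threshold: float = 1e-5
    max_iterations: int = 100
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


@dataclass
class MclResult:
    clusters: list[list[Hashable]]
    converged: bool


def mcl(g: WeightedGraph, cfg: MclConfig = MclConfig()) -> MclResult:
    """Cluster a weighted graph with MCL.

    Self-loops are added with weight equal to each node's maximum incident
    weight (1 for isolated nodes) for numerical stability. Every node lands
    in exactly one cluster; clusters are sorted by size descending, ties by
    smallest node id. A node attracted to several attractor systems goes to
    the one with the largest total attraction, ties to the larger cluster,
    then lexicographic.
    """
    n = g.n_nodes
    if n == 0:
        return MclResult([], True)
    A = g.adjacency()
    loop = A.max(axis=0)
    loop[loop == 0] = 1.0
    A = A + np.diag(loop)
    M = A / A.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(cfg.max_iterations):
        M_new = np.linalg.matrix_power(M, cfg.expansion)
        M_new = np.power(M_new, cfg.inflation)
        M_new[M_new < cfg.pruning_threshold] = 0.0
        colsum = M_new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M_new = M_new / colsum
        delta = np.abs(M_new - M).max()
        M = M_new
        if delta < cfg.tolerance:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge within %d iterations", cfg.max_iterations)

    # attractors: rows with significant mass on the diagonal
    eps = max(cfg.pruning_threshold, 1e-9)
    attractors = np.nonzero(np.diag(M) > eps)[0]
    if len(attractors) == 0:
        attractors = np.arange(n)

    # group attractors that share any column support into attractor systems
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    att_set = set(attractors.tolist())
    for j in range(n):
        rows = [i for i in attractors if M[i, j] > eps]
        for a, b in zip(rows, rows[1:]):
            union(a, b)

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(int(a)), []).append(int(a))

    # assign every node to the system with the largest total attraction
    membership: dict[int, list[int]] = {root: [] for root in systems}
    singletons: list[list[int]] = []
    sys_size_hint = {root: len(m) for root, m in systems.items()}
    for j in range(n):
        scores = []
        for root, members in systems.items():
            total = float(sum(M[i, j] for i in members))
            scores.append((total, root))
        best_total = max(s[0] for s in scores)
        if best_total <= 0:
            singletons.append([j])  # no attraction left anywhere: own cluster
            continue
        tied = [root for total, root in scores if total == best_total]
        if len(tied) > 1:
            tied.sort(key=lambda r: (-sys_size_hint[r], str(sorted(map(str, systems[r]))[0])))
        membership[tied[0]].append(j)

    clusters = [
        sorted((g.nodes[i] for i in members), key=lambda x: str(x))
        for members in list(membership.values()) + singletons
        if members
    ]
    clusters.sort(key=lambda c: (-len(c), str(c[0])))
    return MclResult(clusters, converged)
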
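"""PPI graph topology: degrees, all-pairs distances, geodesics, Louvain clusters.

The distance between two proteins is the number of edges on a shortest path
(hop count, unit weights).  When the network has several connected
components, every cross-component pair is assigned the same finite surrogate
distance: twice the maximum finite distance observed within any component.
This keeps cross-component pairs comparable to (and strictly farther than)
any connected pair while avoiding infinities in downstream averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .datatypes import RandomPairSet
from .errors import InvalidParameterError, NoPathError

__all__ = [
    "PPINetwork", "DistanceMatrix", "PathRecord", "ClusterPartition",
    "network_from_edges", "degree", "all_pairs_distances", "shortest_path",
    "louvain_clusters", "modularity",
]


@dataclass
class PPINetwork:
    """An undirected simple interaction graph keyed by gene identifiers.

    ``planted_blocks`` is retained by the synthetic generator (node -> block
    label) so community-recovery checks can compare against ground truth;
    it is ``None`` for real networks.
    """

    graph: nx.Graph
    planted_blocks: dict[str, int] | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)


def network_from_edges(edges: Iterable[tuple[str, str]],
                       nodes: Iterable[str] | None = None) -> PPINetwork:
    """Build a simple undirected graph, dropping self-loops and duplicates.

    Duplicate records (including reversed duplicates) collapse to one edge.
    Self-loops are dropped with a warning, as are exact duplicates beyond
    the first occurrence (silently; duplication is routine in PPI exports).
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    n_loops = 0
    for (u, v) in edges:
        u, v = str(u), str(v)
        if u == v:
            n_loops += 1
            continue
        g.add_edge(u, v)
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop record(s)", stacklevel=2)
    return PPINetwork(g)


def degree(network: PPINetwork, node: str) -> int:
    """Number of edges incident on ``node``."""
    if not network.has_node(node):
        raise InvalidParameterError(f"node {node} not in network")
    return int(network.graph.degree[node])


@dataclass
class DistanceMatrix:
    """All-pairs hop-count distances with the cross-component surrogate."""

    nodes: list[str]
    matrix: np.ndarray  # int, shape (n, n)
    cross_component_value: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.nodes)}

    def d(self, u: str, v: str) -> int:
        try:
            return int(self.matrix[self._index[u], self._index[v]])
        except KeyError as err:
            raise InvalidParameterError(f"node {err.args[0]} not in distance matrix") from None

    def __contains__(self, node: str) -> bool:
        return node in self._index


def all_pairs_distances(network: PPINetwork) -> DistanceMatrix:
    """All-pairs shortest-path hop counts.

    Computed by breadth-first search from every node, which on an unweighted
    graph yields exactly the Floyd-Warshall distances (asserted by the test
    suite against a Floyd-Warshall oracle).  Cross-component entries are set
    to twice the maximum finite within-component distance over the whole
    graph (0 for an edgeless graph, where no finite distance exists).
    """
    if network.n_nodes < 1:
        raise InvalidParameterError("network must have at least one node")
    nodes = network.nodes()
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    mat = np.full((n, n), -1, dtype=np.int64)
    for u, lengths in nx.all_pairs_shortest_path_length(network.graph):
        i = idx[u]
        for v, d in lengths.items():
            mat[i, idx[v]] = d
    max_within = int(mat.max()) if n else 0
    cross = 2 * max(max_within, 0)
    mat[mat < 0] = cross
    return DistanceMatrix(nodes=nodes, matrix=mat, cross_component_value=cross)


@dataclass(frozen=True)
class PathRecord:
    """One recorded geodesic from source to target."""

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise InvalidParameterError("a path needs at least one node")

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    @property
    def intermediates(self) -> tuple[str, ...]:
        return self.nodes[1:-1]


def shortest_path(network: PPINetwork, source: str, target: str) -> PathRecord:
    """One canonical geodesic between two nodes of the same component.

    Several geodesics may exist; to make the recorded path deterministic the
    path is reconstructed backwards from the target, always stepping to the
    lexicographically smallest neighbor one BFS layer closer to the source.
    """
    g = network.graph
    for node in (source, target):
        if not g.has_node(node):
            raise InvalidParameterError(f"node {node} not in network")
    dist = nx.single_source_shortest_path_length(g, source)
    if target not in dist:
        raise NoPathError(f"{source} and {target} are in different components")
    path = [target]
    current = target
    while current != source:
        layer = dist[current] - 1
        current = min(u for u in g.neighbors(current) if dist.get(u) == layer)
        path.append(current)
    path.reverse()
    # consecutive adjacency is guaranteed by construction
    return PathRecord(nodes=tuple(path))


@dataclass
class ClusterPartition:
    """A hard partition of the network nodes with its modularity score.

    Cluster ids are renumbered 0,1,2,... by decreasing cluster size
    (ties by smallest member id) for stable reporting.
    """

    assignment: dict[str, int]
    modularity_q: float

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out

    def same_cluster(self, u: str, v: str) -> bool:
        try:
            return self.assignment[u] == self.assignment[v]
        except KeyError as err:
            raise InvalidParameterError(f"node {err.args[0]} not in partition") from None

    def clusters_min_size(self, k: int = 2) -> dict[int, set[str]]:
        """Clusters with at least ``k`` members (analysis usually ignores singletons)."""
        return {cid: m for cid, m in self.clusters().items() if len(m) >= k}


def _renumber(communities: Sequence[set[str]]) -> dict[str, int]:
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {node: cid for cid, comm in enumerate(ordered) for node in comm}


def modularity(network: PPINetwork, assignment: Mapping[str, int]) -> float:
    """Newman-Girvan modularity of a hard partition."""
    missing = set(network.graph.nodes) - set(assignment)
    if missing:
        raise InvalidParameterError(
            f"assignment does not cover nodes: {sorted(missing)[:5]}")
    if network.n_edges == 0:
        return 0.0
    groups: dict[int, set[str]] = {}
    for node in network.graph.nodes:
        groups.setdefault(assignment[node], set()).add(node)
    return float(nx.community.modularity(network.graph, groups.values()))


def louvain_clusters(network: PPINetwork, seed: int = 0) -> ClusterPartition:
    """Louvain modularity clustering with seeded, reproducible tie-breaking."""
    if network.n_edges == 0:
        warnings.warn("edgeless network: degenerate partition, one node per cluster",
                      stacklevel=2)
        assignment = _renumber([{v} for v in network.graph.nodes])
        return ClusterPartition(assignment=assignment, modularity_q=0.0)
    comms = nx.community.louvain_communities(network.graph, seed=seed)
    assignment = _renumber([set(c) for c in comms])
    q = modularity(network, assignment)
    return ClusterPartition(assignment=assignment, modularity_q=q)
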
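"""Network representation, edge-list I/O and component extraction.

A :class:`Network` stores the node count ``N``, the link set (unordered
pairs ``i < j`` when undirected, ordered pairs when directed) and an
optional mapping from external node labels to the contiguous 0-based
internal ids used by every matrix in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Network:
    """An unweighted simple network on nodes ``0 .. n_nodes-1``.

    Parameters
    ----------
    n_nodes : int
        Number of nodes ``N``; every link endpoint must lie in ``[0, N)``.
    links : frozenset of (int, int)
        The link set. Undirected links are stored once with ``i < j``;
        directed links are ordered ``(source, target)`` pairs.
    directed : bool
        Whether links are ordered pairs.
    node_labels : dict or None
        Optional mapping from external labels to internal ids.
    """

    n_nodes: int
    links: frozenset
    directed: bool = False
    node_labels: dict | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("a network needs at least one node")
        object.__setattr__(self, "links", frozenset(tuple(l) for l in self.links))
        for i, j in self.links:
            if i == j:
                raise ValueError(f"self-link ({i},{j}) not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"link ({i},{j}) out of range [0,{self.n_nodes})")
            if not self.directed and i > j:
                raise ValueError(f"undirected link ({i},{j}) must satisfy i < j")

    @property
    def n_links(self) -> int:
        """The link count ``E``."""
        return len(self.links)

    @property
    def average_degree(self) -> float:
        """``<k> = 2E/N`` undirected, ``E/N`` (out-degree) directed."""
        if self.directed:
            return self.n_links / self.n_nodes
        return 2 * self.n_links / self.n_nodes

    def has_link(self, i: int, j: int) -> bool:
        if self.directed:
            return (i, j) in self.links
        return (min(i, j), max(i, j)) in self.links

    def to_networkx(self) -> nx.Graph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.links)
        return g

    def adjacency(self) -> sparse.csr_matrix:
        """Boolean adjacency in CSR form; row i holds i's (out-)neighbors."""
        if not self.links:
            return sparse.csr_matrix((self.n_nodes, self.n_nodes), dtype=np.uint8)
        rows, cols = zip(*self.links)
        rows, cols = np.array(rows), np.array(cols)
        if not self.directed:
            rows, cols = np.concatenate([rows, cols]), np.concatenate([cols, rows])
        data = np.ones(len(rows), dtype=np.uint8)
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n_nodes, self.n_nodes))


def _canonical(i: int, j: int, directed: bool) -> tuple:
    return (i, j) if directed else (min(i, j), max(i, j))


def from_edges(edges, n_nodes: int, directed: bool = False, node_labels=None) -> Network:
    """Build a Network from an edge iterable, dropping self-loops and duplicates."""
    links = set()
    dropped = 0
    for i, j in edges:
        if i == j:
            dropped += 1
            continue
        pair = _canonical(i, j, directed)
        if pair in links:
            dropped += 1
        else:
            links.add(pair)
    if dropped:
        logger.info("dropped %d self-loop/duplicate links", dropped)
    return Network(n_nodes=n_nodes, links=frozenset(links), directed=directed,
                   node_labels=node_labels)


def read_edge_list(path, directed: bool = False) -> Network:
    """Read a whitespace-delimited edge list.

    One link per line: ``source target [ignored...]``. Lines starting with
    ``#`` are comments. External labels are mapped to contiguous 0-based
    ids in first-appearance order; duplicate links and self-loops are
    dropped with a logged count.
    """
    labels: dict = {}
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least 2 tokens, got {len(tokens)}")
            ids = []
            for tok in tokens[:2]:
                if tok not in labels:
                    labels[tok] = len(labels)
                ids.append(labels[tok])
            edges.append(tuple(ids))
    return from_edges(edges, n_nodes=max(len(labels), 1), directed=directed, node_labels=labels)


def write_edge_list(net: Network, path) -> None:
    """Write one link per line, internal ids, whitespace-delimited."""
    with open(path, "w") as fh:
        fh.write(f"# nodes={net.n_nodes} directed={net.directed}\n")
        for i, j in sorted(net.links):
            fh.write(f"{i} {j}\n")


def giant_component(net: Network) -> Network:
    """Induced subgraph on the largest (weakly) connected component.

    Node ids are relabeled to contiguous 0-based ids preserving original
    order. Ties between equal-size components are broken by the smallest
    contained original id.
    """
    g = net.to_networkx()
    comps = nx.weakly_connected_components(g) if net.directed else nx.connected_components(g)
    best = max(comps, key=lambda c: (len(c), -min(c)))
    keep = sorted(best)
    remap = {old: new for new, old in enumerate(keep)}
    links = frozenset((remap[i], remap[j]) for i, j in net.links if i in best and j in best)
    labels = None
    if net.node_labels is not None:
        labels = {lab: remap[old] for lab, old in net.node_labels.items() if old in best}
    return Network(n_nodes=len(keep), links=links, directed=net.directed, node_labels=labels)


def degrees(net: Network) -> np.ndarray:
    """Degree vector of length N; total (in+out) degree when directed."""
    deg = np.zeros(net.n_nodes, dtype=np.int64)
    for i, j in net.links:
        deg[i] += 1
        deg[j] += 1
    return deg
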
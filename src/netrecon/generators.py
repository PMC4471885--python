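"""Seeded Barabási–Albert and Watts–Strogatz network generators.

These are the two artificial topologies used throughout the experiments:
scale-free networks (BA, heterogeneous degrees) and small-world ring
networks (WS, homogeneous degrees). Both are parameterised by the target
mean degree ``<k>`` rather than the models' native ``m``/``k`` so that
the same ``<k>`` can be requested from either model.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from netrecon.graph import Network, from_edges


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one artificial network draw."""

    model: str  # "ba" or "ws"
    n_nodes: int
    mean_degree: int
    rewiring_prob: float = 0.1  # WS only
    seed: int = 0

    def realise(self, seed: int | None = None) -> Network:
        s = self.seed if seed is None else seed
        if self.model == "ba":
            return generate_ba(self.n_nodes, self.mean_degree, s)
        if self.model == "ws":
            return generate_ws(self.n_nodes, self.mean_degree, self.rewiring_prob, s)
        raise ValueError(f"unknown model {self.model!r}; expected 'ba' or 'ws'")


def _check_params(n_nodes: int, mean_degree: int) -> int:
    if mean_degree < 2 or mean_degree % 2 != 0:
        raise ValueError(f"mean_degree must be a positive even integer, got {mean_degree}")
    if n_nodes <= mean_degree:
        raise ValueError(f"need n_nodes > mean_degree ({n_nodes} <= {mean_degree})")
    return mean_degree // 2


def generate_ba(n_nodes: int, mean_degree: int, seed: int) -> Network:
    """Barabási–Albert preferential-attachment network.

    Each of the ``N - m`` added nodes attaches ``m = mean_degree/2`` links
    to existing nodes with probability proportional to degree, growing
    from a complete graph on the first ``m`` nodes, so
    ``E = C(m,2) + (N-m)*m`` and ``<k> ~ mean_degree``.
    """
    m = _check_params(n_nodes, mean_degree)
    # m=1: a one-node clique has degree 0 everywhere, which leaves
    # preferential attachment undefined; bootstrap from a single edge
    # (node 1's own attachment), keeping E = C(m,2) + (N-m)*m = N-1.
    initial = nx.complete_graph(m) if m >= 2 else nx.path_graph(2)
    g = nx.barabasi_albert_graph(n_nodes, m, seed=seed, initial_graph=initial)
    return from_edges(g.edges(), n_nodes=n_nodes, directed=False)


def generate_ws(n_nodes: int, mean_degree: int, rewiring_prob: float, seed: int) -> Network:
    """Watts–Strogatz small-world network.

    Ring lattice with ``mean_degree/2`` neighbors on each side; each
    lattice link is rewired with probability ``rewiring_prob`` to a
    uniform non-duplicate, non-self target. Rewiring preserves the link
    count, so ``E = N * mean_degree / 2`` exactly.
    """
    _check_params(n_nodes, mean_degree)
    if not 0.0 <= rewiring_prob <= 1.0:
        raise ValueError(f"rewiring_prob must be in [0,1], got {rewiring_prob}")
    g = nx.watts_strogatz_graph(n_nodes, mean_degree, rewiring_prob, seed=seed)
    return from_edges(g.edges(), n_nodes=n_nodes, directed=False)
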
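"""Discrete-time SIR spreading simulator with time-stamped receptions.

Each news item starts at a single source node (time 0). The dynamics use
a parallel update: at every step, each currently infected node attempts
to infect each of its susceptible (out-)neighbors independently with
probability ``mu``, then recovers. A node infected by several neighbors
in the same step records that step once. The cascade stops when nobody
is infected.

The full spreading experiment draws one Bernoulli(``f``) submission per
node; each submitted news propagates as an independent cascade. The
output is the reception matrix ``R`` (nodes x news, binary) and the time
matrix ``T`` (reception step, -1 where the news never arrived) — the
sole inputs to reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import io as sio
from scipy import sparse

from netrecon.graph import Network

logger = logging.getLogger(__name__)

NOT_RECEIVED = -1


@dataclass(frozen=True)
class SimulationParams:
    """Spreading parameters: submission probability f, infection rate mu."""

    submission_prob: float  # f
    infection_rate: float  # mu
    seed: int = 0

    def __post_init__(self):
        for name in ("submission_prob", "infection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class SpreadingRecord:
    """Observed spreading results: who received which news, and when.

    Attributes
    ----------
    reception : (N, M) uint8 array
        ``R[i, a] = 1`` iff node i received news a.
    times : (N, M) int array
        Step at which i received a; ``-1`` where ``R[i, a] = 0``; the
        source of each news has time 0.
    sources : (M,) int array
        Originating node of each news, in ascending node-id order.
    """

    reception: np.ndarray
    times: np.ndarray
    sources: np.ndarray

    def __post_init__(self):
        if self.reception.shape != self.times.shape:
            raise ValueError("reception and times must have the same shape")
        if self.reception.shape[1] != len(self.sources):
            raise ValueError("one source per news column required")

    @property
    def n_nodes(self) -> int:
        return self.reception.shape[0]

    @property
    def n_news(self) -> int:
        return self.reception.shape[1]

    @property
    def news_audience(self) -> np.ndarray:
        """d_a: number of nodes that received each news (column sums of R)."""
        return self.reception.sum(axis=0)

    @property
    def node_news_count(self) -> np.ndarray:
        """k_i: number of news received by each node (row sums of R)."""
        return self.reception.sum(axis=1)

    def save(self, out_dir) -> None:
        """Write R (Matrix Market pattern), times (TSV) and sources (TSV)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(out / "reception.mtx", sparse.coo_matrix(self.reception), field="pattern")
        rows, cols = np.nonzero(self.reception)
        with open(out / "times.tsv", "w") as fh:
            fh.write("node_id\tnews_id\ttime\n")
            for i, a in zip(rows, cols):
                fh.write(f"{i}\t{a}\t{self.times[i, a]}\n")
        np.savetxt(out / "sources.tsv", self.sources, fmt="%d")

    @classmethod
    def load(cls, in_dir) -> "SpreadingRecord":
        src = Path(in_dir)
        r = np.asarray(sio.mmread(src / "reception.mtx").todense()).astype(np.uint8)
        t = np.full(r.shape, NOT_RECEIVED, dtype=np.int64)
        data = np.loadtxt(src / "times.tsv", skiprows=1, dtype=np.int64, ndmin=2)
        if data.size:
            t[data[:, 0], data[:, 1]] = data[:, 2]
        sources = np.atleast_1d(np.loadtxt(src / "sources.tsv", dtype=np.int64))
        return cls(reception=r, times=t, sources=sources)


def run_cascade(net: Network, source: int, infection_rate: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Run one SIR cascade; return (reception column, time column).

    The source is infected at time 0; infection follows out-links when
    the network is directed. Times are ``-1`` for nodes never reached.
    """
    n = net.n_nodes
    if not 0 <= source < n:
        raise ValueError(f"source {source} out of range [0,{n})")
    adj = net.adjacency()
    received = np.zeros(n, dtype=np.uint8)
    times = np.full(n, NOT_RECEIVED, dtype=np.int64)
    received[source] = 1
    times[source] = 0
    frontier = np.array([source])
    t = 0
    mu = infection_rate
    while frontier.size and mu > 0:
        # all attempts from this step's infected nodes, then they recover
        targets = np.concatenate([adj.indices[adj.indptr[v]:adj.indptr[v + 1]] for v in frontier])
        if targets.size:
            hits = targets[rng.random(targets.size) < mu]
            new = np.unique(hits[received[hits] == 0])
        else:
            new = np.array([], dtype=np.int64)
        t += 1
        received[new] = 1
        times[new] = t
        frontier = new
    return received, times


def check_causality(net: Network, record: SpreadingRecord) -> None:
    """Validate a spreading record against the network's causal structure.

    For every news: the source has time 0; every other recipient at step
    t > 0 has at least one network (in-)neighbor that received the same
    news at step t - 1; nobody unreachable from the source received it.
    Raises ``ValueError`` on the first violation.
    """
    adj_in = net.adjacency().T.tocsr()  # row i: nodes that can infect i
    for a in range(record.n_news):
        src = record.sources[a]
        r, t = record.reception[:, a], record.times[:, a]
        if r[src] != 1 or t[src] != 0:
            raise ValueError(f"news {a}: source {src} lacks R=1, T=0")
        if np.any((r == 1) != (t >= 0)):
            raise ValueError(f"news {a}: times defined iff received violated")
        for i in np.flatnonzero(r):
            if i == src:
                continue
            nbrs = adj_in.indices[adj_in.indptr[i]:adj_in.indptr[i + 1]]
            if not np.any((r[nbrs] == 1) & (t[nbrs] == t[i] - 1)):
                raise ValueError(
                    f"news {a}: node {i} (t={t[i]}) has no neighbor infected at t-1")


def run_spreading(net: Network, params: SimulationParams) -> SpreadingRecord:
    """Simulate the full news-spreading experiment on a network.

    Every node submits one news with probability ``f``; each submitted
    news runs as an independent cascade. Cascades draw from independent
    substreams keyed by the submitting node's id, so the record is
    invariant to execution order and fully determined by the seed.
    """
    n = net.n_nodes
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(n + 1)
    submit_rng = np.random.default_rng(children[0])
    submitters = np.flatnonzero(submit_rng.random(n) < params.submission_prob)
    if submitters.size == 0:
        logger.warning("no news submitted (f=%g, N=%d); returning an empty record",
                       params.submission_prob, n)
        return SpreadingRecord(
            reception=np.zeros((n, 0), dtype=np.uint8),
            times=np.full((n, 0), NOT_RECEIVED, dtype=np.int64),
            sources=np.array([], dtype=np.int64),
        )
    r_cols, t_cols = [], []
    for node in submitters:
        rng = np.random.default_rng(children[node + 1])
        r, t = run_cascade(net, int(node), params.infection_rate, rng)
        r_cols.append(r)
        t_cols.append(t)
    return SpreadingRecord(
        reception=np.stack(r_cols, axis=1),
        times=np.stack(t_cols, axis=1),
        sources=submitters.astype(np.int64),
    )
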
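"""Node-pair similarity metrics computed from spreading records.

Classic metrics count the news two nodes received in common (CN) and
normalise that count in different ways — by the union of received news
(Jaccard), by the product of reception counts (LHN), by audience size
(RA), and so on. Each has a temporal variant in which every common-news
term is down-weighted by the inverse absolute difference of the two
reception times, ``w = 1/|T_ia - T_ja|``, with equal-time terms set to
zero: two nodes that received a news at the same step cannot have passed
it to each other, so the news carries no evidence of a direct link.

Naming: ``cn, jac, ra, lhn, cos, hdi, hpi, ssi, pa`` and their temporal
versions prefixed with ``t`` (``tpa`` has no common-news term and equals
``pa``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from netrecon.simulate import SpreadingRecord

_BASE_METRICS = ("cn", "jac", "ra", "lhn", "cos", "hdi", "hpi", "ssi", "pa")
METRICS = _BASE_METRICS + tuple("t" + m for m in _BASE_METRICS)


def _split(metric: str) -> tuple[str, bool]:
    name = metric.lower()
    if name not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if name in _BASE_METRICS:
        return name, False
    return name[1:], True


# ---------------------------------------------------------------------------
# per-pair definitions (reference implementations, also the public API
# for single pairs)
# ---------------------------------------------------------------------------

def pair_score(record: SpreadingRecord, metric: str, i: int, j: int) -> float:
    """Similarity of one node pair, straight from the metric's definition."""
    base, temporal = _split(metric)
    if i == j:
        raise ValueError("similarity is defined for distinct nodes only")
    R, T = record.reception, record.times
    k_i = int(R[i].sum())
    k_j = int(R[j].sum())
    if base == "pa":
        return float(k_i * k_j)
    common = np.flatnonzero((R[i] == 1) & (R[j] == 1))
    cn_count = len(common)
    if temporal:
        dt = np.abs(T[i, common] - T[j, common])
        weights = np.where(dt == 0, 0.0, 1.0 / np.maximum(dt, 1))
    else:
        weights = np.ones(cn_count)
    if base == "ra":
        d = record.news_audience[common]
        return float(np.sum(weights / d))
    num = float(weights.sum())
    if base == "cn":
        return num
    den = {
        "jac": k_i + k_j - cn_count,
        "lhn": k_i * k_j,
        "cos": np.sqrt(k_i * k_j),
        "hdi": max(k_i, k_j),
        "hpi": min(k_i, k_j),
        "ssi": (k_i + k_j) / 2.0,
    }[base]
    return num / den if den > 0 else 0.0


def cn(record: SpreadingRecord, i: int, j: int) -> float:
    """Common news count: overlap of the news received by i and j."""
    return pair_score(record, "cn", i, j)


def tcn(record: SpreadingRecord, i: int, j: int) -> float:
    """Temporal common news: sum of 1/|ΔT| over common news (0 on ties)."""
    return pair_score(record, "tcn", i, j)


def jac(record: SpreadingRecord, i: int, j: int) -> float:
    """Jaccard: common news over the union of received news."""
    return pair_score(record, "jac", i, j)


def ra(record: SpreadingRecord, i: int, j: int) -> float:
    """Resource allocation: each common news contributes 1/audience."""
    return pair_score(record, "ra", i, j)


def lhn(record: SpreadingRecord, i: int, j: int) -> float:
    """Leicht-Holme-Newman: common news over k_i * k_j."""
    return pair_score(record, "lhn", i, j)


def temporal_variant(base_metric: str, record: SpreadingRecord, i: int, j: int) -> float:
    """Temporal version of a base metric: numerator terms weighted by 1/|ΔT|."""
    base, temporal = _split(base_metric)
    if temporal:
        raise ValueError(f"{base_metric!r} is already temporal")
    return pair_score(record, "t" + base, i, j)


def extended_metric(name: str, record: SpreadingRecord, i: int, j: int) -> float:
    """One of the extended set: cos, hdi, hpi, ssi, pa (or temporal)."""
    base, _ = _split(name)
    if base not in ("cos", "hdi", "hpi", "ssi", "pa"):
        raise ValueError(f"{name!r} is not in the extended metric set")
    return pair_score(record, name, i, j)


# ---------------------------------------------------------------------------
# vectorized all-pairs computation
# ---------------------------------------------------------------------------

def _temporal_numerators(record: SpreadingRecord) -> tuple[np.ndarray, np.ndarray]:
    """(W, W_ra): summed temporal weights, plain and audience-normalised.

    W[i, j] = sum over common news of 1/|T_ia - T_ja| (0 on equal times);
    W_ra additionally divides each term by the news audience d_a.
    """
    n = record.n_nodes
    W = np.zeros((n, n))
    W_ra = np.zeros((n, n))
    d = record.news_audience
    for a in range(record.n_news):
        idx = np.flatnonzero(record.reception[:, a])
        if idx.size < 2:
            continue
        t = record.times[idx, a].astype(np.int64)
        dt = np.abs(t[:, None] - t[None, :])
        w = np.zeros_like(dt, dtype=float)
        nz = dt > 0
        w[nz] = 1.0 / dt[nz]
        W[np.ix_(idx, idx)] += w
        W_ra[np.ix_(idx, idx)] += w / d[a]
    return W, W_ra


def score_matrix(record: SpreadingRecord, metric: str) -> np.ndarray:
    """Dense N x N similarity matrix (diagonal zeroed, symmetric)."""
    base, temporal = _split(metric)
    R = record.reception.astype(np.float64)
    k = record.node_news_count.astype(np.float64)
    if base == "pa":
        S = np.outer(k, k)
        np.fill_diagonal(S, 0.0)
        return S
    CN = R @ R.T
    if temporal:
        W, W_ra = _temporal_numerators(record)
        num = W_ra if base == "ra" else W
    elif base == "ra":
        d = record.news_audience.astype(np.float64)
        num = R @ (R / np.maximum(d, 1)).T
    else:
        num = CN
    if base in ("cn", "ra"):
        S = num.copy()
    else:
        den = {
            "jac": lambda: k[:, None] + k[None, :] - CN,
            "lhn": lambda: np.outer(k, k),
            "cos": lambda: np.sqrt(np.outer(k, k)),
            "hdi": lambda: np.maximum(k[:, None], k[None, :]),
            "hpi": lambda: np.minimum(k[:, None], k[None, :]),
            "ssi": lambda: (k[:, None] + k[None, :]) / 2.0,
        }[base]()
        S = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    np.fill_diagonal(S, 0.0)
    return S


@dataclass(frozen=True)
class ScoreTable:
    """Similarity scores for every candidate node pair under one metric.

    Undirected tables hold the C(N,2) unordered pairs with ``i < j``;
    directed tables hold all N(N-1) ordered pairs. Scores of a symmetric
    metric are equal in both directions.
    """

    n_nodes: int
    pairs: np.ndarray  # (P, 2) int
    scores: np.ndarray  # (P,) float
    metric_name: str
    directed: bool = False

    def __post_init__(self):
        if len(self.pairs) != len(self.scores):
            raise ValueError("pairs and scores must align")

    @property
    def n_candidates(self) -> int:
        return len(self.pairs)

    def to_matrix(self) -> np.ndarray:
        """Dense N x N lookup matrix (symmetrised when undirected)."""
        m = np.zeros((self.n_nodes, self.n_nodes))
        m[self.pairs[:, 0], self.pairs[:, 1]] = self.scores
        if not self.directed:
            m[self.pairs[:, 1], self.pairs[:, 0]] = self.scores
        return m

    def to_tsv(self, path) -> None:
        """Write (i, j, score) sorted by descending score then (i, j)."""
        order = np.lexsort((self.pairs[:, 1], self.pairs[:, 0], -self.scores))
        with open(Path(path), "w") as fh:
            fh.write(f"# metric={self.metric_name} n_nodes={self.n_nodes} directed={self.directed}\n")
            for idx in order:
                i, j = self.pairs[idx]
                fh.write(f"{i}\t{j}\t{self.scores[idx]:.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "ScoreTable":
        meta = {}
        pairs, scores = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        key, _, val = tok.partition("=")
                        meta[key] = val
                    continue
                i, j, s = line.split()
                pairs.append((int(i), int(j)))
                scores.append(float(s))
        return cls(
            n_nodes=int(meta.get("n_nodes", 1 + max(max(p) for p in pairs))),
            pairs=np.array(pairs, dtype=np.int64),
            scores=np.array(scores),
            metric_name=meta.get("metric", "unknown"),
            directed=meta.get("directed", "False") == "True",
        )


def candidate_pairs(n_nodes: int, directed: bool) -> np.ndarray:
    """All candidate node pairs: i<j unordered, or all ordered i != j."""
    if directed:
        i, j = np.meshgrid(np.arange(n_nodes), np.arange(n_nodes), indexing="ij")
        mask = i != j
        return np.column_stack([i[mask], j[mask]])
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def score_all_pairs(record: SpreadingRecord, metric: str,
                    directed: bool = False) -> ScoreTable:
    """Score every candidate node pair via sparse/dense matrix products.

    Equivalent, pair for pair, to calling :func:`pair_score` in a loop.
    """
    S = score_matrix(record, metric)
    pairs = candidate_pairs(record.n_nodes, directed)
    return ScoreTable(
        n_nodes=record.n_nodes,
        pairs=pairs,
        scores=S[pairs[:, 0], pairs[:, 1]],
        metric_name=metric.lower(),
        directed=directed,
    )
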
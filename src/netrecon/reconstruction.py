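"""Estimator-style front end: spreading record in, inferred links out."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from netrecon.evaluate import ReconstructionResult, reconstruct_top_e
from netrecon.similarity import METRICS, ScoreTable, score_all_pairs
from netrecon.simulate import SpreadingRecord


class SimilarityReconstructor(BaseEstimator):
    """Infer a network's link set from an observed spreading record.

    ``fit`` consumes a :class:`SpreadingRecord` (the reception matrix R
    and time matrix T) and scores every candidate node pair with the
    chosen similarity metric; ``predict`` returns the top-``e_target``
    pairs as the reconstructed link set.

    Parameters
    ----------
    metric : str
        One of the registered similarity metrics (``"cn"``, ``"tcn"``,
        ``"jac"``, ``"tjac"``, ``"ra"``, ``"tra"``, ``"lhn"``, ``"tlhn"``,
        the extended set, or their temporal versions). Temporal metrics
        down-weight each common news by 1/|ΔT| of the reception times.
    directed : bool
        Whether candidate pairs are ordered.
    e_target : int or None
        Number of links to select; may instead be passed to ``predict``.
    random_state : int
        Seed for the uniform tie-break among pairs at the score cutoff.

    Attributes
    ----------
    score_table_ : ScoreTable
        Scores for every candidate pair, set by ``fit``.
    n_nodes_ : int
        Number of nodes in the fitted record.
    """

    def __init__(self, metric: str = "tra", directed: bool = False,
                 e_target: int | None = None, random_state: int = 0):
        self.metric = metric
        self.directed = directed
        self.e_target = e_target
        self.random_state = random_state

    def fit(self, record: SpreadingRecord, y=None) -> "SimilarityReconstructor":
        if self.metric.lower() not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not isinstance(record, SpreadingRecord):
            raise TypeError("fit expects a SpreadingRecord")
        self.score_table_: ScoreTable = score_all_pairs(record, self.metric, self.directed)
        self.n_nodes_: int = record.n_nodes
        return self

    def reconstruct(self, e_target: int | None = None) -> ReconstructionResult:
        """Select the top-E pairs (ties at the cutoff broken at random)."""
        if not hasattr(self, "score_table_"):
            raise RuntimeError("call fit before reconstruct")
        e = e_target if e_target is not None else self.e_target
        if e is None:
            raise ValueError("e_target not set")
        return reconstruct_top_e(self.score_table_, e, seed=self.random_state)

    def predict(self, e_target: int | None = None) -> np.ndarray:
        """The reconstructed link set as a (E, 2) integer array."""
        result = self.reconstruct(e_target)
        return np.array(sorted(result.selected_links), dtype=np.int64)
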
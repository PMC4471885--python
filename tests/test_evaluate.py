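import math

import networkx as nx
import numpy as np
import pytest

from netrecon.evaluate import (
    auc_exhaustive,
    auc_sampled,
    degree_correlation,
    evaluate_scores,
    p0_baseline,
    precision,
    reconstruct_top_e,
)
from netrecon.graph import Network, from_edges
from netrecon.similarity import ScoreTable, candidate_pairs, score_all_pairs
from tests.conftest import random_record


def table_from_scores(n_nodes, score_map, directed=False):
    pairs = candidate_pairs(n_nodes, directed)
    scores = np.array([score_map.get(tuple(p), 0.0) for p in pairs])
    return ScoreTable(n_nodes=n_nodes, pairs=pairs, scores=scores,
                      metric_name="synthetic", directed=directed)


class TestReconstructTopE:
    def test_no_ties_takes_highest(self):
        table = table_from_scores(3, {(0, 1): 3, (0, 2): 2, (1, 2): 1})
        res = reconstruct_top_e(table, 2, seed=0)
        assert res.selected_links == {(0, 1), (0, 2)}
        assert res.n_randomly_chosen == 0

    def test_all_tied_uniform_selection(self):
        # 3 equal scores, pick 2: each pair kept in ~2/3 of draws
        table = table_from_scores(3, {(0, 1): 1, (0, 2): 1, (1, 2): 1})
        counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        n_seeds = 3000
        for seed in range(n_seeds):
            for link in reconstruct_top_e(table, 2, seed=seed).selected_links:
                counts[link] += 1
        # multinomial: each count ~ Binomial(3000, 2/3)
        se = math.sqrt(n_seeds * (2 / 3) * (1 / 3))
        for c in counts.values():
            assert abs(c - n_seeds * 2 / 3) < 4 * se

    def test_full_selection(self):
        table = table_from_scores(3, {(0, 1): 3, (0, 2): 2, (1, 2): 1})
        res = reconstruct_top_e(table, 3, seed=0)
        assert res.selected_links == {(0, 1), (0, 2), (1, 2)}

    def test_e_exceeding_candidates_rejected(self):
        table = table_from_scores(3, {})
        with pytest.raises(ValueError):
            reconstruct_top_e(table, 4, seed=0)

    def test_strictly_above_cutoff_always_selected(self):
        rng = np.random.default_rng(0)
        scores = {tuple(p): float(rng.integers(0, 4))
                  for p in candidate_pairs(8, False)}
        table = table_from_scores(8, scores)
        res = reconstruct_top_e(table, 10, seed=5)
        assert len(res.selected_links) == 10
        for pair, s in scores.items():
            if s > res.cutoff_score:
                assert pair in res.selected_links
            elif s < res.cutoff_score:
                assert pair not in res.selected_links


class TestAuc:
    def test_formula_from_counts(self):
        # auc = (n1 + 0.5*n2)/n by construction of the sampler
        truth = Network(n_nodes=3, links=frozenset({(0, 1)}))
        table = table_from_scores(3, {(0, 1): 2, (0, 2): 1, (1, 2): 2})
        auc, n1, n2 = auc_sampled(table, truth, n=1000, seed=1)
        assert auc == (n1 + 0.5 * n2) / 1000

    def test_perfect_separation(self):
        truth = Network(n_nodes=4, links=frozenset({(0, 1), (2, 3)}))
        table = table_from_scores(4, {(0, 1): 5, (2, 3): 4})
        auc, _, _ = auc_sampled(table, truth, n=2000, seed=0)
        assert auc == 1.0
        assert auc_exhaustive(table, truth) == 1.0

    def test_all_equal_scores_half(self):
        truth = Network(n_nodes=4, links=frozenset({(0, 1)}))
        table = table_from_scores(4, {p: 1.0 for p in map(tuple, candidate_pairs(4, False))})
        assert auc_exhaustive(table, truth) == 0.5
        auc, n1, n2 = auc_sampled(table, truth, n=500, seed=0)
        assert (auc, n1, n2) == (0.5, 0, 500)

    def test_undefined_without_links(self):
        table = table_from_scores(3, {})
        with pytest.raises(ValueError):
            auc_sampled(table, Network(n_nodes=3, links=frozenset()), n=10)

    def test_sampled_concentrates_on_exhaustive(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            net, rec = random_record(rng, n_max=20)
            table = score_all_pairs(rec, "cn")
            exact = auc_exhaustive(table, net)
            n = 20_000
            auc, _, _ = auc_sampled(table, net, n=n, seed=int(rng.integers(2**31)))
            se = math.sqrt(max(exact * (1 - exact), 0.25 / 4) / n)
            assert abs(auc - exact) < 4 * max(se, 1e-3)

    def test_same_seed_reproducible(self, ws_pipeline):
        net, rec = ws_pipeline
        table = score_all_pairs(rec, "tjac")
        assert auc_sampled(table, net, n=5000, seed=3) == auc_sampled(table, net, n=5000, seed=3)


class TestPrecision:
    def test_partial_overlap(self):
        truth = from_edges([(0, 1), (1, 2), (2, 3), (3, 4)], n_nodes=5)
        table = table_from_scores(5, {(0, 1): 9, (1, 2): 8, (0, 2): 7, (0, 3): 6})
        res = reconstruct_top_e(table, 4, seed=0)
        assert precision(res, truth) == 0.5

    def test_perfect_reconstruction(self, triangle):
        table = table_from_scores(3, {(0, 1): 3, (0, 2): 2, (1, 2): 1})
        res = reconstruct_top_e(table, 3, seed=0)
        assert precision(res, triangle) == 1.0


class TestDegreeCorrelation:
    def test_identity_is_one(self, path4):
        table = table_from_scores(4, {l: 1.0 + i for i, l in enumerate(sorted(path4.links))})
        res = reconstruct_top_e(table, 3, seed=0)
        assert res.selected_links == path4.links
        assert degree_correlation(res, path4) == pytest.approx(1.0)

    def test_anti_ordered_degrees_negative(self):
        # truth: star center 0 over {0..3}; reconstruction: star center 3
        truth = from_edges([(0, 1), (0, 2), (0, 3)], n_nodes=4)
        table = table_from_scores(4, {(1, 3): 3, (2, 3): 2, (0, 3): 1})
        res = reconstruct_top_e(table, 3, seed=0)
        assert degree_correlation(res, truth) < 0

    def test_regular_truth_gives_nan_sentinel(self, triangle):
        table = table_from_scores(3, {(0, 1): 2, (0, 2): 1})
        res = reconstruct_top_e(table, 2, seed=0)
        assert math.isnan(degree_correlation(res, triangle))


class TestP0Baseline:
    @pytest.mark.parametrize("n,e,directed,expect", [
        (62, 159, False, 0.08),
        (54, 356, True, 0.12),
        (10, 45, False, 1.0),
    ])
    def test_printed_values(self, n, e, directed, expect):
        assert round(p0_baseline(n, e, directed), 2) == expect

    def test_random_reconstruction_attains_p0(self):
        # tie the top-E implementation to the baseline: all-zero scores
        # make selection uniformly random, so mean precision -> P0
        g = nx.gnm_random_graph(100, 300, seed=1)
        truth = from_edges(g.edges(), n_nodes=100)
        table = table_from_scores(100, {})
        precs = [precision(reconstruct_top_e(table, 300, seed=s), truth)
                 for s in range(100)]
        p0 = p0_baseline(100, 300)
        # hypergeometric sd of one draw's precision
        P = 100 * 99 // 2
        var_m = 300 * p0 * (1 - p0) * (P - 300) / (P - 1)
        se_mean = math.sqrt(var_m) / 300 / math.sqrt(100)
        assert abs(np.mean(precs) - p0) < 3 * se_mean


class TestRelabelingInvariance:
    def test_precision_and_degcorr_invariant_under_relabeling(self):
        rng = np.random.default_rng(11)
        net, rec = random_record(rng, n_max=15)
        table = score_all_pairs(rec, "ra")
        # pick an E that swallows the whole tie group at the cutoff, so the
        # selected set is deterministic and comparable across labelings
        vals = np.unique(table.scores)
        e_target = int(np.count_nonzero(table.scores >= vals[len(vals) // 2]))
        res = reconstruct_top_e(table, e_target, seed=4)
        perm = rng.permutation(net.n_nodes)
        relink = frozenset(tuple(sorted((perm[i], perm[j]))) for i, j in net.links)
        net2 = Network(n_nodes=net.n_nodes, links=relink)
        m = table.to_matrix()[np.ix_(np.argsort(perm), np.argsort(perm))]
        # rebuild a permuted table from the permuted score matrix
        pairs = candidate_pairs(net.n_nodes, False)
        table2 = ScoreTable(n_nodes=net.n_nodes, pairs=pairs,
                            scores=m[pairs[:, 0], pairs[:, 1]],
                            metric_name="ra")
        res2 = reconstruct_top_e(table2, e_target, seed=4)
        assert precision(res, net) == pytest.approx(precision(res2, net2))
        dc1, dc2 = degree_correlation(res, net), degree_correlation(res2, net2)
        assert (math.isnan(dc1) and math.isnan(dc2)) or dc1 == pytest.approx(dc2)


def test_evaluate_scores_composes_the_stages(ws_pipeline):
    net, rec = ws_pipeline
    report = evaluate_scores(score_all_pairs(rec, "tra"), net, n_auc=20_000, seed=2)
    assert 0.5 < report.auc <= 1.0
    assert report.auc == (report.n1 + 0.5 * report.n2) / report.auc_n
    assert 0 <= report.precision <= 1
    assert report.p0 == p0_baseline(net.n_nodes, net.n_links)
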
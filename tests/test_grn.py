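"""Attribution and network analysis: Integrated Gradients, score
aggregation, thresholding, degrees, communities and enrichment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from funprose import ModelConfig, build_model, one_hot_encode
from funprose.grn import (TFGeneScoreTable, _bh, degree_statistics,
                          edge_ranking_auroc, integrated_gradients,
                          modularity_clusters, term_enrichment,
                          tf_filter_match, threshold_network)


@pytest.fixture(scope="module")
def toy_model():
    cfg = ModelConfig.small(promoter_length=60, pool1=4, conv2_len=5,
                            pool2=3, conv1_kernels=4, conv2_kernels=4,
                            tf_hidden=8, head_sizes=(8, 4, 2))
    return build_model(cfg, n_tfs=6, seed=9)


@pytest.fixture(scope="module")
def toy_promoter(toy_model):
    rng = np.random.default_rng(2)
    bases = np.array(list("ACGT"))
    return one_hot_encode("".join(rng.choice(bases, size=60)))


class TestIntegratedGradients:
    def test_linear_model_closed_form_any_steps(self):
        """On a model linear in the TF input, IG with a zero baseline is
        exactly w * x for every step count."""

        class LinearTF:
            """Minimal stand-in exposing the model's attribution surface."""
            def __init__(self, w):
                self.w = np.asarray(w, dtype=np.float32)
                self.config = ModelConfig.small(promoter_length=60, pool1=4,
                                                conv2_len=5, pool2=3)
                self.tf_branch = object()

            def conv_forward(self, xcol, train):
                return np.zeros((xcol.shape[0], 1), dtype=np.float32)

            def tf_input_gradient(self, flat, tf):
                return np.tile(self.w, (tf.shape[0], 1))

        w = np.array([0.5, -2.0, 0.0, 3.5])
        model = LinearTF(w)
        x = np.array([1.0, 2.0, -1.0, 0.5], dtype=np.float32)
        promoter = np.zeros((5, 60), dtype=np.uint8)
        promoter[0] = 1
        for steps in (1, 3, 20):
            ig = integrated_gradients(model, promoter, x, steps=steps)
            assert np.allclose(ig, w * x, atol=1e-6)

    def test_input_equal_baseline_gives_zero(self, toy_model, toy_promoter):
        x = np.zeros(6, dtype=np.float32)
        ig = integrated_gradients(toy_model, toy_promoter, x, steps=20)
        assert np.allclose(ig, 0.0)

    def test_completeness_on_nonlinear_model(self, toy_model, toy_promoter):
        """Riemann-sum convergence: at 2000 steps the attributions sum to
        f(x) - f(0) within 1e-3; the 20-step result is within 10%."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=6).astype(np.float32)
        xcol = toy_model.promoter_to_col(toy_promoter,
                                         toy_model.config.conv1_len)[None]
        flat = toy_model.conv_forward(xcol, train=False)
        f_x = toy_model.forward_from_flat(flat, x[None])[0]
        f_0 = toy_model.forward_from_flat(flat, np.zeros((1, 6),
                                                         dtype=np.float32))[0]
        ig_fine = integrated_gradients(toy_model, toy_promoter, x, steps=2000)
        assert abs(ig_fine.sum() - (f_x - f_0)) < 1e-3
        ig_20 = integrated_gradients(toy_model, toy_promoter, x, steps=20)
        assert np.allclose(ig_20.sum(), ig_fine.sum(),
                           rtol=0.10, atol=1e-4)


class TestAggregation:
    def test_single_sample_equals_that_vector(self, toy_model):
        # one test condition per gene -> the table column is that IG vector
        from funprose.containers import ModelDataset
        from funprose.grn import compute_tf_gene_scores
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        genes = [f"G{i}" for i in range(3)]
        promoters = {g: "".join(rng.choice(bases, size=60)) for g in genes}
        z = pd.DataFrame(rng.normal(size=(3, 4)), index=genes,
                         columns=list("abcd"))
        z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1, ddof=0), axis=0)
        tf = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"),
                          index=[f"TF{i}" for i in range(6)])
        ds = ModelDataset(zscores=z, promoters=promoters, tf_expression=tf)
        pairs = np.array([[0, 1], [1, 2], [2, 0]])
        table = compute_tf_gene_scores(toy_model, ds, pairs, steps=10)
        for (g, c) in pairs:
            direct = integrated_gradients(
                toy_model, one_hot_encode(promoters[genes[g]]),
                tf.to_numpy()[:, c], steps=10)
            assert np.allclose(table.scores[genes[g]].to_numpy(),
                               np.abs(direct), atol=1e-5)
        assert (table.n_samples == 1).all()

    def test_signed_aggregate_cancels_opposite_attributions(self):
        # two samples with IG +a and -a average to zero under signed mode
        a = np.array([1.0, -2.0, 0.5])
        signed = np.mean([a, -a], axis=0)
        assert np.allclose(signed, 0.0)
        absolute = np.mean([np.abs(a), np.abs(-a)], axis=0)
        assert np.allclose(absolute, np.abs(a))


class TestThresholdNetwork:
    def _table(self, scores):
        scores = pd.DataFrame(scores)
        scores.index = [f"TF{i}" for i in range(scores.shape[0])]
        scores.columns = [f"G{i}" for i in range(scores.shape[1])]
        return TFGeneScoreTable(scores=scores,
                                n_samples=pd.Series(1, index=scores.columns))

    def test_all_equal_scores_give_empty_network(self):
        with pytest.warns(UserWarning, match="equal"):
            g = threshold_network(self._table(np.ones((3, 4))))
        assert g.number_of_edges() == 0

    def test_single_outlier_is_the_only_edge(self, rng):
        scores = rng.normal(0, 0.01, size=(4, 50))
        scores[2, 7] = 5.0
        g = threshold_network(self._table(scores), k_sd=3)
        assert list(g.edges) == [("TF2", "G7")]

    def test_toy_table_matches_enumeration(self, rng):
        scores = rng.normal(size=(4, 5))
        table = self._table(scores)
        g = threshold_network(table, k_sd=1.0)
        a = np.abs(scores)
        thr = a.mean() + a.std()
        expected = {(f"TF{t}", f"G{j}")
                    for t in range(4) for j in range(5) if a[t, j] > thr}
        assert set(g.edges) == expected

    def test_permutation_equivariance(self, rng):
        scores = rng.normal(size=(5, 8))
        g1 = threshold_network(self._table(scores), k_sd=1.0)
        perm_t = rng.permutation(5)
        perm_g = rng.permutation(8)
        table2 = self._table(scores[np.ix_(perm_t, perm_g)])
        # relabel back to original names
        mapping = {f"TF{i}": f"TF{perm_t[i]}" for i in range(5)}
        mapping.update({f"G{j}": f"G{perm_g[j]}" for j in range(8)})
        g2 = nx.relabel_nodes(threshold_network(table2, k_sd=1.0), mapping)
        assert set(g1.edges) == set(g2.edges)


class TestDegreeStatistics:
    def test_star_graph_hub_coverage(self):
        g = nx.DiGraph()
        g.add_edges_from(("TF0", f"G{i}") for i in range(5))
        stats = degree_statistics(g, top_n=1)
        assert stats["hub_coverage"] == 1.0
        assert stats["n_edges"] == 5

    def test_cumulative_histograms_non_increasing(self, rng):
        g = nx.DiGraph()
        for t in range(4):
            for j in rng.choice(30, size=rng.integers(1, 20), replace=False):
                g.add_edge(f"TF{t}", f"G{j}")
        stats = degree_statistics(g)
        for key in ("out_degree_cumulative", "in_degree_cumulative"):
            counts = [c for _, c in stats[key]]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_toy_network_hand_count(self):
        g = nx.DiGraph()
        g.add_edges_from([("A", "g1"), ("A", "g2"), ("A", "g3"),
                          ("B", "g1"), ("C", "g4")])
        stats = degree_statistics(g, top_n=1)
        assert stats["hub_coverage"] == pytest.approx(3 / 5)
        assert stats["out_degree_cumulative"][0] == (1, 3)  # all 3 TFs >= 1
        assert stats["out_degree_cumulative"][2] == (3, 1)  # only A >= 3
        # in-degrees: g1 has 2, rest 1
        assert stats["in_degree_cumulative"][1] == (2, 1)

    def test_empty_network(self):
        stats = degree_statistics(nx.DiGraph())
        assert stats["n_edges"] == 0 and stats["hub_coverage"] == 0.0


class TestModularity:
    def test_disconnected_bicliques_split_into_two_communities(self):
        g = nx.DiGraph()
        for t in range(2):
            for j in range(3):
                g.add_edge(f"A{t}", f"ga{j}")
                g.add_edge(f"B{t}", f"gb{j}")
        membership, q = modularity_clusters(g, seed=1)
        a_comms = {membership[n] for n in membership if n.startswith(("A", "ga"))}
        b_comms = {membership[n] for n in membership if n.startswith(("B", "gb"))}
        assert len(a_comms) == 1 and len(b_comms) == 1
        assert a_comms != b_comms
        assert q > 0  # better than the trivial one-community partition

    def test_matches_exhaustive_partition_search_on_8_nodes(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5),
                          (2, 3), (6, 7), (5, 6)])
        membership, q = modularity_clusters(g, seed=0)

        def partitions(nodes):
            if not nodes:
                yield []
                return
            first, rest = nodes[0], nodes[1:]
            for smaller in partitions(rest):
                for i in range(len(smaller)):
                    yield smaller[:i] + [[first] + smaller[i]] + smaller[i+1:]
                yield [[first]] + smaller

        best = max(nx.community.modularity(g, [set(b) for b in p])
                   for p in partitions(list(g.nodes)))
        assert q == pytest.approx(best, abs=1e-9)

    def test_empty_network(self):
        membership, q = modularity_clusters(nx.DiGraph())
        assert membership == {} and q == 0.0


class TestHypergeometricMatching:
    def test_closed_form_example(self):
        # population 10, TF targets 5, activated 4, overlap 4:
        # p = C(4,4) C(6,1) / C(10,5) = 6 / 252
        g = nx.DiGraph()
        genes = [f"G{i}" for i in range(10)]
        for gene in genes[:5]:
            g.add_edge("TF0", gene)
        # feature map: one kernel; genes 0..3 strongly activated
        maps = np.zeros((1, 10, 4))
        maps[0, :4, 0] = 10.0
        df = tf_filter_match(g, maps, genes, min_targets=5, act_sd=1.0)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["overlap"] == 4 and row["n_activated"] == 4
        expected = 6 / comb(10, 5, exact=True)
        assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        g = nx.DiGraph()
        genes = [f"G{i}" for i in range(8)]
        for gene in genes[:4]:
            g.add_edge("TF0", gene)
        maps = np.zeros((1, 8, 3))
        maps[0, 5:, 0] = 10.0  # activated genes outside the targets
        df = tf_filter_match(g, maps, genes, min_targets=4, act_sd=1.0)
        assert df.iloc[0]["overlap"] == 0
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_tfs_below_min_targets_skipped(self):
        g = nx.DiGraph()
        g.add_edge("TF0", "G0")
        df = tf_filter_match(g, np.zeros((1, 2, 3)), ["G0", "G1"],
                             min_targets=20)
        assert df.empty


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = _bh(np.array([0.01, 0.02, 0.9]))
        assert np.allclose(q, [0.03, 0.03, 0.9], atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=30)
        q = _bh(p)
        assert np.all(q >= p - 1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestTermEnrichment:
    def test_exact_community_term_match_is_most_significant(self):
        universe = {f"g{i}" for i in range(20)}
        communities = {f"g{i}": (0 if i < 5 else 1) for i in range(20)}
        terms = {"rare": {f"g{i}" for i in range(5)},
                 "everything": set(universe)}
        df = term_enrichment(communities, terms, universe)
        rare0 = df[(df.community == 0) & (df.term == "rare")].iloc[0]
        assert rare0["p"] == df["p"].min()
        every = df[df.term == "everything"]
        assert np.allclose(every["p"], 1.0)

    def test_matches_closed_form_table(self):
        universe = {f"g{i}" for i in range(8)}
        communities = {f"g{i}": (0 if i < 4 else 1) for i in range(8)}
        terms = {"t1": {"g0", "g1", "g5"}}
        df = term_enrichment(communities, terms, universe)
        # community 0 (size 4), term size 3, overlap 2, population 8:
        # p = P(X >= 2) = [C(3,2)C(5,2) + C(3,3)C(5,1)] / C(8,4)
        expected = (comb(3, 2) * comb(5, 2) + comb(3, 3) * comb(5, 1)) \
            / comb(8, 4, exact=True)
        row = df[(df.community == 0)].iloc[0]
        assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_term_file_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment({"g1": 0}, {"t": {"x", "y"}}, {"g1"})


def test_edge_ranking_auroc_perfect_separation():
    scores = pd.DataFrame([[5.0, 0.1], [0.2, 4.0]],
                          index=["TF0", "TF1"], columns=["G0", "G1"])
    table = TFGeneScoreTable(scores=scores,
                             n_samples=pd.Series(1, index=scores.columns))
    assert edge_ranking_auroc(table, {("TF0", "G0"), ("TF1", "G1")}) == 1.0
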
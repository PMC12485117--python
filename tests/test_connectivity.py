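"""Functional connectivity: oracles for correlation, edges, communities,
deflation-ratio statistics, clustering coefficient, and distribution
distances."""

import networkx as nx
import numpy as np
import pytest

from odoresp import connectivity as con
from odoresp import preprocess as pre
from odoresp import synthgen as sg


class TestBuildFC:
    def test_duplicated_node_r_one(self, rng):
        x = rng.normal(size=(1, 50))
        traces = np.vstack([x, x])
        fc = con.build_fc(traces)
        assert fc.corr[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_pearson_loop(self, rng):
        traces = rng.normal(size=(6, 40))
        fc = con.build_fc(traces)
        for i in range(6):
            for j in range(6):
                xi = traces[i] - traces[i].mean()
                xj = traces[j] - traces[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert fc.corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_node_invalid(self, rng):
        traces = np.vstack([np.full(30, 2.0), rng.normal(size=(2, 30))])
        fc = con.build_fc(traces)
        assert not fc.valid[0]
        assert np.isnan(fc.corr[0, 1])
        assert fc.corr[0, 0] == 1.0  # diagonal convention

    def test_top_fraction_edge_count_uses_ceiling(self, rng):
        traces = rng.normal(size=(4, 60))
        fc = con.build_fc(traces)
        g = con.fc_graph(fc, 0.30)
        # 4 nodes -> 6 pairs; ceil(0.3 * 6) = 2 edges
        assert g.number_of_edges() == 2
        # and they are the 2 largest correlations (sort oracle)
        iu, ju = np.triu_indices(4, k=1)
        top = sorted(fc.corr[iu, ju])[-2:]
        kept = sorted(d["weight"] for _, _, d in g.edges(data=True))
        np.testing.assert_allclose(kept, top)

    def test_edge_rule_all_keeps_every_pair(self, rng):
        fc = con.build_fc(rng.normal(size=(5, 30)))
        assert con.fc_graph(fc, "all").number_of_edges() == 10


class TestCommunities:
    def _two_clique_graph(self):
        g = nx.Graph()
        for base in (0, 4):
            for i in range(base, base + 4):
                for j in range(i + 1, base + 4):
                    g.add_edge(i, j, weight=1.0)
        return g

    def test_two_disconnected_cliques_both_methods(self):
        g = self._two_clique_graph()
        for method in ("louvain", "greedy"):
            part = con.detect_communities(g, method, seed=0)
            groups = {}
            for node, c in part.assignment.items():
                groups.setdefault(c, set()).add(node)
            assert sorted(map(sorted, groups.values())) == [[0, 1, 2, 3], [4, 5, 6, 7]]
        a = con.detect_communities(g, "louvain", seed=0)
        b = con.detect_communities(g, "greedy")
        assert con.compare_partitions(a, b) == pytest.approx(1.0)

    def test_complete_uniform_graph_low_modularity(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = con.detect_communities(g, "louvain", seed=1)
        assert part.modularity <= 0.05

    def test_planted_two_block_fc_recovered(self, rng):
        # planted-partition simulation: two latent-driven blocks, detected
        # on the full weighted graph (the top-fraction rule can isolate an
        # unlucky node and is tested separately)
        latent = rng.normal(size=(2, 400))
        traces = np.empty((20, 400))
        for i in range(20):
            traces[i] = latent[i // 10] + 0.3 * rng.normal(size=400)
        fc = con.build_fc(traces)
        part = con.detect_communities(con.fc_graph(fc, "all"), seed=0)
        labels = part.labels_for(fc.node_ids)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, [0] * 10 + [1] * 10) == pytest.approx(1.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            con.detect_communities(nx.Graph(), "louvain")


class TestCommunityRatio:
    def test_all_weight_inside_target(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=2.0)
        part = con.CommunityPartition({"a": 0, "b": 0}, "louvain", 0.0)
        assert con.community_ratio(g, part, {"a"}) == pytest.approx(1.0)

    def test_complete_graph_combinatorial_oracle(self):
        n, k = 8, 3
        g = nx.complete_graph(n)
        nx.set_edge_attributes(g, 1.0, "weight")
        assignment = {i: (0 if i < k else 1 + i) for i in range(n)}
        part = con.CommunityPartition(assignment, "manual", 0.0)
        from math import comb

        ratio = con.community_ratio(g, part, {0, 1, 2})
        assert ratio == pytest.approx(comb(k, 2) / comb(n, 2))

    def test_target_without_internal_edges(self):
        g = nx.star_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = con.CommunityPartition({0: 0, 1: 1, 2: 1, 3: 1, 4: 1}, "manual", 0.0)
        assert con.community_ratio(g, part, {1, 2}) == 0.0

    def test_no_olfactory_nodes_rejected(self):
        g = nx.complete_graph(3)
        part = con.CommunityPartition({0: 0, 1: 0, 2: 0}, "manual", 0.0)
        with pytest.raises(ValueError):
            con.community_ratio(g, part, set())


class TestNodeDegrees:
    def test_triangle_and_star(self):
        tri = nx.complete_graph(3)
        nx.set_edge_attributes(tri, 0.5, "weight")
        deg, avg, _ = con.node_degrees(tri)
        assert all(d == pytest.approx(1.0) for d in deg.values())
        star = nx.star_graph(5)
        nx.set_edge_attributes(star, 1.0, "weight")
        deg, avg, dist = con.node_degrees(star)
        assert deg[0] == 5.0 and deg[1] == 1.0
        assert avg == pytest.approx(10 / 6)

    def test_matches_adjacency_row_sum(self, rng):
        w = rng.uniform(-1, 1, size=(7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = nx.from_numpy_array(w)
        deg, _, _ = con.node_degrees(g)
        for i in range(7):
            assert deg[i] == pytest.approx(w[i].sum(), abs=1e-12)


class TestDeflationRatio:
    def test_constant_matrix_zero(self):
        m = np.full((4, 4), 0.7)
        np.testing.assert_allclose(con.deflation_ratio(m), 0.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        m = rng.uniform(0.1, 1.0, size=(5, 5))
        m = (m + m.T) / 2
        np.testing.assert_allclose(
            con.deflation_ratio(m), con.deflation_ratio(3.7 * m), atol=1e-12
        )

    def test_direct_formula_3x3(self):
        m = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        mbar = np.mean([0.2, 0.4, 0.2, 0.6, 0.4, 0.6])
        np.testing.assert_allclose(con.deflation_ratio(m), (m - mbar) / mbar, atol=1e-14)

    def test_zero_mean_undefined(self):
        m = np.array([[1.0, 0.5], [-0.5, 1.0]])
        m = (m + m.T) / 2  # off-diagonal mean 0
        with pytest.raises(ValueError):
            con.deflation_ratio(m)


def _fc_from(corr, ids=None):
    corr = np.asarray(corr, dtype=float)
    return con.FCMatrix(corr=corr, node_ids=np.asarray(ids if ids is not None
                                                       else np.arange(len(corr))))


class TestDifferenceMatrix:
    def test_identical_channels_zero(self, rng):
        m = rng.uniform(0.1, 0.9, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        d = con.difference_matrix(_fc_from(m), _fc_from(m.copy()), seed=0)
        np.testing.assert_allclose(d.delta, 0.0, atol=1e-12)

    def test_positive_rescaling_invariance(self, rng):
        m1 = rng.uniform(0.1, 0.9, size=(6, 6)); m1 = (m1 + m1.T) / 2
        m2 = rng.uniform(0.1, 0.9, size=(6, 6)); m2 = (m2 + m2.T) / 2
        np.fill_diagonal(m1, 1.0); np.fill_diagonal(m2, 1.0)
        base = con.difference_matrix(_fc_from(m1), _fc_from(m2), seed=0)
        scaled = con.difference_matrix(_fc_from(2.5 * m1), _fc_from(0.3 * m2), seed=0)
        np.testing.assert_allclose(base.delta, scaled.delta, atol=1e-12)

    def test_random_pair_matches_formula_oracle(self, rng):
        m_n = rng.uniform(0.05, 0.9, size=(5, 5)); m_n = (m_n + m_n.T) / 2
        m_c = rng.uniform(0.05, 0.9, size=(5, 5)); m_c = (m_c + m_c.T) / 2
        np.fill_diagonal(m_n, 1.0); np.fill_diagonal(m_c, 1.0)
        off = ~np.eye(5, dtype=bool)
        expected = (m_n - m_n[off].mean()) / m_n[off].mean() - (
            m_c - m_c[off].mean()
        ) / m_c[off].mean()
        d = con.difference_matrix(_fc_from(m_n), _fc_from(m_c), seed=0)
        np.testing.assert_allclose(d.delta, expected, atol=1e-12)

    def test_node_mismatch_rejected(self, rng):
        m = np.eye(3)
        with pytest.raises(ValueError):
            con.difference_matrix(_fc_from(m, [0, 1, 2]), _fc_from(m, [0, 1, 9]))


class TestComplementationMetric:
    def _diff(self, delta, labels):
        return con.DiffMatrix(delta=np.asarray(delta, float),
                              cluster_labels=np.asarray(labels),
                              node_ids=np.arange(len(labels)))

    def test_positive_only_within(self):
        delta = np.array([[0, 0.4, -1, -1], [0.4, 0, -1, -1],
                          [-1, -1, 0, 0.2], [-1, -1, 0.2, 0]])
        d = self._diff(delta, [0, 0, 1, 1])
        assert con.complementation_metric(d) == pytest.approx(0.3)

    def test_balanced_sign_structure_near_zero(self):
        delta = np.array([[0, 0.5, 0.5, -1], [0.5, 0, -1, 0.5],
                          [0.5, -1, 0, 0.5], [-1, 0.5, 0.5, 0]])
        d = self._diff(delta, [0, 0, 1, 1])
        assert con.complementation_metric(d) == pytest.approx(0.0)

    def test_matches_mask_and_mean_loop_oracle(self, rng):
        n = 10
        delta = rng.normal(size=(n, n)); delta = (delta + delta.T) / 2
        labels = rng.integers(0, 3, size=n)
        within, between = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if delta[i, j] > 0:
                    (within if labels[i] == labels[j] else between).append(delta[i, j])
        expected = (np.mean(within) if within else 0.0) - (
            np.mean(between) if between else 0.0
        )
        assert con.complementation_metric(self._diff(delta, labels)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError):
            con.complementation_metric(self._diff(np.zeros((3, 3)), [0, 0, 0]))


class TestClusteringCoefficient:
    def test_triangle_and_star(self):
        _, avg = con.clustering_coefficient(nx.complete_graph(3))
        assert avg == pytest.approx(1.0)
        _, avg = con.clustering_coefficient(nx.star_graph(5))
        assert avg == 0.0

    def test_matches_brute_force_triangles(self, rng):
        g = nx.erdos_renyi_graph(15, 0.4, seed=5)
        per_node, avg = con.clustering_coefficient(g)
        for v in g.nodes:
            nbrs = list(g.neighbors(v))
            k = len(nbrs)
            e = sum(
                1
                for a in range(k)
                for b in range(a + 1, k)
                if g.has_edge(nbrs[a], nbrs[b])
            )
            expected = 2 * e / (k * (k - 1)) if k >= 2 else 0.0
            assert per_node[v] == pytest.approx(expected, abs=1e-12)
        assert avg == pytest.approx(np.mean(list(per_node.values())))


def wasserstein_lp_oracle(a, b):
    """Discrete optimal-transport LP for W1 between empirical distributions."""
    from scipy.optimize import linprog

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    a_eq = []
    for i in range(na):
        row = np.zeros((na, nb)); row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(nb):
        row = np.zeros((na, nb)); row[:, j] = 1
        a_eq.append(row.ravel())
    b_eq = np.concatenate([np.full(na, 1 / na), np.full(nb, 1 / nb)])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, method="highs")
    return res.fun


class TestCentralityDistance:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=20)
        assert con.centrality_distance(x, x.copy(), "wasserstein") == 0.0
        assert con.centrality_distance(x, x.copy(), "energy") == 0.0

    def test_point_masses_closed_form(self):
        assert con.centrality_distance([2.0], [5.5], "wasserstein") == pytest.approx(3.5)

    def test_wasserstein_matches_lp_oracle(self, rng):
        for _ in range(3):
            a = rng.normal(size=7)
            b = rng.normal(1.0, size=5)
            assert con.centrality_distance(a, b, "wasserstein") == pytest.approx(
                wasserstein_lp_oracle(a, b), abs=1e-9
            )

    def test_symmetry_and_nonnegativity(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=11)
        for metric in ("wasserstein", "energy"):
            d_ab = con.centrality_distance(a, b, metric)
            d_ba = con.centrality_distance(b, a, metric)
            assert d_ab == pytest.approx(d_ba)
            assert d_ab >= 0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            con.centrality_distance([], [1.0])


class TestExports:
    def test_edge_list_graphml_partition_roundtrip(self, tmp_path, rng):
        fc = con.build_fc(rng.normal(size=(5, 40)))
        g = con.fc_graph(fc, "all")
        part = con.detect_communities(g, "louvain", seed=0)
        con.write_edge_list(g, tmp_path / "edges.tsv")
        con.write_graphml(g, tmp_path / "g.graphml")
        con.write_partition(part, tmp_path / "part.tsv")
        import csv

        with open(tmp_path / "edges.tsv") as f:
            rows = list(csv.reader(f, delimiter="\t"))
        assert rows[0] == ["node_a", "node_b", "weight"]
        assert len(rows) - 1 == g.number_of_edges()
        import networkx as nx

        g2 = nx.read_graphml(tmp_path / "g.graphml")
        assert g2.number_of_edges() == g.number_of_edges()


class TestEnsembleFC:
    def _trials(self, values, odors, coords):
        values = np.asarray(values, float)
        return pre.TrialTensor(
            values=values,
            window_offsets=np.arange(values.shape[2]),
            odor_labels=np.asarray(odors, dtype=object),
            session_ids=np.zeros(values.shape[0], int),
            frame_rate=2.0,
            voxel_coords=np.asarray(coords),
            region_id=np.ones(values.shape[1], int),
        )

    def test_two_voxel_weighted_distance(self, rng):
        values = rng.normal(size=(4, 2, 6))
        coords = np.array([[0, 0, 0], [3, 4, 0]])  # distance 5
        tt = self._trials(values, ["A"] * 4, coords)
        out = con.ensemble_fc(tt, {"A": np.array([0, 1])})
        sel = np.asarray(tt.odor_labels) == "A"
        flat = values[sel].transpose(1, 0, 2).reshape(2, -1)
        r = np.corrcoef(flat)[0, 1]
        assert out.weighted_coverage["A"] == pytest.approx(5.0 * r)

    def test_planted_ensembles_block_structure(self, rng):
        # two ensembles driven by disjoint odors: within-block r >> between
        n_trials, f = 30, 10
        odors = np.array(["A", "B"] * (n_trials // 2), dtype=object)
        values = 0.1 * rng.normal(size=(n_trials, 8, f))
        values[odors == "A", :4, :] += 1.0 + 0.2 * rng.normal(size=(15, 4, f))
        values[odors == "B", 4:, :] += 1.0 + 0.2 * rng.normal(size=(15, 4, f))
        coords = np.column_stack([np.arange(8), np.zeros(8), np.zeros(8)])
        tt = self._trials(values, odors, coords)
        out = con.ensemble_fc(tt, {"A": np.arange(4), "B": np.arange(4, 8)})
        corr = out.fc.corr
        inv = {v: i for i, v in enumerate(out.voxel_indices)}
        a_pos = [inv[v] for v in range(4)]
        b_pos = [inv[v] for v in range(4, 8)]
        within = np.concatenate([
            corr[np.ix_(a_pos, a_pos)][np.triu_indices(4, 1)],
            corr[np.ix_(b_pos, b_pos)][np.triu_indices(4, 1)],
        ])
        between = corr[np.ix_(a_pos, b_pos)].ravel()
        assert within.mean() > between.mean() + 0.5

    def test_single_pair_minimum(self, rng):
        tt = self._trials(rng.normal(size=(4, 3, 5)), ["A"] * 4, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            con.ensemble_fc(tt, {"A": np.array([0])})
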
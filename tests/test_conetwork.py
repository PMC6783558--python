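"""Spearman matrices (vs rank-then-Pearson oracle), thresholded network
construction, topology summaries and graph export."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ripresil.conetwork import (
    CooccurrenceNetwork,
    CorrelationMatrices,
    build_network,
    export_network,
    filter_network_taxa,
    spearman_matrix,
    topology_summary,
)
from ripresil.tables_io import CompositionTable, CountTable


def _composition(matrix, taxa=None, samples=None):
    matrix = np.asarray(matrix, dtype=float)
    taxa = taxa or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"S{j}" for j in range(matrix.shape[1])]
    props = matrix / matrix.sum(axis=0, keepdims=True)
    return CompositionTable(pd.DataFrame(props, index=taxa, columns=samples))


def _brute_force_spearman(x, y):
    """Rank (average ties) then Pearson, written independently."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearmanMatrix:
    def test_monotone_pair_is_one(self):
        a = np.array([1, 2, 3, 5, 8, 13.0])
        comp = _composition(np.vstack([a, 2 * a, 20 - a]))
        corr = spearman_matrix(comp)
        assert corr.rho[0, 1] == pytest.approx(1.0)
        assert corr.p[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_minus_one(self):
        a = np.array([1, 2, 3, 4, 5, 6.0])
        b = a[::-1].copy()
        comp = _composition(np.vstack([a, b, a + b]))
        corr = spearman_matrix(comp)
        assert corr.rho[0, 1] == pytest.approx(-1.0)

    def test_tied_pair_matches_brute_force_oracle(self):
        # 8 samples with a tie in each row
        x = np.array([3, 3, 1, 4, 6, 2, 5, 7.0])
        y = np.array([2, 5, 5, 1, 7, 3, 6, 4.0])
        # constant column sums so the ties survive closure to proportions
        comp = _composition(np.vstack([x, y, 20.0 - x - y]))
        corr = spearman_matrix(comp)
        assert corr.rho[0, 1] == pytest.approx(_brute_force_spearman(x, y), abs=1e-12)

    def test_matrix_matches_oracle_and_scipy(self, rng):
        x = rng.random((6, 12))
        comp = _composition(x)
        corr = spearman_matrix(comp)
        # proportions, not raw values: ranks are taken on the closed data
        props = comp.proportions.to_numpy()
        for i, j in itertools.combinations(range(6), 2):
            oracle = _brute_force_spearman(props[i], props[j])
            assert corr.rho[i, j] == pytest.approx(oracle, abs=1e-12)
            rho_sp, p_sp = stats.spearmanr(props[i], props[j])
            assert corr.rho[i, j] == pytest.approx(rho_sp, abs=1e-12)
            assert corr.p[i, j] == pytest.approx(p_sp, abs=1e-8)

    def test_symmetry_and_diagonal(self, rng):
        corr = spearman_matrix(_composition(rng.random((5, 9))))
        assert np.allclose(corr.rho, corr.rho.T, atol=1e-12)
        assert np.all(np.diagonal(corr.rho) == 1.0)
        assert np.all(np.diagonal(corr.p) == 0.0)

    def test_constant_taxon_is_nan_with_warning(self):
        x = np.vstack(
            [np.ones(6), np.arange(6) + 1.0, (np.arange(6) + 1.0)[::-1]]
        )
        # make column sums constant so the constant taxon stays constant
        comp = CompositionTable(
            pd.DataFrame(x / x.sum(0), index=["c", "a", "b"],
                         columns=[f"S{j}" for j in range(6)])
        )
        with pytest.warns(UserWarning, match="constant"):
            corr = spearman_matrix(comp)
        assert np.isnan(corr.rho[0, 1])

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="5 samples"):
            spearman_matrix(_composition(rng.random((3, 4))))


class TestFilterNetworkTaxa:
    def _table(self, prevalences, n_samples=10):
        rows = []
        for k, prev in enumerate(prevalences):
            row = np.zeros(n_samples, dtype=int)
            row[: int(round(prev * n_samples))] = 5
            rows.append(row)
        counts = pd.DataFrame(np.vstack(rows) + 0,
                              index=[f"g{k}" for k in range(len(prevalences))],
                              columns=[f"S{j}" for j in range(n_samples)])
        counts.iloc[0] += 1  # keep all columns positive
        return CountTable(counts)

    def test_zero_thresholds_are_identity(self, otu_table):
        out = filter_network_taxa(otu_table, 0.0, 0.0)
        assert out.taxon_ids == otu_table.taxon_ids

    def test_prevalence_boundary(self):
        table = self._table([1.0, 0.3])
        kept = filter_network_taxa(table, min_prevalence=0.3)
        assert "g1" in kept.taxon_ids
        dropped = filter_network_taxa(table, min_prevalence=0.34)
        assert "g1" not in dropped.taxon_ids

    def test_known_prevalences_enumeration(self):
        prevalences = [1.0, 0.9, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
        table = self._table(prevalences)
        kept = filter_network_taxa(table, min_prevalence=0.45)
        expected = [f"g{k}" for k, p in enumerate(prevalences) if p >= 0.45]
        assert kept.taxon_ids == expected

    def test_empty_result_advises(self):
        counts = pd.DataFrame(
            [[5] * 5 + [0] * 5, [0] * 5 + [5] * 5],
            index=["g0", "g1"],
            columns=[f"S{j}" for j in range(10)],
        )
        with pytest.raises(ValueError, match="relax"):
            filter_network_taxa(CountTable(counts), min_prevalence=0.9)


def _corr_from_edges(n_taxa, edges):
    """CorrelationMatrices with the given (i, j, rho, p) entries."""
    taxa = [f"g{i}" for i in range(n_taxa)]
    rho = np.zeros((n_taxa, n_taxa))
    p = np.ones((n_taxa, n_taxa))
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    for i, j, r, pv in edges:
        rho[i, j] = rho[j, i] = r
        p[i, j] = p[j, i] = pv
    return CorrelationMatrices(taxa, rho, p, n_samples=24)


class TestBuildNetwork:
    def test_strict_thresholds(self):
        corr = _corr_from_edges(4, [(0, 1, 0.7, 0.005), (1, 2, 0.6, 0.001),
                                    (2, 3, 0.9, 0.01)])
        net = build_network(corr, rho_min=0.6, p_max=0.01)
        assert set(net.edges) == {("g0", "g1")}  # 0.6 and 0.01 excluded (strict)
        assert net.graph.edges[("g0", "g1")]["sign"] == 1

    def test_rho_min_one_gives_no_edges(self):
        corr = _corr_from_edges(3, [(0, 1, 1.0, 0.0)])
        net = build_network(corr, rho_min=1.0, p_max=0.01)
        assert net.edges == []

    def test_negative_edge_sign(self):
        corr = _corr_from_edges(3, [(0, 2, -0.8, 0.001)])
        net = build_network(corr, rho_min=0.6, p_max=0.01)
        assert net.graph.edges[("g0", "g2")]["sign"] == -1

    def test_isolated_nodes_retained_and_flagged(self):
        corr = _corr_from_edges(4, [(0, 1, 0.8, 0.001)])
        net = build_network(corr)
        assert len(net.nodes) == 4
        assert net.graph.nodes["g3"]["isolated"] is True
        assert len(net.drop_isolated().nodes) == 2

    def test_nan_pairs_skipped(self):
        corr = _corr_from_edges(3, [(0, 1, 0.8, 0.001)])
        corr.rho[1, 2] = corr.rho[2, 1] = np.nan
        corr.p[1, 2] = corr.p[2, 1] = np.nan
        net = build_network(corr)
        assert set(net.edges) == {("g0", "g1")}

    def test_edge_set_invariant_to_orderings(self, rng):
        x = rng.random((6, 20))
        comp = _composition(x)
        net1 = build_network(spearman_matrix(comp), 0.3, 0.05)
        perm_taxa = list(reversed(comp.taxon_ids))
        perm_samples = list(rng.permutation(comp.sample_ids))
        shuffled = CompositionTable(
            comp.proportions.loc[perm_taxa, perm_samples]
        )
        net2 = build_network(spearman_matrix(shuffled), 0.3, 0.05)
        canon = lambda net: {frozenset(e) for e in net.edges}
        assert canon(net1) == canon(net2)


class TestTopologySummary:
    def _from_graph(self, g):
        for u, v in g.edges:
            g.edges[u, v].setdefault("rho", 0.8)
            g.edges[u, v].setdefault("sign", 1)
        return CooccurrenceNetwork(graph=g, rho_min=0.6, p_max=0.01)

    def test_complete_graph_closed_form(self):
        topo = topology_summary(self._from_graph(nx.complete_graph(4)))
        assert topo.average_degree == pytest.approx(3.0)
        assert topo.average_path_length == pytest.approx(1.0)
        assert topo.diameter == 1.0
        assert topo.clustering_coefficient == pytest.approx(1.0)

    def test_avg_degree_identity_on_printed_sizes(self, rng):
        # the two observed network sizes: 24 nodes/112 edges and 20/67
        for n, e, expected in ((24, 112, 9.333), (20, 67, 6.700)):
            g = nx.gnm_random_graph(n, e, seed=int(rng.integers(2**31)))
            topo = topology_summary(self._from_graph(g))
            assert topo.n_edges == e
            assert topo.average_degree == pytest.approx(expected, abs=5e-4)
            assert topo.average_degree == pytest.approx(2 * e / n)

    def test_two_disjoint_cliques_louvain_q_half(self):
        """Two disjoint 5-cliques: the two-module partition has Q = 0.5
        (closed form, and optimal over all bipartitions)."""
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        topo = topology_summary(self._from_graph(g), modularity_seed=1)
        assert topo.modularity == pytest.approx(0.5)
        # exhaustive check that no bipartition beats the two cliques
        best = max(
            nx.community.modularity(g, [set(combo), set(g) - set(combo)])
            for r in range(1, 10)
            for combo in itertools.combinations(g, r)
        )
        assert best == pytest.approx(0.5)

    def test_modularity_deterministic_for_seed(self, rng):
        g = nx.gnm_random_graph(30, 60, seed=7)
        net = self._from_graph(g)
        q1 = topology_summary(net, modularity_seed=5).modularity
        q2 = topology_summary(net, modularity_seed=5).modularity
        assert q1 == q2
        spread = [topology_summary(net, modularity_seed=s).modularity for s in range(6)]
        assert max(spread) - min(spread) < 0.05

    def test_positive_negative_edge_split(self):
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.9, sign=1)
        g.add_edge("b", "c", rho=-0.7, sign=-1)
        topo = topology_summary(CooccurrenceNetwork(g, 0.6, 0.01))
        assert (topo.n_positive_edges, topo.n_negative_edges) == (1, 1)
        assert topo.n_edges == topo.n_positive_edges + topo.n_negative_edges

    def test_path_length_on_largest_component(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.complete_graph(2))
        topo = topology_summary(self._from_graph(g))
        # largest component is the 3-path: mean distance (1+1+2)/3
        assert topo.average_path_length == pytest.approx(4 / 3)
        assert topo.diameter == 2.0

    def test_edgeless_and_empty(self):
        g = nx.empty_graph(3)
        topo = topology_summary(self._from_graph(g))
        assert topo.n_edges == 0 and np.isnan(topo.modularity)
        with pytest.raises(ValueError):
            topology_summary(CooccurrenceNetwork(nx.Graph(), 0.6, 0.01))


class TestExport:
    def _network(self):
        corr = _corr_from_edges(4, [(0, 1, 0.8, 0.001), (1, 2, -0.7, 0.002)])
        taxonomy = pd.Series(
            {f"g{i}": f"Archaea;Phylum{i};c;o;f;g{i}" for i in range(4)}
        )
        return build_network(corr, taxonomy=taxonomy)

    @pytest.mark.parametrize("fmt,reader", [
        ("gexf", nx.read_gexf),
        ("graphml", nx.read_graphml),
    ])
    def test_round_trip(self, tmp_path, fmt, reader):
        net = self._network()
        path = tmp_path / f"net.{fmt}"
        export_network(net, str(path), fmt)
        g = reader(str(path))
        assert set(g.nodes) == set(net.nodes)
        assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in net.edges}
        assert g.nodes["g0"]["phylum"] == "Phylum0"
        assert g.edges["g0", "g1"]["rho"] == pytest.approx(0.8)

    def test_edge_tsv_contents(self, tmp_path):
        net = self._network()
        path = tmp_path / "edges.tsv"
        export_network(net, str(path), "edge_tsv")
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 2
        assert set(df.columns) == {"taxon_a", "taxon_b", "rho", "p", "sign"}

    def test_empty_edge_network_exports(self, tmp_path):
        corr = _corr_from_edges(3, [])
        net = build_network(corr)
        path = tmp_path / "empty.gexf"
        export_network(net, str(path), "gexf")
        assert set(nx.read_gexf(str(path)).nodes) == {"g0", "g1", "g2"}

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(self._network(), str(tmp_path / "x"), "dot")
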
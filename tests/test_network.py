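"""Co-occurrence network core: correlation oracle, thresholds, topology, roles."""

import logging
import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import spearmanr

from otunet import (
    CooccurrenceNetwork,
    CorrelationResult,
    OtuTable,
    build_network,
    classify_role,
    detect_modules,
    spearman_exact_pvalue,
    spearman_matrix,
    topology,
    zi_pi,
)


def brute_force_spearman(x, y):
    """1 - 6 sum(d^2) / (n (n^2 - 1)) on tie-free data — the textbook formula."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    return 1.0 - 6.0 * ((rx - ry) ** 2).sum() / (n * (n ** 2 - 1))


def _table(rows, ids=None):
    rows = np.asarray(rows)
    ids = ids or tuple(f"o{i}" for i in range(rows.shape[0]))
    return OtuTable(rows, ids, tuple(f"s{j}" for j in range(rows.shape[1])))


def _corr(rho, p, ids):
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    return CorrelationResult(rho=rho, p=p, otu_ids=tuple(ids), n_samples=10)


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        t = _table([[1, 2, 3, 4, 5], [10, 20, 30, 40, 50], [5, 4, 3, 2, 1]])
        corr = spearman_matrix(t)
        assert corr.rho[0, 1] == pytest.approx(1.0)
        assert corr.rho[0, 2] == pytest.approx(-1.0)
        assert corr.p[0, 1] == 0.0 and corr.p[0, 2] == 0.0

    def test_hand_computed_rho(self):
        # x=(1..5), y=(3,1,2,4,5): d^2 = (4,1,1,0,0) -> rho = 1 - 36/120 = 0.7
        t = _table([[1, 2, 3, 4, 5], [3, 1, 2, 4, 5]])
        corr = spearman_matrix(t)
        assert corr.rho[0, 1] == pytest.approx(0.7, abs=1e-12)
        # and agreement with the rank formula on another permutation
        t2 = _table([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5]])
        assert spearman_matrix(t2).rho[0, 1] == pytest.approx(
            brute_force_spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]), abs=1e-12)

    def test_matches_brute_force_on_tiefree_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            x = rng.permutation(100)[:8] + 1  # distinct -> tie-free
            y = rng.permutation(100)[:8] + 1
            corr = spearman_matrix(_table([x, y]))
            assert abs(corr.rho[0, 1] - brute_force_spearman(x, y)) < 1e-12

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 4, size=(6, 15))  # many ties incl. zeros
        counts[np.ptp(counts, axis=1) == 0] += rng.integers(
            0, 3, size=(1, 15))  # avoid constants
        t = _table(counts)
        corr = spearman_matrix(t)
        ref_rho, ref_p = spearmanr(counts.T)
        keep = [t.otu_ids.index(o) for o in corr.otu_ids]
        assert np.allclose(corr.rho, ref_rho[np.ix_(keep, keep)], atol=1e-12)
        offdiag = ~np.eye(len(keep), dtype=bool)
        assert np.allclose(corr.p[offdiag],
                           ref_p[np.ix_(keep, keep)][offdiag], atol=1e-10)

    def test_constant_otu_dropped_with_warning(self, caplog):
        t = _table([[1, 2, 3, 4, 5], [7, 7, 7, 7, 7], [2, 1, 4, 3, 5]])
        with caplog.at_level(logging.WARNING, logger="otunet.network"):
            corr = spearman_matrix(t)
        assert corr.otu_ids == ("o0", "o2")
        assert any("constant" in rec.message for rec in caplog.records)

    def test_prevalence_filter(self):
        t = _table([[1, 2, 3, 4, 5], [0, 0, 0, 0, 3], [5, 3, 1, 2, 4]])
        corr = spearman_matrix(t, min_prevalence=0.5)
        assert "o1" not in corr.otu_ids

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(_table([[1, 2, 3], [3, 1, 2]]))

    def test_exact_permutation_pvalue_small_n(self):
        x, y = [1, 2, 3, 4, 5], [1, 2, 3, 5, 4]
        p = spearman_exact_pvalue(x, y)
        # P(|rho| >= 0.9) under uniform ranks, n=5: 10/120 by full enumeration
        assert p == pytest.approx(10 / 120)


class TestBuildNetwork:
    def test_threshold_boundaries(self):
        rho = [[1.0, 0.71, 0.70], [0.71, 1.0, -0.9], [0.70, -0.9, 1.0]]
        p = [[0.0, 0.005, 0.001], [0.005, 0.0, 0.02], [0.001, 0.02, 0.0]]
        net = build_network(_corr(rho, p, "abc"))
        # 0.71/0.005 kept; 0.70 exactly -> rejected; |-0.9| strong but p=0.02 -> rejected
        assert net.edge_set() == {frozenset(("a", "b"))}

    def test_negative_correlations_kept_by_default(self):
        rho = [[1.0, -0.9], [-0.9, 1.0]]
        p = [[0.0, 0.001], [0.001, 0.0]]
        net = build_network(_corr(rho, p, "ab"))
        assert net.n_edges == 1
        assert net.graph.edges["a", "b"]["sign"] == "-"
        assert build_network(_corr(rho, p, "ab"), positive_only=True).n_edges == 0

    def test_no_qualifying_pair_empty_network(self):
        rho = [[1.0, 0.2], [0.2, 1.0]]
        p = [[0.0, 0.5], [0.5, 0.0]]
        net = build_network(_corr(rho, p, "ab"))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_isolated_otus_excluded(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.95
        p = np.full((3, 3), 0.5)
        p[0, 1] = p[1, 0] = 1e-5
        np.fill_diagonal(p, 0)
        net = build_network(_corr(rho, p, "abc"))
        assert set(net.graph.nodes) == {"a", "b"}

    def test_raising_rho_min_never_adds_edges(self):
        rng = np.random.default_rng(12)
        n = 20
        rho = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (n, n))), -1, 1)
        np.fill_diagonal(rho, 1)
        p = (lambda a: (a + a.T) / 2)(rng.uniform(0, 0.05, (n, n)))
        np.fill_diagonal(p, 0)
        corr = _corr(rho, p, [f"o{i}" for i in range(n)])
        counts = [build_network(corr, rho_min=r).n_edges
                  for r in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestTopology:
    def test_triangle(self):
        topo = topology(nx.complete_graph(3), modules={i: 0 for i in range(3)})
        assert topo.average_clustering_coefficient == 1.0
        assert topo.average_path_length == 1.0
        assert topo.edge_density == 1.0

    def test_path_graph_average_path_length(self):
        topo = topology(nx.path_graph(3), modules={i: 0 for i in range(3)})
        assert topo.average_path_length == pytest.approx(4 / 3)

    def test_identities_on_published_scale_graph(self):
        g = nx.gnm_random_graph(153, 961, seed=0)
        topo = topology(g, modules={n: 0 for n in g})
        assert round(topo.average_degree, 3) == 12.562
        assert topo.average_degree == pytest.approx(2 * 961 / 153)
        assert topo.complexity == pytest.approx(961 / 153)

    def test_identities_hold_on_random_graphs(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            e = int(rng.integers(n - 1, n * (n - 1) // 2))
            g = nx.gnm_random_graph(n, e, seed=int(rng.integers(2 ** 31)))
            topo = topology(g, modules={v: 0 for v in g})
            assert topo.average_degree == pytest.approx(2 * topo.edges / topo.nodes)
            assert topo.edge_density == pytest.approx(
                2 * topo.edges / (topo.nodes * (topo.nodes - 1)))
            assert topo.complexity == pytest.approx(topo.average_degree / 2)

    def test_disconnected_pairs_mode(self):
        g = nx.Graph([(0, 1), (2, 3)])  # two components
        topo = topology(g, modules={v: v // 2 for v in g})
        assert topo.average_path_length == 1.0  # mean over connected pairs only

    def test_empty_network_undefined_metrics(self):
        net = CooccurrenceNetwork(graph=nx.Graph(), rho_min=0.7, p_max=0.01)
        topo = topology(net)
        assert topo.nodes == 0 and topo.edges == 0
        assert math.isnan(topo.average_degree) and math.isnan(topo.modularity)

    def test_single_module_partition_has_zero_modularity(self):
        g = nx.gnm_random_graph(12, 30, seed=1)
        topo = topology(g, modules={v: 0 for v in g})
        assert topo.modularity == pytest.approx(0.0, abs=1e-12)


class TestDetectModules:
    @staticmethod
    def _two_cliques():
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        return CooccurrenceNetwork(graph=g, rho_min=0.7, p_max=0.01)

    def test_two_disjoint_cliques(self):
        net = self._two_cliques()
        mods = detect_modules(net, seed=0)
        assert len(set(mods.values())) == 2
        topo = topology(net, mods)
        assert topo.modularity == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        mods = detect_modules(nx.complete_graph(8), seed=0)
        assert len(set(mods.values())) == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(nx.Graph())

    def test_seeded_determinism(self):
        g = nx.gnm_random_graph(40, 120, seed=5)
        assert detect_modules(g, seed=3) == detect_modules(g, seed=3)

    def test_labels_canonical_by_size(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(6))
        mods = detect_modules(g, seed=0)
        # larger module gets id 0
        sizes = {m: sum(1 for v in mods.values() if v == m) for m in set(mods.values())}
        assert sizes[0] == 6 and sizes[1] == 3


class TestZiPi:
    def test_all_edges_within_module_pi_zero(self):
        g = nx.complete_graph(4)
        df = zi_pi(g, {v: 0 for v in g})
        assert (df["pi"] == 0.0).all()
        assert (df["zi"] == 0.0).all()  # all degrees equal the module mean

    def test_even_split_pi_half(self):
        # hub connected to one node in each of two other modules
        g = nx.Graph([("h", "a"), ("h", "b"), ("a", "a2"), ("b", "b2")])
        mods = {"h": 0, "a": 1, "a2": 1, "b": 2, "b2": 2}
        df = zi_pi(g, mods)
        assert df.loc["h", "pi"] == pytest.approx(0.5)

    def test_pi_degree_normalization(self):
        rng = np.random.default_rng(14)
        g = nx.gnm_random_graph(30, 90, seed=7)
        mods = detect_modules(g, seed=0)
        df = zi_pi(g, mods)
        assert (df["pi"] >= 0).all() and (df["pi"] <= 1).all()
        # node touching m modules has pi <= 1 - 1/m
        for v in g.nodes:
            touched = {mods[u] for u in g.neighbors(v)}
            assert df.loc[v, "pi"] <= 1 - 1 / len(touched) + 1e-12

    def test_missing_module_assignment_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="'b'"):
            zi_pi(g, {"a": 0})


class TestClassifyRole:
    @pytest.mark.parametrize(
        "zi, pi, role",
        [
            (3.0, 0.10, "module_hub"),
            (1.0, 0.70, "connector"),
            (3.0, 0.90, "network_hub"),
            (0.0, 0.00, "peripheral"),
            (2.5, 0.62, "peripheral"),  # boundary values fall to lower category
            (2.5, 0.90, "connector"),
            (3.0, 0.62, "module_hub"),
        ],
    )
    def test_role_grid(self, zi, pi, role):
        assert classify_role(zi, pi) == role

    def test_pi_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_role(0.0, 1.5)
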
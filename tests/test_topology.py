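"""Topology metrics, with brute-force oracles on small graphs."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from adnet import (
    detect_modules,
    harmonic_geodesic,
    modularity,
    node_roles,
    per_sample_subnetworks,
    powerlaw_fit,
    summarize,
    topology_vs_parameters,
)
from adnet.io_formats import SampleMetadata
from adnet.topology import average_clustering

from conftest import random_count_table


# ----- independent brute-force oracles (pure python) -----

def brute_distances(g):
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    d = [[float("inf")] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0
    for u, v in g.edges:
        d[idx[u]][idx[v]] = d[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def brute_harmonic_gd(g):
    d = brute_distances(g)
    n = len(d)
    total, pairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if d[i][j] != float("inf"):
                total += 1.0 / d[i][j]
    return pairs / total


def brute_avg_clustering(g):
    acc = 0.0
    for u in g.nodes:
        nbrs = list(g[u])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        acc += 2.0 * links / (k * (k - 1))
    return acc / g.number_of_nodes()


def brute_modularity(g, partition):
    m = g.number_of_edges()
    q = 0.0
    comms = set(partition.values())
    for c in comms:
        members = [n for n in g.nodes if partition[n] == c]
        e_in = sum(1 for u, v in g.edges if partition[u] == c and partition[v] == c)
        deg = sum(g.degree(n) for n in members)
        q += e_in / m - (deg / (2.0 * m)) ** 2
    return q


def small_graph_suite():
    """All connected + some disconnected graphs on 4-7 nodes from the atlas."""
    graphs = []
    for g in nx.graph_atlas_g()[1:]:
        if 4 <= g.number_of_nodes() <= 7 and g.number_of_edges() >= 1:
            graphs.append(g)
    return graphs[::3]  # every third: 140+ graphs, enough coverage


class TestClosedForms:
    def test_triangle(self):
        g = nx.complete_graph(3)
        s = summarize(g)
        assert s.avgK == pytest.approx(2.0)
        assert s.avgCC == pytest.approx(1.0)
        assert s.GD == pytest.approx(1.0)
        assert s.pct_positive_edges == pytest.approx(100.0)

    def test_star(self):
        s = summarize(nx.star_graph(3))
        assert s.avgK == pytest.approx(1.5)
        assert s.avgCC == pytest.approx(0.0)

    def test_two_disjoint_edges_gd(self):
        g = nx.Graph([(0, 1), (2, 3)])
        assert harmonic_geodesic(g) == pytest.approx(3.0)

    def test_path_gd(self):
        assert harmonic_geodesic(nx.path_graph(3)) == pytest.approx(1.2)

    @pytest.mark.parametrize("n", [2, 4, 7, 15])
    def test_complete_graph_gd_is_one(self, n):
        assert harmonic_geodesic(nx.complete_graph(n)) == pytest.approx(1.0)

    def test_single_edge_gd(self):
        assert harmonic_geodesic(nx.path_graph(2)) == pytest.approx(1.0)

    def test_no_finite_pair_rejected(self):
        with pytest.raises(ValueError):
            harmonic_geodesic(nx.empty_graph(3))


class TestBruteForceEquivalence:
    def test_metrics_match_bruteforce_on_small_graphs(self):
        for g in small_graph_suite():
            s = summarize(g)
            assert s.avgK == pytest.approx(
                2 * g.number_of_edges() / g.number_of_nodes())
            assert s.GD == pytest.approx(brute_harmonic_gd(g), abs=1e-9), g
            assert s.avgCC == pytest.approx(brute_avg_clustering(g), abs=1e-9), g

    def test_detected_partition_q_matches_definition(self):
        for g in small_graph_suite()[::5]:
            part, q, n_mod = detect_modules(g)
            assert q == pytest.approx(brute_modularity(g, part), abs=1e-9)
            assert n_mod == len(set(part.values()))


class TestDetectModules:
    def test_two_disjoint_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        part, q, n_mod = detect_modules(g)
        assert n_mod == 2
        assert q == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        part, q, n_mod = detect_modules(nx.complete_graph(5))
        assert n_mod == 1
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_planted_three_module_graph_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(0)
        g = nx.Graph()
        truth = {}
        for m in range(3):
            members = [m * 12 + i for i in range(12)]
            for n in members:
                truth[n] = m
            for a, b in itertools.combinations(members, 2):
                if rng.random() < 0.8:
                    g.add_edge(a, b)
        nodes = list(g.nodes)
        for _ in range(15):
            a, b = rng.choice(nodes, 2, replace=False)
            if truth[a] != truth[b]:
                g.add_edge(a, b)
        part, q, _ = detect_modules(g)
        labels = [part[n] for n in nodes]
        ari = adjusted_rand_score([truth[n] for n in nodes], labels)
        assert ari >= 0.9

    def test_init_partition_never_decreases_q(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            g = nx.planted_partition_graph(3, 10, 0.7, 0.05, seed=trial)
            planted = {n: n // 10 for n in g.nodes}
            q0 = modularity(g, planted)
            _, q1, _ = detect_modules(g, init_partition=planted)
            assert q1 >= q0 - 1e-12

    def test_leading_eigenvector_available(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        _, q, n_mod = detect_modules(g, method="leading_eigenvector")
        assert n_mod == 2


class TestPowerlawFit:
    def test_exact_powerlaw_histogram(self):
        # configuration multigraph with degree frequencies ~ k^-2, k=1..10:
        # the degree histogram is exact by construction, so the log-log OLS
        # is (near-)perfectly linear up to integer rounding of frequencies
        degs = [k for k in range(1, 11) for _ in range(int(round(1000 / k**2)))]
        if sum(degs) % 2:
            degs.append(1)
        g = nx.configuration_model(degs, seed=0)
        r2, p = powerlaw_fit(g)
        assert r2 > 0.99
        assert p < 0.01

    def test_regular_graph_rejected(self):
        with pytest.raises(ValueError):
            powerlaw_fit(nx.cycle_graph(10))

    def test_er_graph_not_scale_free(self):
        r2s = []
        for seed in range(20):
            g = nx.gnm_random_graph(500, 1500, seed=seed)
            r2s.append(powerlaw_fit(g)[0])
        assert np.median(r2s) < 0.9


class TestNodeRoles:
    def test_participation_examples(self):
        g = nx.Graph()
        g.add_edges_from([("h", f"a{i}") for i in range(2)])
        g.add_edges_from([("h", f"b{i}") for i in range(2)])
        part = {"h": 0, "a0": 0, "a1": 0, "b0": 1, "b1": 1}
        roles = {r.node: r for r in node_roles(g, part)}
        assert roles["h"].p == pytest.approx(0.5)   # degree 4 split evenly
        assert roles["a0"].p == pytest.approx(0.0)  # all edges inside module

    def test_uniform_within_degree_gives_no_hubs(self):
        g = nx.complete_graph(6)
        part = {n: 0 for n in g.nodes}
        roles = node_roles(g, part)
        assert all(r.z == 0 for r in roles)
        assert all(r.role != "module hub" for r in roles)

    def test_partition_must_cover_nodes(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            node_roles(g, {0: 0, 1: 0})

    def test_hub_detected_in_modular_graph(self):
        g = nx.Graph()
        for i in range(10):
            g.add_edge("hub", f"m{i}")
        for i in range(9):
            g.add_edge(f"m{i}", f"m{i+1}")
        g.add_edge("other1", "other2")
        part = {n: 0 for n in g.nodes if str(n).startswith(("hub", "m"))}
        part.update({"other1": 1, "other2": 1})
        roles = {r.node: r for r in node_roles(g, part)}
        assert roles["hub"].role == "module hub"


class TestPerSampleSubnetworks:
    def test_identity_empty_and_triangle(self, tiny_table):
        import pandas as pd
        from adnet import AbundanceTable
        data = pd.DataFrame(
            {"all": [1, 1, 1, 1], "none": [0, 0, 0, 0], "tri": [1, 1, 1, 0]},
            index=["a", "b", "c", "d"],
        )
        table = AbundanceTable(data=data, kind="count")
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        subs = per_sample_subnetworks(net, table)
        assert nx.utils.graphs_equal(subs["all"], net)
        assert subs["none"].number_of_nodes() == 0
        assert set(subs["tri"].edges) == {("a", "b"), ("b", "c"), ("a", "c")}

    def test_node_absent_from_table_rejected(self, tiny_table):
        net = nx.Graph([("OTU_1", "missing")])
        with pytest.raises(ValueError):
            per_sample_subnetworks(net, tiny_table)


class TestTopologyVsParameters:
    def _meta(self, values):
        n = len(values)
        df = pd.DataFrame({
            "digester_id": ["C1"] * n, "group": ["control"] * n,
            "day": [45 + i for i in range(n)],
            "vs_load": values, "ph": 7.0, "acetate": 0.5, "total_ammonia": 2.0,
            "vs_removal": 50.0, "biogas_production": 3.0,
            "methane_production": 1.8,
        }, index=[f"s{i}" for i in range(n)])
        df["day"] = df["day"].clip(upper=76)
        return SampleMetadata(df=df)

    def test_perfect_and_inverse_correlation(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        meta = self._meta(vals)
        summaries = pd.DataFrame(
            {"n_edges": vals, "GD": vals[::-1], "const": 1.0},
            index=meta.samples,
        )
        r, p = topology_vs_parameters(summaries, meta, parameters=("vs_load",))
        assert r.loc["n_edges", "vs_load"] == pytest.approx(1.0)
        assert r.loc["GD", "vs_load"] == pytest.approx(-1.0)
        assert np.isnan(r.loc["const", "vs_load"])  # constant property masked

    def test_tracking_edge_count_recovers_band(self):
        """Edge count constructed to track VS load gives r above the
        detection band used for the empirical networks (r > 0.38)."""
        rng = np.random.default_rng(3)
        load = np.linspace(1.0, 1.5, 30) + rng.normal(0, 0.02, 30)
        edges = 100 + 200 * (load - 1.0) + rng.normal(0, 5, 30)
        meta = self._meta(list(load))
        summaries = pd.DataFrame({"n_edges": edges}, index=meta.samples)
        r, p = topology_vs_parameters(summaries, meta, parameters=("vs_load",))
        assert r.loc["n_edges", "vs_load"] > 0.38
        assert p.loc["n_edges", "vs_load"] < 0.05
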
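"""Network construction, graph metrics, randomization, threshold selection."""

import collections

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metcornet import (SyntheticConfig, build_network, correlation_table,
                       generate_profiles, graph_metrics, randomize_profiles,
                       select_threshold, spearman_matrix, sweep_thresholds)
from metcornet.topology import TopologySweep

from conftest import make_profile


def pair_table(rs):
    """Long correlation table from {(u, v): r}."""
    return pd.DataFrame(
        [(u, v, r, 10) for (u, v), r in rs.items()],
        columns=["u", "v", "r", "n"],
    )


class TestBuildNetwork:
    def test_threshold_zero_keeps_positive_pairs_as_complete_graph(self):
        rs = {("a", "b"): 0.3, ("a", "c"): 0.9, ("b", "c"): 0.1}
        g = build_network(pair_table(rs), threshold=0.0)
        assert g.number_of_edges() == 3

    def test_negative_correlations_excluded_by_default(self):
        rs = {("a", "b"): -0.9, ("a", "c"): 0.9}
        g = build_network(pair_table(rs), threshold=0.5)
        assert set(g.edges) == {("a", "c")}
        g2 = build_network(pair_table(rs), threshold=0.5, only_positive=False)
        assert g2.number_of_edges() == 2

    def test_threshold_one_keeps_only_perfect_pairs(self):
        rs = {("a", "b"): 1.0, ("a", "c"): 0.99}
        g = build_network(pair_table(rs), threshold=1.0)
        assert set(g.edges) == {("a", "b")}
        assert g["a"]["b"]["r"] == 1.0

    def test_all_metabolites_become_nodes_even_isolated(self):
        rs = {("a", "b"): 0.9, ("a", "c"): 0.0}
        g = build_network(pair_table(rs), threshold=0.5)
        assert set(g.nodes) == {"a", "b", "c"}


def bfs_oracle_metrics(g: nx.Graph):
    """Brute-force metrics: hand BFS, triangle counting by enumeration."""
    nodes = list(g.nodes)
    N, E = len(nodes), g.number_of_edges()
    density = np.nan if N < 2 else 2 * E / (N * (N - 1))
    avg_deg = np.nan if N == 0 else 2 * E / N
    triangles = sum(
        1 for a in nodes for b in g[a] for c in g[b]
        if c in g[a]
    ) / 6
    triples = sum(d * (d - 1) / 2 for _, d in g.degree)
    trans = 0.0 if triples == 0 else 3 * triangles / triples
    # BFS from every node
    comps = set()
    tot = cnt = 0
    for s in nodes:
        dist = {s: 0}
        q = collections.deque([s])
        while q:
            u = q.popleft()
            for v in g[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        comps.add(frozenset(dist))
        for v, d in dist.items():
            if v != s:
                tot += d
                cnt += 1
    apl = tot / cnt if cnt else np.nan
    return density, trans, avg_deg, apl, len(comps), E


class TestGraphMetrics:
    def test_complete_graph_k4(self):
        m = graph_metrics(nx.complete_graph(4))
        assert m.graph_density == 1.0
        assert m.clustering_coefficient == 1.0
        assert m.average_degree == 3.0
        assert m.average_path_length == 1.0
        assert m.n_components == 1 and m.n_edges == 6

    def test_path_graph_on_four_nodes(self):
        m = graph_metrics(nx.path_graph(4))
        assert m.n_edges == 3
        assert m.graph_density == pytest.approx(0.5)
        assert m.clustering_coefficient == 0.0
        assert m.n_components == 1
        assert m.average_path_length == pytest.approx((1 * 3 + 2 * 2 + 3) / 6)

    def test_empty_five_node_graph(self):
        g = nx.empty_graph(5)
        m = graph_metrics(g)
        assert m.n_components == 5 and m.n_edges == 0
        assert np.isnan(m.average_path_length)

    def test_single_node_density_undefined(self):
        m = graph_metrics(nx.empty_graph(1))
        assert np.isnan(m.graph_density)

    def test_agrees_with_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            g = nx.gnp_random_graph(12, rng.uniform(0.05, 0.7),
                                    seed=int(rng.integers(2 ** 31)))
            got = graph_metrics(g).as_tuple()
            want = bfs_oracle_metrics(g)
            for a, b in zip(got, want):
                if np.isnan(b):
                    assert np.isnan(a)
                else:
                    assert a == pytest.approx(b, abs=1e-12)


class TestRandomizeProfiles:
    def test_marginals_preserved_exactly(self):
        rng = np.random.default_rng(0)
        pm = make_profile(rng.standard_normal((5, 20)))
        for r in randomize_profiles(pm, n_random=3, seed=1):
            assert np.allclose(
                np.sort(r.values.to_numpy(), axis=1),
                np.sort(pm.values.to_numpy(), axis=1),
            )

    def test_randomization_destroys_correlation(self):
        cfg = SyntheticConfig(n_metabolites=20, module_sizes=(20,),
                              groups=(("g", 30),), shift_spec=(), seed=2)
        pm, _ = generate_profiles(cfg)
        mean_r = []
        for r in randomize_profiles(pm, n_random=20, seed=3):
            mean_r.append(spearman_matrix(r)["r"].mean())
        # mean over pairs and replicates within 2 SE of zero
        se = np.std(mean_r) / np.sqrt(len(mean_r))
        assert abs(np.mean(mean_r)) < 2 * max(se, 1e-3)

    def test_deterministic_under_seed(self):
        pm = make_profile(np.random.default_rng(5).standard_normal((4, 10)))
        a = [r.values.to_numpy() for r in randomize_profiles(pm, 2, seed=9)]
        b = [r.values.to_numpy() for r in randomize_profiles(pm, 2, seed=9)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestSweep:
    @pytest.fixture(scope="class")
    def small_sweep(self):
        cfg = SyntheticConfig(n_metabolites=20, module_sizes=(6, 5),
                              groups=(("g", 30),), shift_spec=(), seed=4)
        pm, truth = generate_profiles(cfg)
        corr = correlation_table(pm)
        sweep = sweep_thresholds(corr, randomize_profiles(pm, 30, seed=5))
        return pm, truth, corr, sweep

    def test_edge_count_nonincreasing_and_density_identity(self, small_sweep):
        _, _, _, sweep = small_sweep
        e = sweep.real["n_edges"].to_numpy()
        assert np.all(np.diff(e) <= 0)
        n = 20
        assert np.allclose(sweep.real["graph_density"],
                           2 * e / (n * (n - 1)), equal_nan=True)

    def test_edges_at_zero_threshold_count_positive_pairs(self, small_sweep):
        _, _, corr, sweep = small_sweep
        assert sweep.real["n_edges"].iloc[0] == int((corr["r"] > 0).sum())

    def test_real_transitivity_exceeds_null_band_at_mid_thresholds(
            self, small_sweep):
        _, _, _, sweep = small_sweep
        frame = sweep.to_frame()
        mid = frame[(frame.threshold >= 0.3) & (frame.threshold <= 0.6)]
        assert (mid["clustering_coefficient"]
                > mid["clustering_coefficient_null_q95"]).mean() > 0.8

    def test_null_band_columns_are_plot_ready(self, small_sweep):
        _, _, _, sweep = small_sweep
        frame = sweep.to_frame()
        for m in ("n_components", "n_edges"):
            for s in ("null_mean", "null_q05", "null_q95"):
                assert f"{m}_{s}" in frame.columns


class TestSelectThreshold:
    def test_component_jump_rule_without_null_band(self):
        sweep = TopologySweep(
            thresholds=np.array([0.1, 0.2, 0.3, 0.4, 0.5]),
            real=pd.DataFrame({"n_components": [1, 1, 1, 10, 12]}),
        )
        assert select_threshold(sweep) == pytest.approx(0.3)

    def test_flat_curve_falls_back_to_default(self, caplog):
        sweep = TopologySweep(
            thresholds=np.array([0.1, 0.2, 0.3]),
            real=pd.DataFrame({"n_components": [4, 4, 4]}),
        )
        assert select_threshold(sweep) == 0.5
        assert "flat" in caplog.text

    def test_override_wins_regardless_of_curve(self):
        sweep = TopologySweep(
            thresholds=np.array([0.1, 0.2]),
            real=pd.DataFrame({"n_components": [1, 5]}),
        )
        assert select_threshold(sweep, override=0.5) == 0.5

    def test_selection_lands_near_module_noise_separator(self):
        """Selected threshold tracks the within/between |r| separator.

        Separator oracle: midpoint between the 95th percentile of
        between-module |r| and the 5th percentile of within-module |r|.
        """
        devs = []
        for seed in (21, 22, 23):
            pm, truth = generate_profiles(SyntheticConfig(seed=seed))
            corr = correlation_table(pm)
            sweep = sweep_thresholds(
                corr, randomize_profiles(pm, 50, seed=100 + seed))
            sel = select_threshold(sweep)
            mem = truth.module_membership
            same = np.array([mem.get(u, -1) == mem.get(v, -2)
                             for u, v in zip(corr["u"], corr["v"])])
            r = np.abs(corr["r"].to_numpy())
            sep = (np.nanquantile(r[~same], 0.95)
                   + np.nanquantile(r[same], 0.05)) / 2
            devs.append(abs(sel - sep))
        assert np.mean(devs) <= 0.1
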
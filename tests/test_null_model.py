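"""Monte Carlo null, hypergeometric closed form, and convergence filters."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from sklearn.base import clone

from ppiconverge.ego_network import SeedList, membership_stats
from ppiconverge.null_model import (
    ConvergenceAnalyzer,
    NullModel,
    NullSummary,
    closed_form_null,
    convergence_table,
    simulate_null,
)


class TestClosedFormNull:
    def test_path_graph_end_node(self, path_graph):
        null = closed_form_null(path_graph, seed_set_size=1)
        assert null.node_mean["A"] == pytest.approx(0.6)
        assert null.node_sd["A"] == pytest.approx(np.sqrt(0.6 * 0.4), abs=1e-12)

    def test_complete_graph_degenerate(self, complete_graph):
        for k in (1, 3, 5):
            null = closed_form_null(complete_graph, seed_set_size=k)
            assert all(m == 1.0 for m in null.node_mean.values())
            assert all(s == 0.0 for s in null.node_sd.values())

    def test_full_seed_set_has_zero_variance(self, path_graph):
        null = closed_form_null(path_graph, seed_set_size=5)
        assert all(s == pytest.approx(0.0, abs=1e-12) for s in null.node_sd.values())
        assert null.node_mean["C"] == 1.0 and null.node_mean["A"] == 0.6

    def test_single_node_graph_variance_zero(self):
        g = nx.Graph()
        g.add_node("X")
        null = closed_form_null(g, seed_set_size=1)
        assert null.node_mean["X"] == 1.0 and null.node_sd["X"] == 0.0

    def test_moments_match_scipy_hypergeom(self):
        """Independent oracle: per-node moments equal those of
        scipy.stats.hypergeom(N, m_v, k) scaled by 1/k."""
        g = nx.gnp_random_graph(30, 0.1, seed=3)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        k, n = 7, g.number_of_nodes()
        null = closed_form_null(g, seed_set_size=k)
        for node in g.nodes:
            m = len(nx.single_source_shortest_path_length(g, node, cutoff=2))
            hg = sps.hypergeom(n, m, k)
            assert null.node_mean[node] == pytest.approx(hg.mean() / k)
            assert null.node_sd[node] == pytest.approx(hg.std() / k, abs=1e-12)


class TestSimulateNull:
    def test_deterministic_given_seed(self, path_graph):
        a = simulate_null(path_graph, 2, replicates=50, rng_seed=42)
        b = simulate_null(path_graph, 2, replicates=50, rng_seed=42)
        assert a == b

    def test_different_seeds_differ(self, path_graph):
        a = simulate_null(path_graph, 2, replicates=50, rng_seed=1)
        b = simulate_null(path_graph, 2, replicates=50, rng_seed=2)
        assert a.node_mean != b.node_mean

    def test_complete_graph_exact(self, complete_graph):
        null = simulate_null(complete_graph, 2, replicates=20, rng_seed=0)
        assert all(m == 1.0 for m in null.node_mean.values())
        assert all(s == 0.0 for s in null.node_sd.values())

    def test_every_node_has_an_entry(self, path_graph):
        null = simulate_null(path_graph, 1, replicates=10, rng_seed=0)
        assert set(null.node_mean) == set(path_graph.nodes)

    def test_means_approach_closed_form(self, path_graph):
        sim = simulate_null(path_graph, 1, replicates=4000, rng_seed=5)
        exact = closed_form_null(path_graph, 1)
        for node in path_graph.nodes:
            se = exact.node_sd[node] / np.sqrt(4000)
            assert abs(sim.node_mean[node] - exact.node_mean[node]) <= 4 * se + 1e-12

    def test_oversized_seed_set_fatal(self, path_graph):
        with pytest.raises(ValueError, match="seed_set_size"):
            simulate_null(path_graph, 6)

    def test_zero_replicates_fatal(self, path_graph):
        with pytest.raises(ValueError, match="replicates"):
            simulate_null(path_graph, 2, replicates=0)


def _summary(mean, sd, radius=2, replicates=1000, k=2):
    return NullSummary(
        replicates=replicates,
        seed_set_size=k,
        radius=radius,
        node_mean=mean,
        node_sd=sd,
    )


def _stats(graph, seeds, radius=2):
    return membership_stats(graph, seeds, radius=radius)


class TestConvergenceTable:
    def test_fold_enrichment_and_sd_filter(self, path_graph):
        stats = _stats(path_graph, ["A", "E"])
        mean = {g: 0.20 for g in path_graph.nodes}
        sd = {g: 0.05 for g in path_graph.nodes}
        table = convergence_table(stats, _summary(mean, sd), min_membership=1)
        row = table.set_index("gene").loc["C"]  # observed proportion 1.0
        assert row["fold_enrichment"] == pytest.approx(5.0)
        assert row["passes_sd_filter"] and row["retained"]

    def test_boundary_exactly_at_threshold_passes(self, path_graph):
        # B has proportion 0.5; mean + 3*sd == 0.5 exactly
        stats = _stats(path_graph, ["A", "E"])
        mean = {g: 0.2 for g in path_graph.nodes}
        sd = {g: 0.1 for g in path_graph.nodes}
        table = convergence_table(stats, _summary(mean, sd), min_membership=1)
        assert table.set_index("gene").loc["B", "passes_sd_filter"]

    def test_membership_number_one_excluded(self, path_graph):
        stats = _stats(path_graph, ["A", "E"])
        mean = {g: 0.0 for g in path_graph.nodes}
        sd = {g: 0.0 for g in path_graph.nodes}
        table = convergence_table(stats, _summary(mean, sd)).set_index("gene")
        assert not table.loc["B", "passes_membership_filter"]
        # B and D are not seeds, so they are simply not retained
        assert not table.loc["B", "retained"] and not table.loc["D", "retained"]

    def test_failing_seed_restored_with_flag(self, path_graph):
        stats = _stats(path_graph, ["A", "E"])
        mean = {g: 0.9 for g in path_graph.nodes}
        sd = {g: 1.0 for g in path_graph.nodes}
        table = convergence_table(stats, _summary(mean, sd)).set_index("gene")
        for seed in ("A", "E"):
            assert table.loc[seed, "is_restored_seed"]
            assert table.loc[seed, "retained"]
        assert not table.loc["C", "is_restored_seed"]

    def test_seed_missing_from_graph_restored_with_zeros(self, path_graph):
        seeds = SeedList.from_symbols(["A", "E", "GHOST"], path_graph)
        stats = membership_stats(path_graph, seeds)
        mean = {g: 0.0 for g in path_graph.nodes}
        sd = {g: 0.0 for g in path_graph.nodes}
        table = convergence_table(stats, _summary(mean, sd)).set_index("gene")
        ghost = table.loc["GHOST"]
        assert ghost["is_restored_seed"] and ghost["retained"]
        assert ghost["observed_membership_number"] == 0
        assert ghost["fold_enrichment"] == 0.0

    def test_each_gene_appears_once(self, path_graph):
        stats = _stats(path_graph, ["A", "E"])
        mean = {g: 0.9 for g in path_graph.nodes}
        sd = {g: 1.0 for g in path_graph.nodes}
        table = convergence_table(stats, _summary(mean, sd))
        assert table["gene"].is_unique

    def test_radius_mismatch_fatal(self, path_graph):
        stats = _stats(path_graph, ["A"], radius=2)
        null = closed_form_null(path_graph, 1, radius=1)
        with pytest.raises(ValueError, match="radius"):
            convergence_table(stats, null)

    def test_universe_mismatch_fatal(self, path_graph):
        stats = _stats(path_graph, ["A", "E"])
        null = _summary({"A": 0.1}, {"A": 0.1})
        with pytest.raises(ValueError, match="universe"):
            convergence_table(stats, null)

    @given(st.integers(0, 199))
    def test_filters_monotone_in_thresholds(self, seed):
        """Raising the SD multiplier or the membership floor never
        enlarges the retained set (restored seeds excluded)."""
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(25, 0.12, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        seeds = [f"N{i}" for i in rng.choice(25, size=5, replace=False)]
        stats = membership_stats(g, seeds)
        mean = {n: float(rng.uniform(0, 0.5)) for n in g.nodes}
        sd = {n: float(rng.uniform(0, 0.2)) for n in g.nodes}
        null = _summary(mean, sd, k=5)

        def retained(sd_mult, min_mem):
            t = convergence_table(
                stats, null, sd_multiplier=sd_mult, min_membership=min_mem
            )
            return set(t.loc[t["retained"] & ~t["is_restored_seed"], "gene"])

        base = retained(1.0, 1)
        assert retained(3.0, 1) <= base
        assert retained(1.0, 2) <= base
        assert retained(3.0, 3) <= retained(3.0, 2) <= retained(2.0, 2)


class TestEstimators:
    def test_null_model_closed_form_matches_function(self, path_graph):
        est = NullModel(method="closed_form").fit(path_graph, seed_set_size=2)
        assert est.summary_ == closed_form_null(path_graph, 2)

    def test_null_model_unknown_method(self, path_graph):
        with pytest.raises(ValueError, match="method"):
            NullModel(method="bogus").fit(path_graph, 1)

    def test_analyzer_params_round_trip(self):
        est = ConvergenceAnalyzer(replicates=10, sd_multiplier=2.5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.set_params(min_membership=3)
        assert cloned.min_membership == 3

    def test_analyzer_fit_deterministic(self, path_graph):
        a = ConvergenceAnalyzer(replicates=50, random_state=7).fit(
            path_graph, ["A", "E"]
        )
        b = ConvergenceAnalyzer(replicates=50, random_state=7).fit(
            path_graph, ["A", "E"]
        )
        pd.testing.assert_frame_equal(a.results_, b.results_)
        assert a.retained_ == b.retained_
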
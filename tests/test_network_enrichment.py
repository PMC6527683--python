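import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from prenet import catalog_io, network_enrichment as ne, pre_scoring


def graph_from_edges(edges, extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return g


class TestFilterInteractome:
    def test_induced_subgraph(self):
        ppi = graph_from_edges([("a", "b"), ("b", "c")])
        cell = ne.filter_interactome(ppi, {"a", "b"}, "T")
        assert set(cell.edges) == {("a", "b")}
        assert cell.graph["bucket"] == "T"

    def test_identity_when_all_expressed(self):
        ppi = graph_from_edges([("a", "b"), ("b", "c")])
        cell = ne.filter_interactome(ppi, {"a", "b", "c"}, "B")
        assert set(cell.edges) == set(ppi.edges)

    def test_disjoint_errors(self):
        ppi = graph_from_edges([("a", "b")])
        with pytest.raises(ValueError, match="M"):
            ne.filter_interactome(ppi, {"x"}, "M")


class TestExtractSubnetwork:
    def test_lcc_metrics(self):
        inter = graph_from_edges([("a", "b"), ("b", "c"), ("d", "e")])
        inter.graph["bucket"] = "T"
        _, m = ne.extract_subnetwork(inter, {"a", "b", "c", "d", "e"})
        assert (m.n_nodes, m.n_edges, m.lcc_nodes, m.lcc_edges) == (5, 3, 3, 2)
        assert not m.eligible  # LCC of 3 <= 15 nodes

    def test_isolated_selection_flagged(self):
        inter = graph_from_edges([], extra_nodes=["a", "b"])
        inter.graph["bucket"] = "T"
        _, m = ne.extract_subnetwork(inter, {"a"})
        assert (m.lcc_nodes, m.lcc_edges, m.eligible) == (1, 0, False)

    def test_eligibility_threshold(self):
        # a 17-node path has an LCC of 17 > 15
        inter = nx.path_graph(17)
        inter = nx.relabel_nodes(inter, str)
        inter.graph["bucket"] = "T"
        _, m = ne.extract_subnetwork(inter, set(inter.nodes))
        assert m.eligible

    def test_lcc_matches_exhaustive_enumeration(self):
        """Agree with networkx component enumeration on every 4-node graph
        and on random graphs up to 8 nodes."""
        nodes = list("abcd")
        for edge_set in itertools.chain.from_iterable(
            itertools.combinations(list(itertools.combinations(nodes, 2)), k)
            for k in range(7)
        ):
            g = graph_from_edges(edge_set, extra_nodes=nodes)
            g.graph["bucket"] = "x"
            _, m = ne.extract_subnetwork(g, set(nodes))
            comps = list(nx.connected_components(g))
            best = max(len(c) for c in comps)
            assert m.lcc_nodes == best
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = nx.gnp_random_graph(8, rng.uniform(0.1, 0.6), seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, str)
            g.graph["bucket"] = "x"
            _, m = ne.extract_subnetwork(g, set(g.nodes))
            comps = list(nx.connected_components(g))
            assert m.lcc_nodes == max(len(c) for c in comps)
            sizes = [
                (len(c), g.subgraph(c).number_of_edges()) for c in comps
            ]
            assert (m.lcc_nodes, m.lcc_edges) == max(sizes)


class TestEmpiricalP:
    @pytest.mark.parametrize(
        "observed,null,expected",
        [
            (10, list(range(4)), 1 / 5),        # above all null values
            (0, [1, 2, 3, 4], 1.0),             # below or equal to all
            (3, [1, 2, 3, 4], 0.6),             # (2 ties-or-above + 1) / 5
        ],
    )
    def test_examples(self, observed, null, expected):
        assert ne.empirical_p(observed, null) == pytest.approx(expected)

    def test_never_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            null = rng.integers(0, 10, size=int(rng.integers(1, 30)))
            obs = rng.integers(0, 20)
            p = ne.empirical_p(obs, null)
            assert 1 / (len(null) + 1) <= p <= 1.0


class TestSampleNull:
    def test_full_graph_draws_are_constant(self):
        g = nx.gnp_random_graph(20, 0.3, seed=2)
        g = nx.relabel_nodes(g, str)
        null = ne.sample_null(g, k=20, reps=10, seed=0)
        assert (null["edges"] == g.number_of_edges()).all()
        lcc = max(nx.connected_components(g), key=len)
        assert (null["lcc_nodes"] == len(lcc)).all()

    def test_singleton_draws(self):
        g = nx.path_graph(5)
        g = nx.relabel_nodes(g, str)
        null = ne.sample_null(g, k=1, reps=20, seed=0)
        assert (null["edges"] == 0).all()
        assert (null["lcc_nodes"] == 1).all()
        assert (null["lcc_edges"] == 0).all()

    def test_k_too_large(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            ne.sample_null(g, k=5, reps=1, seed=0)

    def test_er_closed_form_mean(self):
        """Mean induced edges of k-node samples from G(n, p) is close to
        p * C(k, 2): E over both graph and sampling randomness."""
        p, k, reps = 0.05, 50, 2000
        g = nx.gnp_random_graph(200, p, seed=9)
        g = nx.relabel_nodes(g, str)
        null = ne.sample_null(g, k=k, reps=reps, seed=3)
        expected = p * k * (k - 1) / 2
        se = null["edges"].std(ddof=1) / np.sqrt(reps)
        # allow graph-level fluctuation of the realized edge density too
        density_se = np.sqrt(p * (1 - p) * 200 * 199 / 2) * (k * (k - 1)) / (200 * 199)
        assert abs(null["edges"].mean() - expected) < 3 * (se + density_se)

    def test_seed_reproducibility_and_seed_sensitivity(self):
        g = nx.gnp_random_graph(200, 0.05, seed=9)
        g = nx.relabel_nodes(g, str)
        a = ne.sample_null(g, k=50, reps=400, seed=7)
        b = ne.sample_null(g, k=50, reps=400, seed=7)
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])
        c = ne.sample_null(g, k=50, reps=400, seed=8)
        assert not all((a[k] == c[k]).all() for k in a)
        se = a["edges"].std(ddof=1) * np.sqrt(2 / 400)
        assert abs(a["edges"].mean() - c["edges"].mean()) < 3 * se

    def test_degree_matched_sampler_preserves_bins(self):
        g = nx.barabasi_albert_graph(100, 3, seed=4)
        g = nx.relabel_nodes(g, str)
        hubs = sorted(g.nodes, key=g.degree)[-10:]
        null_plain = ne.sample_null(g, k=10, reps=300, seed=0)
        null_matched = ne.sample_null(g, k=10, reps=300, seed=0, degree_reference=hubs)
        # degree-matched draws of hub-like sets carry far more edges
        assert null_matched["edges"].mean() > null_plain["edges"].mean()


class TestEnrichmentTest:
    def test_planted_clique_detected(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(150, 0.03, seed=5)
        g = nx.relabel_nodes(g, lambda i: f"n{i:03d}")
        clique = [f"n{i:03d}" for i in range(12)]
        g.add_edges_from(itertools.combinations(clique, 2))
        g.graph["bucket"] = "T"
        m = ne.enrichment_test(g, set(clique), reps=500, seed=6)
        assert m.p_edges == pytest.approx(1 / 501)

    def test_empty_selection(self):
        g = nx.path_graph(5)
        g = nx.relabel_nodes(g, str)
        g.graph["bucket"] = "T"
        m = ne.enrichment_test(g, set(), reps=10, seed=0)
        assert m.n_nodes == 0 and m.p_edges is None


class TestSensitivityGrid:
    def test_row_count_and_absent_tier(self, sim_data):
        interactomes = {
            b: ne.filter_interactome(sim_data.ppi, set(sim_data.counts.index), b)
            for b in ("T", "B")
        }
        grid = ne.sensitivity_grid(
            {"GW": sim_data.effects_by_tier["GW"], "SR": None, "NR": None},
            sim_data.proxies,
            sim_data.catalogue,
            interactomes,
            reps=50,
            seed=0,
        )
        assert len(grid) == 3 * 3 * 3 * 2
        assert (grid.loc[grid["tier"] != "GW", "status"] == "absent").all()
        assert (grid.loc[grid["tier"] == "GW", "status"] == "ok").all()

    def test_single_cell_matches_direct_run(self, sim_data):
        interactomes = {"T": ne.filter_interactome(sim_data.ppi, set(sim_data.counts.index), "T")}
        grid = ne.sensitivity_grid(
            {"GW": sim_data.effects_by_tier["GW"]},
            sim_data.proxies,
            sim_data.catalogue,
            interactomes,
            tiers=("GW",),
            r2_values=(0.5,),
            q_values=(25,),
            reps=200,
            seed=3,
        )
        assert len(grid) == 1
        totals = pre_scoring.bucket_totals(sim_data.catalogue)
        region_snps = catalog_io.expand_ld(
            sim_data.effects_by_tier["GW"], sim_data.proxies, 0.5
        )
        pre = pre_scoring.compute_pre(region_snps, sim_data.catalogue, totals)
        gene_pre = pre_scoring.aggregate_gene_pre(pre)
        selected = pre_scoring.select_high_pre(gene_pre, "T", 25)
        direct = ne.enrichment_test(interactomes["T"], selected, reps=200, seed=3)
        row = grid.iloc[0]
        assert row["n_edges"] == direct.n_edges
        assert row["p_edges"] == direct.p_edges

    def test_planted_signal_orders_tiers(self, sim_data):
        """GW effects carry the planted signal, NR effects none, so the GW
        connectivity p-value beats the NR one at matched settings."""
        interactomes = {"T": ne.filter_interactome(sim_data.ppi, set(sim_data.counts.index), "T")}
        grid = ne.sensitivity_grid(
            {t: sim_data.effects_by_tier[t] for t in ("GW", "NR")},
            sim_data.proxies,
            sim_data.catalogue,
            interactomes,
            tiers=("GW", "NR"),
            r2_values=(0.5,),
            q_values=(25,),
            reps=500,
            seed=1,
        )
        p = grid.set_index("tier")["p_edges"]
        assert p["GW"] < p["NR"]
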
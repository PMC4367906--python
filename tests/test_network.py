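import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import zipf

from kinomescreen import (
    InteractomeConfig,
    PlantedModule,
    build_network,
    default_fer_crkl_module,
    degree_stats,
    extract_module,
    fit_power_law,
    generate_interactome,
    shared_neighbor_modules,
    summarize_topology,
)
from kinomescreen.exceptions import FitError, ValidationError


def _interactions(rows):
    return pd.DataFrame(rows, columns=["source", "target", "relation"])


@pytest.fixture(scope="module")
def receptor_module_graph():
    """Two hit kinases jointly wired to three receptors, plus a decoy."""
    rows = [
        ("FER", "EGFR", "interacting_phospho"),
        ("FER", "ERBB2", "interacting_phospho"),
        ("FER", "ERBB3", "interacting"),
        ("CRKL", "EGFR", "substrate"),
        ("CRKL", "ERBB2", "interacting_phospho"),
        ("CRKL", "ERBB3", "interacting_phospho"),
        ("CRKL", "IRS1", "interacting"),
        ("AURKB", "INCENP", "interacting"),
    ]
    graph, _ = build_network(["FER", "CRKL", "AURKB"], _interactions(rows))
    return graph


class TestBuildNetwork:
    def test_first_neighbor_rule(self):
        rows = [("A", "B", "interacting"), ("B", "C", "substrate")]
        graph, unmapped = build_network(["A"], _interactions(rows))
        assert set(graph.nodes) == {"A", "B"}
        assert graph.number_of_edges() == 1
        assert unmapped == []

    def test_two_hits_pull_both_edges(self):
        rows = [("A", "B", "interacting"), ("B", "C", "substrate")]
        graph, _ = build_network(["A", "C"], _interactions(rows))
        assert set(graph.nodes) == {"A", "B", "C"}
        assert graph.number_of_edges() == 2

    def test_row_order_invariance(self, rng):
        rows = [
            ("A", "B", "interacting"),
            ("B", "A", "substrate_phospho"),
            ("A", "C", "substrate"),
            ("C", "D", "interacting_phospho"),
        ]
        g1, _ = build_network(["A", "C"], _interactions(rows))
        shuffled = _interactions([rows[i] for i in rng.permutation(len(rows))])
        g2, _ = build_network(["A", "C"], shuffled)
        assert nx.utils.graphs_equal(g1, g2)

    def test_conflicting_relations_keep_most_informative(self):
        rows = [("A", "B", "interacting"), ("B", "A", "substrate_phospho")]
        graph, _ = build_network(["A"], _interactions(rows))
        assert graph.edges["A", "B"]["relation"] == 4
        rows = [("A", "B", "substrate"), ("B", "A", "interacting_phospho")]
        graph, _ = build_network(["A"], _interactions(rows))
        assert graph.edges["A", "B"]["relation"] == 2

    def test_undocumented_hits_reported(self):
        rows = [("A", "B", "interacting")]
        graph, unmapped = build_network(["A", "ORPHAN1", "ORPHAN2"], _interactions(rows))
        assert unmapped == ["ORPHAN1", "ORPHAN2"]
        _, summary = degree_stats(graph)
        assert summary.n_hit_kinases_included + len(unmapped) == 3

    def test_empty_hit_list_rejected(self):
        with pytest.raises(ValidationError):
            build_network([], _interactions([("A", "B", "interacting")]))

    def test_edge_class_conservation(self):
        interactions, _ = generate_interactome(InteractomeConfig(n_proteins=200, seed=4))
        hits = interactions["source"].unique()[:20]
        graph, _ = build_network(hits, interactions)
        per_class = {c: 0 for c in (1, 2, 3, 4)}
        for _, _, data in graph.edges(data=True):
            per_class[data["relation"]] += 1
        assert sum(per_class.values()) == graph.number_of_edges()


class TestDegreeStats:
    def test_star_graph(self):
        graph = nx.star_graph(9)
        hist, summary = degree_stats(graph)
        assert hist == {1: 9, 9: 1}
        assert summary.mean_degree == pytest.approx(1.8)
        assert summary.n_components == 1

    def test_empty_graph(self):
        hist, summary = degree_stats(nx.Graph())
        assert hist == {} and summary.n_nodes == 0 and summary.n_edges == 0

    def test_preferential_attachment_is_heavy_tailed(self):
        graph = nx.barabasi_albert_graph(2000, 2, seed=0)
        degrees = np.array([d for _, d in graph.degree()])
        assert degrees.max() >= 5 * np.median(degrees)


class TestFitPowerLaw:
    def test_recovers_known_discrete_exponent(self):
        degrees = zipf(3.0).rvs(5000, random_state=1)
        fit = fit_power_law(degrees)
        assert 2.8 <= fit.gamma <= 3.2

    def test_preferential_attachment_exponent(self):
        graph = nx.barabasi_albert_graph(2000, 2, seed=3)
        fit = fit_power_law([d for _, d in graph.degree()])
        assert 2.5 <= fit.gamma <= 3.5

    def test_constant_degrees_cannot_be_fit(self):
        with pytest.raises(FitError):
            fit_power_law([4] * 50)

    def test_too_small_tail_rejected(self):
        with pytest.raises(FitError):
            fit_power_law([1, 2, 3, 4, 5])

    def test_diagnostics_reported(self):
        degrees = zipf(2.5).rvs(2000, random_state=0)
        fit = fit_power_law(degrees)
        assert fit.method == "discrete_mle"
        assert fit.gamma_continuous > 1
        assert fit.n_tail >= 10


class TestExtractModule:
    def test_receptor_module_around_seed_pair(self, receptor_module_graph):
        module = extract_module(receptor_module_graph, ["FER", "CRKL"], radius=1)
        assert set(module.nodes) >= {"FER", "CRKL", "EGFR", "ERBB2", "ERBB3"}
        assert "AURKB" not in module

    def test_radius_zero_is_seed_induced_subgraph(self, receptor_module_graph):
        module = extract_module(receptor_module_graph, ["FER", "CRKL"], radius=0)
        assert set(module.nodes) == {"FER", "CRKL"}

    def test_disconnected_seed_kept_as_isolate(self):
        graph = nx.Graph()
        graph.add_edge("A", "B")
        graph.add_node("LONER")
        module = extract_module(graph, ["LONER"], radius=1)
        assert set(module.nodes) == {"LONER"}

    def test_missing_seed_listed(self, receptor_module_graph):
        with pytest.raises(ValidationError, match="GHOST"):
            extract_module(receptor_module_graph, ["FER", "GHOST"])

    def test_all_hits_radius_one_returns_full_network(self, receptor_module_graph):
        module = extract_module(receptor_module_graph, ["FER", "CRKL", "AURKB"], radius=1)
        assert nx.utils.graphs_equal(module, receptor_module_graph)


class TestSharedNeighborModules:
    def test_receptor_module_ranks_first(self, receptor_module_graph):
        ranked = shared_neighbor_modules(receptor_module_graph, min_shared=2)
        (pair, shared) = ranked[0]
        assert pair == ("CRKL", "FER")
        assert shared == ["EGFR", "ERBB2", "ERBB3"]

    def test_no_shared_neighbors_empty(self):
        graph, _ = build_network(
            ["A", "C"], _interactions([("A", "B", "interacting"), ("C", "D", "interacting")])
        )
        assert shared_neighbor_modules(graph) == []

    def test_min_shared_one_on_wedge(self):
        graph, _ = build_network(
            ["A", "B"], _interactions([("A", "C", "interacting"), ("B", "C", "interacting")])
        )
        assert shared_neighbor_modules(graph, min_shared=1) == [(("A", "B"), ["C"])]

    def test_planted_module_recovered_from_generator(self):
        module = default_fer_crkl_module()
        for seed in (0, 1, 2):
            interactions, truth = generate_interactome(
                InteractomeConfig(n_proteins=500, planted_modules=(module,), seed=seed)
            )
            rng = np.random.default_rng(seed)
            backbone = [n for n in truth["names"].values() if n.startswith("P")]
            hits = list(module.seeds) + list(rng.choice(backbone, 30, replace=False))
            graph, _ = build_network(hits, interactions)
            ranked = shared_neighbor_modules(graph, min_shared=2)
            found = {pair: shared for pair, shared in ranked}
            assert ("CRKL", "FER") in found
            assert set(found[("CRKL", "FER")]) >= set(module.partners)


class TestTopologySummary:
    def test_gamma_filled_when_fittable(self):
        interactions, _ = generate_interactome(InteractomeConfig(n_proteins=1000, seed=9))
        hits = pd.unique(interactions[["source", "target"]].to_numpy().ravel())[:80]
        graph, _ = build_network(hits, interactions)
        summary = summarize_topology(graph)
        assert summary.power_law_gamma is not None
        assert summary.mean_degree == pytest.approx(
            2 * summary.n_edges / summary.n_nodes
        )
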
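import itertools

import networkx as nx
import numpy as np
import pytest

from omicpaths.errors import ConfigurationError, UndefinedTestError, ValidationError
from omicpaths.graph import build_metabolic_graph
from omicpaths.hubs import (
    gene_neighborhood,
    hub_binomial_test,
    network_percentile,
    run_hub_analysis,
)
from omicpaths.model import (
    FeatureKind,
    MetabolicGraph,
    NodeKind,
    Pathway,
    PathwayDatabase,
    PathwayNode,
)
from omicpaths.simulate import FixtureSpec, PlantedEffect, generate
from tests.conftest import make_dataset


def _graph_from_edges(edges, kinds, measured=(), significant=()):
    g = MetabolicGraph()
    for node, kind in kinds.items():
        g.add_node(node, kind)
        g.g.nodes[node]["measured"] = node in measured
        g.g.nodes[node]["significant"] = node in significant
    for a, b in edges:
        g.add_edge(a, b)
    return g


@pytest.fixture
def chain_graph():
    # A(cpd) - g1 - B(cpd) - g2
    kinds = {
        "A": NodeKind.COMPOUND,
        "g1": NodeKind.GENE,
        "B": NodeKind.COMPOUND,
        "g2": NodeKind.GENE,
    }
    return _graph_from_edges(
        [("A", "g1"), ("g1", "B"), ("B", "g2")],
        kinds,
        measured={"g1", "g2"},
        significant={"g1"},
    )


class TestNeighborhood:
    def test_step1_direct_edge(self, chain_graph):
        assert gene_neighborhood(chain_graph, "A", 1).genes == {"g1"}

    def test_step3_through_two_intermediates(self, chain_graph):
        assert gene_neighborhood(chain_graph, "A", 3).genes == {"g1", "g2"}

    def test_isolated_compound_empty_at_every_step(self):
        g = _graph_from_edges([], {"X": NodeKind.COMPOUND})
        for step in range(1, 5):
            assert gene_neighborhood(g, "X", step).genes == frozenset()

    def test_non_compound_rejected(self, chain_graph):
        with pytest.raises(ValidationError):
            gene_neighborhood(chain_graph, "g1", 1)
        with pytest.raises(ValidationError):
            gene_neighborhood(chain_graph, "nope", 1)
        with pytest.raises(ValidationError):
            gene_neighborhood(chain_graph, "A", 5)

    def test_bfs_equals_brute_force_path_enumeration(self):
        """On small random graphs the BFS neighborhood equals the set of gene
        nodes reachable by some simple path of length <= step."""
        rng = np.random.default_rng(123)
        for trial in range(100):
            n = int(rng.integers(4, 26))
            kinds = {
                f"n{i}": (NodeKind.COMPOUND if rng.random() < 0.4 else NodeKind.GENE)
                for i in range(n)
            }
            nodes = list(kinds)
            edges = [
                (a, b)
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.15
            ]
            g = _graph_from_edges(edges, kinds)
            compounds = [x for x in nodes if kinds[x] == NodeKind.COMPOUND]
            if not compounds:
                continue
            cpd = compounds[int(rng.integers(len(compounds)))]
            step = int(rng.integers(1, 5))
            brute = set()
            for target in nodes:
                if kinds[target] != NodeKind.GENE or target == cpd:
                    continue
                if nx.has_path(g.g, cpd, target) and any(
                    len(path) - 1 <= step
                    for path in nx.all_simple_paths(g.g, cpd, target, cutoff=step)
                ):
                    brute.add(target)
            assert gene_neighborhood(g, cpd, step).genes == brute

    def test_nesting_across_steps(self):
        for seed in range(100):
            bundle = generate(FixtureSpec(seed=700 + seed, n_pathways=8))
            g = build_metabolic_graph(bundle.db, bundle.datasets)
            for cpd in g.compound_ids()[:10]:
                sets = [gene_neighborhood(g, cpd, s).genes for s in (1, 2, 3, 4)]
                assert sets[0] <= sets[1] <= sets[2] <= sets[3]


class TestHubBinomial:
    def test_zero_degs_gives_one(self):
        assert hub_binomial_test(0, 12, 0.25) == 1.0

    def test_three_of_three_at_half(self):
        assert hub_binomial_test(3, 3, 0.5) == pytest.approx(0.125)

    def test_undefined_without_measured_genes(self):
        with pytest.raises(UndefinedTestError):
            hub_binomial_test(0, 0, 0.25)


class TestNetworkPercentile:
    def _five_compound_graph(self):
        # five compounds, ten genes; compound ci has i significant of 2 measured
        kinds = {}
        edges = []
        measured, significant = set(), set()
        props = {}
        # construct proportions 0.0, 0.25, 0.5, 0.75, 1.0 using 4 genes each
        for i in range(5):
            cpd = f"c{i}"
            kinds[cpd] = NodeKind.COMPOUND
            for j in range(4):
                gene = f"g{i}{j}"
                kinds[gene] = NodeKind.GENE
                edges.append((cpd, gene))
                measured.add(gene)
                if j < i:
                    significant.add(gene)
            props[cpd] = i / 4
        return _graph_from_edges(edges, kinds, measured, significant), significant, props

    def test_distinct_proportions_midrank(self):
        g, sig, props = self._five_compound_graph()
        assert network_percentile(g, sig, "c4", 1) == pytest.approx(90.0)
        assert network_percentile(g, sig, "c0", 1) == pytest.approx(10.0)

    def test_full_tie_gives_fifty(self):
        kinds, edges, measured = {}, [], set()
        for i in range(4):
            kinds[f"c{i}"] = NodeKind.COMPOUND
            kinds[f"g{i}"] = NodeKind.GENE
            edges.append((f"c{i}", f"g{i}"))
            measured.add(f"g{i}")
        g = _graph_from_edges(edges, kinds, measured)
        for i in range(4):
            assert network_percentile(g, set(), f"c{i}", 1) == pytest.approx(50.0)

    def test_undefined_without_measured_neighbors(self):
        g = _graph_from_edges(
            [("c0", "g0"), ("c1", "g1")],
            {
                "c0": NodeKind.COMPOUND,
                "c1": NodeKind.COMPOUND,
                "g0": NodeKind.GENE,
                "g1": NodeKind.GENE,
            },
            measured={"g0"},
        )
        with pytest.raises(UndefinedTestError):
            network_percentile(g, set(), "c1", 1)


class TestRunHubAnalysis:
    def test_p0_recorded_and_single_metabolite_adjustment(self, chain_db):
        expr = make_dataset(
            "transcriptomics",
            {f"g{i}": [0.0, 1.0] for i in range(1, 5)},
            significant={"g1"},
        )
        mets = make_dataset(
            "metabolomics",
            {"A": [0, 1]},
            significant={"A"},
            kind=FeatureKind.COMPOUND,
        )
        g = build_metabolic_graph(chain_db, [expr, mets])
        results = run_hub_analysis(g, expr, mets, step=1)
        assert len(results) == 1
        r = results[0]
        assert r.p0 == pytest.approx(0.25)
        assert r.adjusted_p == pytest.approx(r.binomial_p)

    def test_requires_informative_expression_layer(self, chain_db):
        expr = make_dataset("transcriptomics", {"g1": [0, 1]}, significant={"g1"})
        mets = make_dataset(
            "metabolomics", {"A": [0, 1]}, significant={"A"}, kind=FeatureKind.COMPOUND
        )
        g = build_metabolic_graph(chain_db, [expr, mets])
        with pytest.raises(ConfigurationError):
            run_hub_analysis(g, expr, mets, step=1)  # p0 = 1

    def test_planted_hub_ranked_first(self):
        bundle = generate(
            FixtureSpec(seed=77, n_pathways=20, planted=[PlantedEffect("hub", strength=0.6)])
        )
        g = build_metabolic_graph(bundle.db, bundle.datasets)
        results = run_hub_analysis(
            g, bundle.expression, bundle.metabolites, step=1, scope="significant"
        )
        planted = bundle.truth["planted"]["hub"]["compound"]
        assert results[0].metabolite == planted
        # small neighborhoods can reach proportion 1.0 by chance, so the
        # planted hub need not top the percentile scale — but it sits high
        assert results[0].percentile >= 90.0

    def test_scope_all_tests_every_measured_compound(self):
        bundle = generate(FixtureSpec(seed=13, n_pathways=6))
        g = build_metabolic_graph(bundle.db, bundle.datasets)
        res_all = run_hub_analysis(g, bundle.expression, bundle.metabolites, 1, "all")
        res_sig = run_hub_analysis(g, bundle.expression, bundle.metabolites, 1)
        assert len(res_all) >= len(res_sig)
        assert {r.metabolite for r in res_sig} <= {r.metabolite for r in res_all}
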
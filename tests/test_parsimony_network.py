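import networkx as nx
import numpy as np
import pytest

from haplogeo.io_model import CodedMatrix, FormatError
from haplogeo.haplotyping import code_indels, pairwise_step_distances
from haplogeo.io_model import AlignedSequenceSet
from haplogeo.parsimony_network import (
    AmbiguityError,
    HaplotypeNetwork,
    build_network,
    lineage_bipartition,
    parsimony_connection_limit,
    parsimony_probability,
    population_lineages,
    resolve_loops,
)
from haplogeo.synthetic_data import SimulationConfig, simulate_phylogeography

from oracles import mc_parsimony_probability


def matrix_from_rows(rows, n_chars=None):
    n = len(rows[0])
    cols = code_indels(
        AlignedSequenceSet((("ref", "A" * n),), (("seg", 1, n),))
    ).columns
    return CodedMatrix(
        [f"h{k}" for k in range(len(rows))],
        cols,
        np.array([list(r) for r in rows], dtype=object),
        total_sites=n_chars or n,
    )


class TestConnectionLimit:
    def test_reference_length(self):
        limit = parsimony_connection_limit(1381, alpha=0.05)
        assert limit >= 11
        assert limit == 12  # birthday-product model at 95% confidence

    def test_confidence_near_one_only_single_steps(self):
        # As alpha -> 1 only the always-parsimonious single-step connections
        # meet the confidence level (P_2 = 1 - 1/1381 = 0.99928).
        assert parsimony_connection_limit(1381, alpha=0.9999) == 1
        assert parsimony_connection_limit(1381, alpha=0.999) == 2

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            parsimony_connection_limit(100, alpha=0.0)
        with pytest.raises(ValueError):
            parsimony_connection_limit(100, alpha=1.0)

    def test_probability_monotone_decreasing(self):
        probs = [parsimony_probability(j, 200) for j in range(1, 30)]
        assert probs[0] == 1.0
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_small_n_matches_monte_carlo_oracle(self, rng):
        n_sites = 60
        limit = parsimony_connection_limit(n_sites, alpha=0.05)
        n_draws = 40000
        for j in (limit, limit + 1):
            exact = parsimony_probability(j, n_sites)
            mc = mc_parsimony_probability(j, n_sites, n_draws, rng)
            se = np.sqrt(exact * (1 - exact) / n_draws)
            assert abs(mc - exact) < 4 * se + 1e-9
        assert parsimony_probability(limit, n_sites) >= 0.95
        assert parsimony_probability(limit + 1, n_sites) < 0.95


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self):
        m = matrix_from_rows(["ACGT", "ACGA"])
        net = build_network(m, limit=5)
        assert net.graph.number_of_edges() == 1
        assert net.graph.edges["h0", "h1"]["steps"] == 1

    def test_limit_severs_network(self):
        m = matrix_from_rows(["AAAA", "TTTT"])
        net = build_network(m, limit=2)
        assert net.graph.number_of_edges() == 0
        assert net.components_after == 2

    def test_empty_matrix_rejected(self, table2):
        with pytest.raises(FormatError):
            build_network(table2.subset_rows([]))

    def test_resolved_weight_equals_mst_oracle(self, rng):
        for _ in range(20):
            rows = set()
            while len(rows) < 6:
                rows.add("".join(rng.choice(list("ACGT"), size=10)))
            m = matrix_from_rows(sorted(rows))
            net = resolve_loops(build_network(m, limit=10))
            got = sum(d["steps"] for _, _, d in net.graph.edges(data=True))
            dm = pairwise_step_distances(m)
            g = nx.Graph()
            for i, a in enumerate(dm.labels):
                for j in range(i + 1, len(dm.labels)):
                    g.add_edge(a, dm.labels[j], weight=dm.values[i, j])
            expected = sum(
                d["weight"] for _, _, d in nx.minimum_spanning_tree(g).edges(data=True)
            )
            assert got == expected

    def test_fixture_structure(self, table1, table2):
        net = build_network(table2, populations=table1)
        north = {f"H{i}" for i in range(1, 7)}
        south = {f"H{i}" for i in range(7, 17)}
        inter = [
            (u, v, d["steps"])
            for u, v, d in net.graph.edges(data=True)
            if (u in north) != (v in north)
        ]
        assert inter and all(s == 12 for _, _, s in inter)
        # Every within-lineage edge is much shorter than the split.
        intra = [
            d["steps"] for u, v, d in net.graph.edges(data=True)
            if (u in north) == (v in north)
        ]
        assert max(intra) <= 3
        # Minimal inter-lineage graph distance in steps.
        dist = nx.shortest_path_length(net.graph, "H1", "H7", weight="steps")
        assert 11 <= dist <= 12
        assert net.graph.nodes["H1"]["frequency"] == 392


class TestResolveLoops:
    def test_acyclic_input_unchanged(self):
        m = matrix_from_rows(["ACGT", "ACGA", "ACTA"])
        net = build_network(m, limit=5)
        resolved = resolve_loops(net)
        assert resolved.loops == []
        assert sorted(resolved.graph.edges) == sorted(net.graph.edges)

    def test_square_loop_keeps_high_frequency_node_edges(self):
        # 4-cycle of equal-weight edges; h0 is the high-frequency node.
        g = nx.Graph()
        freqs = {"h0": 50, "h1": 1, "h2": 1, "h3": 1}
        for n, f in freqs.items():
            g.add_node(n, frequency=f, regions=())
        for u, v in [("h0", "h1"), ("h1", "h2"), ("h2", "h3"), ("h3", "h0")]:
            g.add_edge(u, v, steps=2)
        net = HaplotypeNetwork(g, connection_limit=5, components_before=4, components_after=1)
        resolved = resolve_loops(net)
        assert nx.is_forest(resolved.graph)
        removed = resolved.loops[0].removed
        assert "h0" not in removed  # rule (1): keep edges at the frequent node
        assert resolved.loops[0].criterion == "frequency"

    def test_fixture_loop_resolution(self, table1, table2):
        net = build_network(table2, populations=table1)
        assert nx.cycle_basis(net.graph)  # tied 12-step alternatives form loops
        resolved = resolve_loops(net, table1)
        assert nx.is_forest(resolved.graph)
        involved = set()
        for loop in resolved.loops:
            involved |= set(loop.cycle)
        assert {"H1", "H5", "H7", "H11"} <= involved
        # Trees: each component has nodes - 1 edges.
        for comp in nx.connected_components(resolved.graph):
            sub = resolved.graph.subgraph(comp)
            assert sub.number_of_edges() == len(comp) - 1


class TestLineageBipartition:
    def test_fixture_bipartition(self, table1, table2):
        net = resolve_loops(build_network(table2, populations=table1), table1)
        scheme = lineage_bipartition(net)
        groups = {frozenset(scheme.members(g)) for g in scheme.groups()}
        assert frozenset(f"H{i}" for i in range(1, 7)) in groups
        assert frozenset(f"H{i}" for i in range(7, 17)) in groups

    def test_star_network_is_ambiguous(self):
        m = matrix_from_rows(["AAAA", "TAAA", "ATAA", "AATA"])
        net = build_network(m, limit=5)
        with pytest.raises(AmbiguityError):
            lineage_bipartition(resolve_loops(net))

    def test_synthetic_split_recovered(self):
        cfg = SimulationConfig(split_steps=9, seed=42, n_sites=1381)
        table, matrix, truth = simulate_phylogeography(cfg)
        net = resolve_loops(build_network(matrix, populations=table), table)
        scheme = lineage_bipartition(net)
        groups = {frozenset(scheme.members(g)) for g in scheme.groups()}
        planted = {
            frozenset(h for h, l in truth.bipartition.items() if l == "north"),
            frozenset(h for h, l in truth.bipartition.items() if l == "south"),
        }
        assert groups == planted

    def test_input_order_invariance(self, table1, table2):
        perm = np.random.default_rng(3).permutation(table2.n_rows)
        shuffled = CodedMatrix(
            [table2.haplotype_ids[i] for i in perm],
            table2.columns,
            table2.states[perm],
            total_sites=table2.total_sites,
        )
        a = lineage_bipartition(resolve_loops(build_network(table2, populations=table1), table1))
        b = lineage_bipartition(resolve_loops(build_network(shuffled, populations=table1), table1))
        ga = {frozenset(a.members(g)) for g in a.groups()}
        gb = {frozenset(b.members(g)) for g in b.groups()}
        assert ga == gb

    def test_population_lineage_propagation(self, table1, table2):
        net = resolve_loops(build_network(table2, populations=table1), table1)
        pops = population_lineages(lineage_bipartition(net), table1)
        sizes = sorted(len(pops.members(g)) for g in pops.groups())
        assert sizes == [16, 31]
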
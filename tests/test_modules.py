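import io

import networkx as nx
import numpy as np
import pytest

from netge import (
    EmptySeedError,
    FixtureSpec,
    PlantedModule,
    build_all_modules,
    build_seed_set,
    extract_shortest_path_network,
    generate_fixture,
    minimize_network,
    modules_to_json,
    quality_filter,
    rank_connecting_nodes,
)
from netge.modules import SeedSet, similarity_ttest
from netge.network import InteractionNetwork
from netge.ontology import load_annotations

from oracles import spn_by_path_enumeration


def _seed_set(term, in_network, isolated=()):
    return SeedSet(term=term, in_network=frozenset(in_network), isolated=frozenset(isolated))


class TestBuildSeedSet:
    def test_partitions_by_network_presence(self, chain_corpus, diamond_net):
        net = InteractionNetwork.from_edges([("p0", "p9")])
        ss = build_seed_set("GO:0000003", chain_corpus, net)
        assert ss.in_network == {"p0"}
        assert ss.isolated == {"p1"}

    def test_uses_direct_not_propagated(self, chain_corpus):
        net = InteractionNetwork.from_edges([("p0", "p2")])
        # GO:0000002 annotates p2..p4 directly; p0, p1 only via propagation
        ss = build_seed_set("GO:0000002", chain_corpus, net)
        assert ss.seeds == {"p2", "p3", "p4"}

    def test_term_without_direct_annotation_errors(self, chain_dag):
        corpus = load_annotations(io.StringIO("p1\tGO:0000003\n"), chain_dag)
        net = InteractionNetwork.from_edges([("p1", "x")])
        with pytest.raises(EmptySeedError):
            build_seed_set("GO:0000002", corpus, net)


class TestShortestPathNetwork:
    def test_longer_detour_excluded(self, detour_net):
        spn = extract_shortest_path_network(detour_net, _seed_set("T", ["s", "t"]))
        assert set(spn.graph.nodes) == {"s", "t", "u", "v"}
        assert spn.connecting_nodes == {"u", "v"}

    def test_single_seed_is_alone(self, detour_net):
        spn = extract_shortest_path_network(detour_net, _seed_set("T", ["s"]))
        assert set(spn.graph.nodes) == {"s"}

    def test_adjacent_seeds_direct_edge_only(self):
        net = InteractionNetwork.from_edges([("s", "t"), ("s", "u"), ("u", "t")])
        spn = extract_shortest_path_network(net, _seed_set("T", ["s", "t"]))
        assert set(spn.graph.nodes) == {"s", "t"}
        assert set(map(frozenset, spn.graph.edges)) == {frozenset({"s", "t"})}

    def test_isolated_seed_carried_as_degree_zero(self, diamond_net):
        spn = extract_shortest_path_network(
            diamond_net, _seed_set("T", ["s", "t"], isolated=["p9"])
        )
        assert "p9" in spn.graph
        assert spn.graph.degree("p9") == 0

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        from oracles import random_connected_graph

        for _ in range(50):
            g = random_connected_graph(rng)
            net = InteractionNetwork(g)
            nodes = sorted(g.nodes)
            n_seeds = int(rng.integers(2, min(4, len(nodes)) + 1))
            seeds = [nodes[i] for i in rng.choice(len(nodes), n_seeds, replace=False)]
            spn = extract_shortest_path_network(net, _seed_set("T", seeds))
            nodes_expected, edges_expected = spn_by_path_enumeration(g, seeds)
            assert set(spn.graph.nodes) == nodes_expected
            assert set(map(frozenset, spn.graph.edges)) == edges_expected


class TestRanking:
    def _rank(self, net, seeds, corpus, term="GO:0000001"):
        ss = _seed_set(term, seeds)
        spn = extract_shortest_path_network(net, ss)
        return spn, rank_connecting_nodes(spn, ss, term, corpus, net)

    def test_single_path_node(self, chain_corpus):
        net = InteractionNetwork.from_edges([("s", "v"), ("v", "t")])
        _, ranking = self._rank(net, ["s", "t"], chain_corpus)
        (r,) = ranking
        assert (r.node, r.sc, r.bc) == ("v", 1, 1.0)

    def test_star_hub_counts_all_pairs(self, chain_corpus):
        net = InteractionNetwork.from_edges([("h", "s1"), ("h", "s2"), ("h", "s3")])
        _, ranking = self._rank(net, ["s1", "s2", "s3"], chain_corpus)
        (r,) = ranking
        assert (r.node, r.sc, r.bc) == ("h", 3, 3.0)

    def test_split_betweenness_on_diamond(self, diamond_net, chain_corpus):
        _, ranking = self._rank(diamond_net, ["s", "t"], chain_corpus)
        assert {r.node for r in ranking} == {"u", "v"}
        for r in ranking:
            assert r.sc == 1
            assert r.bc == pytest.approx(0.5)

    def test_every_connecting_node_scores_positive(self):
        rng = np.random.default_rng(3)
        from oracles import random_connected_graph

        for _ in range(20):
            g = random_connected_graph(rng)
            net = InteractionNetwork(g)
            nodes = sorted(g.nodes)
            seeds = nodes[:3]
            spn, ranking = (
                extract_shortest_path_network(net, _seed_set("T", seeds)),
                None,
            )
            from netge.ontology import AnnotationCorpus, OntologyDag

            dag = OntologyDag({"T": set()})
            corpus = AnnotationCorpus({"pX": {"T"}}, dag)
            ranking = rank_connecting_nodes(spn, _seed_set("T", seeds), "T", corpus, net)
            for r in ranking:
                assert r.sc >= 1
                assert r.bc > 0


class TestMinimize:
    def _minimize(self, net, seeds, corpus, term="GO:0000001"):
        ss = _seed_set(term, seeds)
        spn = extract_shortest_path_network(net, ss)
        ranking = rank_connecting_nodes(spn, ss, term, corpus, net)
        return minimize_network(spn, ranking)

    def test_diamond_tie_break_removes_smaller_id(self, diamond_net, chain_corpus):
        module = self._minimize(diamond_net, ["s", "t"], chain_corpus)
        # u and v tie on (sc, ss, bc); u is processed first and removed
        assert module.connecting_nodes == {"v"}
        assert nx.shortest_path_length(module.graph, "s", "t") == 2

    def test_no_connecting_nodes_is_noop(self):
        net = InteractionNetwork.from_edges([("s", "t")])
        ss = _seed_set("T", ["s", "t"])
        spn = extract_shortest_path_network(net, ss)
        module = minimize_network(spn, [])
        assert set(module.graph.nodes) == {"s", "t"}

    def test_unique_path_fully_retained(self, chain_corpus):
        net = InteractionNetwork.from_edges([("s", "a"), ("a", "b"), ("b", "t")])
        module = self._minimize(net, ["s", "t"], chain_corpus)
        assert set(module.graph.nodes) == {"s", "a", "b", "t"}


class TestQualityFilter:
    def test_zero_connecting_nodes_rejected(self, chain_corpus):
        net = InteractionNetwork.from_edges([("s", "t")])
        ss = _seed_set("GO:0000003", ["s", "t"])
        module = minimize_network(extract_shortest_path_network(net, ss), [])
        q = quality_filter(module, "GO:0000003", chain_corpus, net)
        assert not q.accepted
        assert q.reason == "no_connecting_nodes"

    def test_single_connecting_node_rejected(self, chain_corpus):
        net = InteractionNetwork.from_edges([("s", "v"), ("v", "t")])
        ss = _seed_set("GO:0000003", ["s", "t"])
        spn = extract_shortest_path_network(net, ss)
        ranking = rank_connecting_nodes(spn, ss, "GO:0000003", chain_corpus, net)
        module = minimize_network(spn, ranking)
        q = quality_filter(module, "GO:0000003", chain_corpus, net)
        assert not q.accepted
        assert q.reason == "single_connecting_node"

    def test_related_connectors_accepted(self):
        # connecting nodes all maximally similar, background near zero
        conn = np.ones(5)
        network = np.concatenate([np.zeros(95), np.full(5, 0.1)])
        accepted, p = similarity_ttest(conn, network)
        assert accepted
        assert p < 1e-6

    def test_null_distribution_rarely_accepted(self):
        # type-I control of the module quality test itself
        rng = np.random.default_rng(2024)
        n_accept = 0
        reps = 200
        for _ in range(reps):
            pool = rng.beta(0.5, 4.0, size=300)
            conn = pool[rng.choice(300, 30, replace=False)]
            accepted, _ = similarity_ttest(conn, pool)
            n_accept += accepted
        assert n_accept <= 0.10 * reps


class TestBuildAllModules:
    def test_planted_fixture_recovers_planted_terms(self):
        spec = FixtureSpec(seed=5, planted=(PlantedModule(),), noise_rate=0.0)
        fx = generate_fixture(spec)
        modules, report = build_all_modules(fx.net, fx.corpus)
        (term,) = fx.truth.planted_terms
        assert term in modules
        # nothing outside the planted branch is accepted with zero noise
        related = set(fx.truth.related_terms.values())
        assert set(modules) <= {term} | related
        assert fx.truth.members[term] <= modules[term].members

    def test_report_covers_every_attempted_term(self):
        fx = generate_fixture(FixtureSpec(seed=6))
        modules, report = build_all_modules(fx.net, fx.corpus)
        assert {r.term for r in report.records} == set(fx.corpus.per_term_direct)
        assert sum(report.counts().values()) == len(report.records)

    def test_serialization_deterministic(self):
        fx = generate_fixture(FixtureSpec(seed=7))
        m1, _ = build_all_modules(fx.net, fx.corpus)
        m2, _ = build_all_modules(fx.net, fx.corpus)
        assert modules_to_json(m1) == modules_to_json(m2)

    def test_roundtrip_through_json(self):
        from netge import modules_from_json

        fx = generate_fixture(FixtureSpec(seed=8))
        m1, _ = build_all_modules(fx.net, fx.corpus)
        m2 = modules_from_json(modules_to_json(m1))
        assert set(m1) == set(m2)
        for t in m1:
            assert m1[t].members == m2[t].members
            assert set(map(frozenset, m1[t].graph.edges)) == set(
                map(frozenset, m2[t].graph.edges)
            )


class TestModuleInvariants:
    def test_distance_preservation_and_one_minimality(self):
        fx = generate_fixture(FixtureSpec(seed=9))
        modules, _ = build_all_modules(fx.net, fx.corpus)
        assert modules
        for term, module in modules.items():
            seeds = sorted(module.seed_set.in_network)
            for i, s in enumerate(seeds):
                d_full = nx.single_source_shortest_path_length(fx.net.graph, s)
                d_mod = nx.single_source_shortest_path_length(module.graph, s)
                for t in seeds[i + 1 :]:
                    if t in d_full:
                        assert d_mod.get(t) == d_full[t]
            # 1-minimality: removing any connecting node breaks a distance
            for v in module.connecting_nodes:
                reduced = module.graph.copy()
                reduced.remove_node(v)
                broken = False
                for i, s in enumerate(seeds):
                    d_full = nx.single_source_shortest_path_length(fx.net.graph, s)
                    d_red = nx.single_source_shortest_path_length(reduced, s)
                    for t in seeds[i + 1 :]:
                        if t in d_full and d_red.get(t) != d_full[t]:
                            broken = True
                assert broken, f"{v} removable from module of {term}"

    def test_module_within_spn_within_network(self):
        fx = generate_fixture(FixtureSpec(seed=10))
        for term in fx.truth.planted_terms:
            ss = build_seed_set(term, fx.corpus, fx.net)
            spn = extract_shortest_path_network(fx.net, ss)
            ranking = rank_connecting_nodes(spn, ss, term, fx.corpus, fx.net)
            module = minimize_network(spn, ranking)
            assert set(module.graph.nodes) <= set(spn.graph.nodes)
            assert set(spn.graph.nodes) - ss.isolated <= fx.net.nodes
            # monotone reduction of the size inflation factor
            n_seed = max(1, len(ss.seeds))
            assert (
                module.graph.number_of_nodes() / n_seed
                <= spn.graph.number_of_nodes() / n_seed
            )
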
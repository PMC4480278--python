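"""Function-specific module extraction.

For each ontology term, the proteins directly annotated with it form a
*seed set*.  The seed set is grown into the *shortest path network*
(SPN): the union of all shortest paths between every pair of seeds in
the interaction network.  The SPN is then reduced to a *minimal
connecting network* by greedily deleting connecting nodes — least
important first — whenever deletion does not increase the shortest
distance between any seed pair.  Finding the true smallest
distance-preserving subgraph is Steiner-tree-like and NP-hard; the
greedy pass yields a 1-minimal (no single node removable) subgraph that
preserves all seed-pair distances.

Connecting nodes are ordered by the lexicographic triple

* ``sc`` — seed centrality: number of distinct seed pairs the node lies
  on a shortest path between;
* ``ss`` — maximum Lin semantic similarity of the node's annotations to
  the reference term;
* ``bc`` — betweenness restricted to seed pairs (fraction of seed-pair
  shortest paths passing through the node, summed over pairs);

all ascending, so the least functionally and topologically relevant
nodes are tried for removal first.  Scores and the distance-preservation
check both use the *full* network's distances, cached once per term:
preservation is defined relative to the original interactome, not to the
shrinking intermediate subgraph.

A built module is accepted only if (a) it has at least two connecting
nodes and (b) a one-sided Welch t-test finds the connecting nodes' mean
semantic similarity to the reference term significantly higher than the
mean over all network nodes.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .network import InteractionNetwork
from .ontology import AnnotationCorpus

log = logging.getLogger(__name__)

__version_tag__ = "netge-modules-1"


class EmptySeedError(ValueError):
    """Raised when a term has no directly annotated protein."""


@dataclass(frozen=True)
class SeedSet:
    """Directly annotated proteins for a reference term, split by network presence."""

    term: str
    in_network: frozenset[str]
    isolated: frozenset[str]

    @property
    def seeds(self) -> frozenset[str]:
        return self.in_network | self.isolated


@dataclass
class ShortestPathNetwork:
    """Union of all seed-pair shortest paths, plus cached full-network distances.

    ``graph`` contains the seed nodes, the connecting nodes and only the
    edges lying on some seed-pair shortest path (not the induced
    subgraph).  ``seed_distances`` maps each in-network seed to its BFS
    distance dictionary over the *full* network; ``pair_distances`` holds
    the original distance for every connected seed pair.
    """

    term: str
    graph: nx.Graph
    seed_set: SeedSet
    connecting_nodes: frozenset[str]
    seed_distances: dict[str, dict[str, int]]
    pair_distances: dict[tuple[str, str], int]


@dataclass(frozen=True, order=True)
class NodeRank:
    """Removal-order key for a connecting node: ascending (sc, ss, bc, id)."""

    sc: int
    ss: float
    bc: float
    node: str


@dataclass
class QualityResult:
    accepted: bool
    reason: str
    p_value: float | None = None
    mean_connecting_ss: float | None = None
    mean_network_ss: float | None = None


@dataclass
class FunctionModule:
    """Minimal connecting network for one reference term."""

    term: str
    seed_set: SeedSet
    connecting_nodes: frozenset[str]
    graph: nx.Graph
    quality: QualityResult | None = None

    @property
    def members(self) -> frozenset[str]:
        """Seeds (including isolated ones) plus retained connecting nodes."""
        return self.seed_set.seeds | self.connecting_nodes


def build_seed_set(
    term: str,
    corpus: AnnotationCorpus,
    net: InteractionNetwork,
    idmap: dict[str, str] | None = None,
) -> SeedSet:
    """Collect the proteins *directly* annotated with *term*.

    If *idmap* (network id -> annotation id) is given, the network is
    relabeled into annotation space before membership is checked.
    """
    term = corpus.dag.resolve(term)
    seeds = corpus.per_term_direct.get(term, frozenset())
    if not seeds:
        raise EmptySeedError(f"term {term} has no directly annotated protein")
    if idmap is not None:
        net = net.relabeled(idmap)
    in_net = frozenset(s for s in seeds if s in net)
    return SeedSet(term=term, in_network=in_net, isolated=seeds - in_net)


def extract_shortest_path_network(
    net: InteractionNetwork, seeds: SeedSet
) -> ShortestPathNetwork:
    """Build the union of all shortest paths between in-network seed pairs.

    A non-seed node v belongs to the SPN iff some seed pair (s, t)
    satisfies d(s,v) + d(v,t) = d(s,t); an edge (u, v) belongs iff it
    lies on such a path, i.e. d(s,u) + 1 + d(v,t) = d(s,t) in either
    orientation.  Isolated seeds are carried over as degree-0 nodes.
    """
    in_net = sorted(seeds.in_network)
    if not in_net:
        raise ValueError("shortest path network needs at least one in-network seed")
    dist = {s: net.distances_from(s) for s in in_net}

    pair_distances: dict[tuple[str, str], int] = {}
    for s, t in itertools.combinations(in_net, 2):
        d = dist[s].get(t)
        if d is not None:
            pair_distances[(s, t)] = d

    nodes: set[str] = set(seeds.seeds)
    for v in net.nodes:
        if v in nodes:
            continue
        for (s, t), d in pair_distances.items():
            dsv = dist[s].get(v)
            dtv = dist[t].get(v)
            if dsv is not None and dtv is not None and dsv + dtv == d:
                nodes.add(v)
                break

    g = nx.Graph()
    g.add_nodes_from(seeds.seeds)
    g.add_nodes_from(nodes)
    for u, v in net.graph.edges:
        if u not in nodes or v not in nodes:
            continue
        on_path = False
        for (s, t), d in pair_distances.items():
            dsu, dtu = dist[s].get(u), dist[t].get(u)
            dsv, dtv = dist[s].get(v), dist[t].get(v)
            if dsu is None or dtv is None or dsv is None or dtu is None:
                continue
            if dsu + 1 + dtv == d or dsv + 1 + dtu == d:
                on_path = True
                break
        if on_path:
            g.add_edge(u, v)

    connecting = frozenset(nodes - seeds.seeds)
    return ShortestPathNetwork(
        term=seeds.term,
        graph=g,
        seed_set=seeds,
        connecting_nodes=connecting,
        seed_distances=dist,
        pair_distances=pair_distances,
    )


def _shortest_path_counts(graph: nx.Graph, source: str) -> dict[str, float]:
    """Number of distinct shortest paths from *source* to every node (BFS pass)."""
    sigma: dict[str, float] = {source: 1.0}
    dist: dict[str, int] = {source: 0}
    queue = [source]
    for v in queue:
        for w in graph[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0.0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return sigma


def rank_connecting_nodes(
    spn: ShortestPathNetwork,
    seeds: SeedSet,
    reference: str,
    corpus: AnnotationCorpus,
    net: InteractionNetwork,
) -> list[NodeRank]:
    """Order connecting nodes ascending by (sc, ss, bc), ties by node id.

    All three scores are evaluated on the full network: sc counts seed
    pairs whose shortest distance passes through the node; bc sums the
    per-pair fractions of shortest paths through the node (endpoints
    excluded); ss is the node's maximum Lin similarity to the reference.
    """
    dist = spn.seed_distances
    sigma = {s: _shortest_path_counts(net.graph, s) for s in dist}
    ranks: list[NodeRank] = []
    for v in sorted(spn.connecting_nodes):
        sc = 0
        bc = 0.0
        for (s, t), d in spn.pair_distances.items():
            dsv, dtv = dist[s].get(v), dist[t].get(v)
            if dsv is None or dtv is None or dsv + dtv != d:
                continue
            sc += 1
            bc += sigma[s][v] * sigma[t][v] / sigma[s][t]
        ss = corpus.max_semantic_similarity(v, reference)
        ranks.append(NodeRank(sc=sc, ss=ss, bc=bc, node=v))
    ranks.sort()
    return ranks


def minimize_network(
    spn: ShortestPathNetwork, ranking: list[NodeRank]
) -> FunctionModule:
    """Greedy distance-preserving reduction of the SPN.

    Nodes are tried for deletion from least to most important; a node is
    deleted iff afterwards every connected seed pair keeps its original
    full-network distance inside the current subgraph.  The result is
    1-minimal: no single retained connecting node can still be removed
    (removals only shrink the path set, so a node kept earlier can never
    become removable later).
    """
    work = spn.graph.copy()
    in_net_seeds = sorted(spn.seed_set.in_network)

    def distances_ok() -> bool:
        for s in in_net_seeds:
            d = nx.single_source_shortest_path_length(work, s)
            for (a, b), d0 in spn.pair_distances.items():
                if a == s and d.get(b, None) != d0:
                    return False
        return True

    for rank in ranking:
        v = rank.node
        saved_edges = list(work.edges(v))
        work.remove_node(v)
        if not distances_ok():
            work.add_node(v)
            work.add_edges_from(saved_edges)

    connecting = frozenset(set(work.nodes) - spn.seed_set.seeds)
    return FunctionModule(
        term=spn.term,
        seed_set=spn.seed_set,
        connecting_nodes=connecting,
        graph=work,
    )


def network_semantic_similarities(
    net: InteractionNetwork, reference: str, corpus: AnnotationCorpus
) -> np.ndarray:
    """Maximum semantic similarity to *reference* for every network node."""
    return np.array(
        [corpus.max_semantic_similarity(v, reference) for v in sorted(net.nodes)]
    )


def quality_filter(
    module: FunctionModule,
    reference: str,
    corpus: AnnotationCorpus,
    net: InteractionNetwork,
    alpha: float = 0.05,
    network_ss: np.ndarray | None = None,
) -> QualityResult:
    """Accept a module iff its connecting nodes look function-related.

    Rejects modules without connecting nodes outright, and modules with a
    single connecting node (within-group variance undefined).  Otherwise
    runs a one-sided Welch t-test of the connecting nodes' maximum
    semantic similarities against those of all network nodes; the module
    is accepted when the connecting-node mean is significantly higher.
    """
    conn = sorted(module.connecting_nodes)
    if len(conn) == 0:
        return QualityResult(False, "no_connecting_nodes")
    if len(conn) == 1:
        return QualityResult(False, "single_connecting_node")
    if network_ss is None:
        network_ss = network_semantic_similarities(net, reference, corpus)
    conn_ss = np.array([corpus.max_semantic_similarity(v, reference) for v in conn])
    accepted, p = similarity_ttest(conn_ss, network_ss, alpha=alpha)
    return QualityResult(
        accepted,
        "accepted" if accepted else "rejected_ttest",
        p_value=p,
        mean_connecting_ss=float(conn_ss.mean()),
        mean_network_ss=float(network_ss.mean()),
    )


def similarity_ttest(
    conn_ss: np.ndarray, network_ss: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float | None]:
    """One-sided Welch t-test: is mean(conn_ss) significantly above mean(network_ss)?"""
    # a zero-variance connecting-node group triggers a harmless precision warning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            np.asarray(conn_ss, dtype=float),
            np.asarray(network_ss, dtype=float),
            equal_var=False,
            alternative="greater",
        )
    p = float(res.pvalue)
    if not np.isfinite(p):
        return False, None
    return bool(p < alpha), p


@dataclass
class TermBuildRecord:
    """Per-term outcome of the module building pass."""

    term: str
    outcome: str  # built | rejected_ttest | no_connecting_nodes |
    #               single_connecting_node | too_few_seeds
    n_seeds: int = 0
    n_seeds_in_network: int = 0
    spn_size: int = 0
    module_size: int = 0
    ttest_p: float | None = None


@dataclass
class BuildReport:
    records: list[TermBuildRecord] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.outcome] = out.get(r.outcome, 0) + 1
        return out


def build_all_modules(
    net: InteractionNetwork,
    corpus: AnnotationCorpus,
    idmap: dict[str, str] | None = None,
    alpha: float = 0.05,
    apply_quality_filter: bool = True,
) -> tuple[dict[str, FunctionModule], BuildReport]:
    """Attempt one module per directly annotated term; keep accepted ones.

    Terms with fewer than two in-network seeds cannot yield a non-trivial
    module and are recorded as ``too_few_seeds``.  Per-term failures are
    logged, never fatal.  The returned dict maps term id to its accepted
    :class:`FunctionModule`; the report records every attempt.
    """
    if idmap is not None:
        net = net.relabeled(idmap)
    report = BuildReport()
    accepted: dict[str, FunctionModule] = {}
    for term in sorted(corpus.per_term_direct):
        seeds = build_seed_set(term, corpus, net)
        rec = TermBuildRecord(
            term=term,
            outcome="too_few_seeds",
            n_seeds=len(seeds.seeds),
            n_seeds_in_network=len(seeds.in_network),
        )
        if len(seeds.in_network) < 2:
            report.records.append(rec)
            continue
        spn = extract_shortest_path_network(net, seeds)
        rec.spn_size = spn.graph.number_of_nodes()
        ranking = rank_connecting_nodes(spn, seeds, term, corpus, net)
        module = minimize_network(spn, ranking)
        rec.module_size = module.graph.number_of_nodes()
        if apply_quality_filter:
            quality = quality_filter(module, term, corpus, net, alpha=alpha)
        else:
            quality = QualityResult(True, "unfiltered")
        module.quality = quality
        rec.ttest_p = quality.p_value
        if quality.accepted:
            rec.outcome = "built"
            accepted[term] = module
        else:
            rec.outcome = quality.reason
        report.records.append(rec)
    log.info("module build outcomes: %s", report.counts())
    return accepted, report


# -- serialization ------------------------------------------------------


def _module_payload(module: FunctionModule) -> dict:
    return {
        "term": module.term,
        "seeds_in_network": sorted(module.seed_set.in_network),
        "seeds_isolated": sorted(module.seed_set.isolated),
        "connecting_nodes": sorted(module.connecting_nodes),
        "edges": sorted(tuple(sorted(e)) for e in module.graph.edges),
        "quality": {
            "accepted": module.quality.accepted if module.quality else None,
            "reason": module.quality.reason if module.quality else None,
            "p_value": module.quality.p_value if module.quality else None,
        },
    }


def modules_to_json(
    modules: dict[str, FunctionModule], config: dict | None = None
) -> str:
    """Deterministic JSON serialization of a module archive."""
    config = dict(sorted((config or {}).items()))
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload = {
        "format": __version_tag__,
        "config": config,
        "config_hash": cfg_hash,
        "modules": [_module_payload(modules[t]) for t in sorted(modules)],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def modules_from_json(text: str) -> dict[str, FunctionModule]:
    payload = json.loads(text)
    out: dict[str, FunctionModule] = {}
    for m in payload["modules"]:
        g = nx.Graph()
        g.add_nodes_from(m["seeds_in_network"])
        g.add_nodes_from(m["seeds_isolated"])
        g.add_nodes_from(m["connecting_nodes"])
        g.add_edges_from(m["edges"])
        seed_set = SeedSet(
            term=m["term"],
            in_network=frozenset(m["seeds_in_network"]),
            isolated=frozenset(m["seeds_isolated"]),
        )
        q = m.get("quality", {})
        out[m["term"]] = FunctionModule(
            term=m["term"],
            seed_set=seed_set,
            connecting_nodes=frozenset(m["connecting_nodes"]),
            graph=g,
            quality=QualityResult(
                bool(q.get("accepted")), q.get("reason") or "", q.get("p_value")
            ),
        )
    return out


def module_edges_tsv(module: FunctionModule) -> str:
    """Two-column edge list of a module, for graph viewers."""
    lines = [f"{u}\t{v}" for u, v in sorted(tuple(sorted(e)) for e in module.graph.edges)]
    return "\n".join(lines) + ("\n" if lines else "")
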
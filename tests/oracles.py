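"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the package
(path enumeration instead of distance arithmetic, exhaustive subset
search instead of greedy reduction, scipy's hypergeometric survival
function instead of exact tail summation) so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import stats


def spn_by_path_enumeration(graph: nx.Graph, seeds: list[str]):
    """Nodes and edges on any shortest path between any seed pair.

    Enumerates every shortest path explicitly via networkx.
    """
    nodes: set = set(s for s in seeds if s in graph)
    edges: set = set()
    for s, t in itertools.combinations(sorted(seeds), 2):
        if s not in graph or t not in graph or not nx.has_path(graph, s, t):
            continue
        for path in nx.all_shortest_paths(graph, s, t):
            nodes.update(path)
            edges.update(frozenset(e) for e in zip(path, path[1:]))
    return nodes, edges


def minimum_distance_preserving_size(
    graph: nx.Graph, spn: nx.Graph, seeds: list[str]
) -> int:
    """Size of the smallest SPN subgraph preserving all seed-pair distances.

    Exhaustive search over subsets of non-seed SPN nodes, smallest first;
    feasible only for toy instances.
    """
    seeds_in = [s for s in seeds if s in graph]
    target = {}
    for s, t in itertools.combinations(sorted(seeds_in), 2):
        if nx.has_path(graph, s, t):
            target[(s, t)] = nx.shortest_path_length(graph, s, t)
    connecting = sorted(set(spn.nodes) - set(seeds))
    for size in range(len(connecting) + 1):
        for keep in itertools.combinations(connecting, size):
            sub = spn.subgraph(list(keep) + seeds_in)
            ok = True
            for (s, t), d in target.items():
                try:
                    if nx.shortest_path_length(sub, s, t) != d:
                        ok = False
                        break
                except nx.NetworkXNoPath:
                    ok = False
                    break
            if ok:
                return size + len(set(spn.nodes) - set(connecting))
    raise AssertionError("SPN itself must be distance preserving")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) via scipy's hypergeometric survival function."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def lin_similarity_bruteforce(
    parents: dict[str, set[str]], counts: dict[str, int], total: int, t1: str, t2: str
) -> float:
    """Lin similarity by explicit common-ancestor enumeration on a parent map."""

    def up(t: str) -> set[str]:
        acc = {t}
        frontier = [t]
        while frontier:
            x = frontier.pop()
            for p in parents.get(x, ()):  # child -> parents walk
                if p not in acc:
                    acc.add(p)
                    frontier.append(p)
        return acc

    def ic(t: str) -> float:
        return -np.log(counts[t] / total)

    common = [t for t in up(t1) & up(t2) if counts.get(t, 0) > 0]
    if not common:
        return 0.0
    mica = max(ic(t) for t in common)
    denom = ic(t1) + ic(t2)
    return 0.0 if denom == 0 else 2.0 * mica / denom


def random_connected_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """Small random graph (not necessarily connected) with string node ids."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.15, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


def random_dag_corpus(rng: np.random.Generator, n_terms_max: int = 20):
    """Random rooted DAG (parent map) plus a nested annotation-count corpus.

    Counts are generated by simulating direct annotations and propagating
    them, so parent counts always dominate child counts like a real corpus.
    """
    n = int(rng.integers(3, n_terms_max + 1))
    terms = [f"T{i:02d}" for i in range(n)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, n):
        k = int(rng.integers(1, min(i, 3) + 1))
        idx = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = {terms[j] for j in idx}
    n_prot = int(rng.integers(4, 30))
    direct: dict[str, set[str]] = {}
    for p in range(n_prot):
        n_ann = int(rng.integers(1, 4))
        idx = rng.choice(n, size=min(n_ann, n), replace=False)
        direct[f"p{p:02d}"] = {terms[j] for j in idx}
    # propagate
    counts: dict[str, set[str]] = {t: set() for t in terms}
    for prot, ts in direct.items():
        closure: set[str] = set()
        frontier = list(ts)
        while frontier:
            x = frontier.pop()
            if x not in closure:
                closure.add(x)
                frontier.extend(parents[x])
        for t in closure:
            counts[t].add(prot)
    count_map = {t: len(ps) for t, ps in counts.items()}
    return parents, direct, count_map, n_prot
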
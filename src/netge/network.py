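"""Interaction-network loading and graph queries.

The interaction network is an undirected, unweighted, self-loop-free
graph of protein identifiers.  Two edge-list dialects are read: the
STRING ``protein.actions`` table (header + item_id_a / item_id_b / mode
columns; every documented action is kept irrespective of score, and
action modes on the same pair collapse to a single edge) and a generic
two-column TSV.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping

import networkx as nx

log = logging.getLogger(__name__)


class InteractionNetwork:
    """Undirected, unweighted protein interaction graph."""

    def __init__(self, graph: nx.Graph) -> None:
        if any(u == v for u, v in graph.edges):
            raise ValueError("interaction network must be self-loop free")
        self.graph = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_edges_from((u, v) for u, v in edges if u != v)
        return cls(g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def distances_from(self, source: str) -> dict[str, int]:
        """Hop-count shortest distances to every reachable node (BFS)."""
        return nx.single_source_shortest_path_length(self.graph, source)

    def relabeled(self, mapping: Mapping[str, str]) -> "InteractionNetwork":
        """Return a copy with node ids translated where *mapping* covers them."""
        g = nx.relabel_nodes(self.graph, dict(mapping), copy=True)
        return InteractionNetwork(g)


def load_edge_list(path, dialect: str = "generic") -> InteractionNetwork:
    """Load an interaction network from a tab-separated edge list.

    dialect="string-actions" expects a header naming at least
    ``item_id_a`` and ``item_id_b``; dialect="generic" expects two
    identifier columns per row (``#`` comments allowed).  Self-loop rows
    are dropped (and counted); duplicate and symmetric rows collapse.
    """
    if dialect not in ("generic", "string-actions"):
        raise ValueError(f"unknown edge-list dialect: {dialect!r}")
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    col_a, col_b = 0, 1
    start = 0
    if dialect == "string-actions":
        if not lines:
            raise ValueError("empty STRING actions file")
        header = lines[0].rstrip().split("\t")
        try:
            col_a = header.index("item_id_a")
            col_b = header.index("item_id_b")
        except ValueError as exc:
            raise ValueError(
                "STRING actions header must name item_id_a and item_id_b"
            ) from exc
        start = 1

    g = nx.Graph()
    n_self = 0
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) <= max(col_a, col_b):
            raise ValueError(f"edge list line {lineno}: too few columns")
        a, b = fields[col_a].strip(), fields[col_b].strip()
        if not a or not b:
            raise ValueError(f"edge list line {lineno}: empty identifier")
        if a == b:
            n_self += 1
            continue
        g.add_edge(a, b)
    if n_self:
        log.info("dropped %d self-loop rows", n_self)
    if g.number_of_edges() == 0:
        raise ValueError("no edges left after filtering")
    return InteractionNetwork(g)


def load_idmap(path) -> dict[str, str]:
    """Load a network-id → annotation-id map from two-column TSV.

    Network ids mapping to more than one annotation id, and annotation
    ids targeted by more than one network id, are dropped (ambiguous).
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    pairs: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"id-map line {lineno}: expected 2 columns")
        pairs.add((fields[0].strip(), fields[1].strip()))
    fwd_count: dict[str, int] = {}
    rev_count: dict[str, int] = {}
    for a, b in pairs:
        fwd_count[a] = fwd_count.get(a, 0) + 1
        rev_count[b] = rev_count.get(b, 0) + 1
    mapping = {
        a: b for a, b in pairs if fwd_count[a] == 1 and rev_count[b] == 1
    }
    dropped = len(pairs) - len(mapping)
    if dropped:
        log.warning("dropped %d ambiguous id mappings", dropped)
    return mapping


def pairwise_seed_distances(
    net: InteractionNetwork, seeds: Iterable[str]
) -> dict[frozenset[str], float]:
    """Hop distances between all unordered distinct seed pairs.

    Pairs lying in different components map to ``math.inf``.
    """
    seeds = sorted(set(seeds))
    dist = {s: net.distances_from(s) for s in seeds if s in net}
    out: dict[frozenset[str], float] = {}
    for s, t in itertools.combinations(seeds, 2):
        if s in dist and t in dist[s]:
            out[frozenset((s, t))] = dist[s][t]
        else:
            out[frozenset((s, t))] = math.inf
    return out
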
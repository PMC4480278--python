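"""Walk through module extraction on a seven-node toy interactome.

Two seed proteins s and t are joined by two 2-hop paths (via u and v)
and one 3-hop detour (via w, x).  The shortest path network keeps only
nodes on *shortest* paths, and the minimization then deletes whichever
of the two redundant 2-hop connectors ranks lower.
"""

import io

from netge import (
    extract_shortest_path_network,
    load_annotations,
    load_obo,
    minimize_network,
    rank_connecting_nodes,
)
from netge.modules import SeedSet
from netge.network import InteractionNetwork

net = InteractionNetwork.from_edges(
    [("s", "u"), ("u", "t"), ("s", "v"), ("v", "t"), ("s", "w"), ("w", "x"), ("x", "t")]
)
# a two-term ontology; v is annotated close to the reference term, u is not
obo = """format-version: 1.2
ontology: example

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: reference process
is_a: GO:0000001
"""
dag = load_obo(io.StringIO(obo))
corpus = load_annotations(
    io.StringIO("s\tGO:0000002\nt\tGO:0000002\nv\tGO:0000002\np1\tGO:0000001\n"), dag
)

seeds = SeedSet(term="GO:0000002", in_network=frozenset({"s", "t"}), isolated=frozenset())
spn = extract_shortest_path_network(net, seeds)
print("SPN nodes:", sorted(spn.graph.nodes))  # w, x are off all shortest paths

ranking = rank_connecting_nodes(spn, seeds, "GO:0000002", corpus, net)
for r in ranking:
    print(f"  candidate {r.node}: sc={r.sc} ss={r.ss:.3f} bc={r.bc:.2f}")

module = minimize_network(spn, ranking)
print("module nodes:", sorted(module.graph.nodes))
print("retained connecting nodes:", sorted(module.connecting_nodes))
# u is removed first (lower semantic similarity) and v alone preserves
# the distance d(s, t) = 2, so the module is seeds + v.
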
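"""Desk-scale synthetic fixtures with planted function-specific modules.

The generator emulates the real pipeline inputs — an interaction
network, a single-namespace ontology, a protein→term annotation file —
at toy scale, and plants ground-truth modules whose recovery can be
asserted rather than hoped for:

* the background interactome is an Erdős–Rényi (or preferential
  attachment) random graph;
* each planted module consists of seed proteins directly annotated with
  a dedicated leaf term and connector proteins wired as *bridges* on
  otherwise-unique seed-pair geodesics (any competing length-2 path is
  cut), so the shortest-path network provably contains the connectors
  and minimization provably retains them;
* connectors carry a sibling leaf term of the planted term, giving them
  high Lin similarity to it so planted modules pass the quality t-test;
* background nodes receive annotation noise drawn from leaves outside
  the planted branches.

All randomness flows from the single spec-level seed through named
substreams (graph, annotations); queries take their own seed so they
can be redrawn independently of the fixture.

Every fixture is rendered to the same text formats the real pipeline
reads (generic edge-list TSV, OBO 1.2, two-column annotation TSV) and
re-loaded through the production loaders, so fixtures exercise the I/O
paths by construction.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import InteractionNetwork, load_edge_list
from .ontology import AnnotationCorpus, OntologyDag, load_annotations, load_obo


@dataclass(frozen=True)
class PlantedModule:
    """Shape of one planted function-specific module."""

    n_seeds: int = 8
    n_connectors: int = 4
    #: internal wiring density: probability of a direct edge between
    #: non-consecutive seeds.  Functional modules are densely wired in real
    #: interactomes; dense seed wiring also keeps within-module geodesics
    #: competitive with background shortcuts, so minimization can discard
    #: unrelated background nodes.
    extra_seed_edge_prob: float = 0.65

    def __post_init__(self) -> None:
        if self.n_seeds < 2 or self.n_connectors < 0:
            raise ValueError("planted module needs >= 2 seeds")
        if self.n_connectors > self.n_seeds - 1:
            raise ValueError("at most n_seeds - 1 connectors can be bridged")

    @property
    def size(self) -> int:
        return self.n_seeds + self.n_connectors


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture; identical spec + seed → identical fixture."""

    seed: int
    n_nodes: int = 300
    model: str = "er"  # "er" | "ba"
    edge_prob: float = 0.02
    ba_edges: int = 3
    depth: int = 3
    branching: int = 3
    planted: tuple[PlantedModule, ...] = (
        PlantedModule(),
        PlantedModule(),
        PlantedModule(),
    )
    noise_rate: float = 0.1
    #: off-network proteins annotated with each connector-side (related)
    #: term, mimicking annotated proteins absent from the interactome
    n_related_padding: int = 10
    #: off-network proteins annotated outside the planted branches, so branch
    #: ancestors never annotate the whole corpus (their information content
    #: would collapse to zero otherwise, as no real corpus behaves)
    n_filler: int = 5

    def __post_init__(self) -> None:
        if self.n_nodes <= 0 or not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("invalid fixture spec")
        if sum(m.size for m in self.planted) > self.n_nodes:
            raise ValueError("planted modules larger than the graph")
        if self.branching < 2 or self.depth < 2:
            raise ValueError("ontology needs depth >= 2 and branching >= 2")


@dataclass(frozen=True)
class GroundTruth:
    """Planted member sets plus the node universe, for recovery and decoy draws."""

    members: dict[str, frozenset[str]]
    related_terms: dict[str, str]
    all_nodes: frozenset[str]

    @property
    def planted_terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass
class Fixture:
    spec: FixtureSpec
    net: InteractionNetwork
    dag: OntologyDag
    corpus: AnnotationCorpus
    truth: GroundTruth
    files: dict[str, str] = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Serialize the fixture files plus ground truth into *outdir*."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, text in self.files.items():
            (out / name).write_text(text)
        truth = {
            "members": {t: sorted(m) for t, m in self.truth.members.items()},
            "related_terms": dict(sorted(self.truth.related_terms.items())),
            "all_nodes": sorted(self.truth.all_nodes),
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        spec = {
            "seed": self.spec.seed,
            "n_nodes": self.spec.n_nodes,
            "model": self.spec.model,
            "edge_prob": self.spec.edge_prob,
            "ba_edges": self.spec.ba_edges,
            "depth": self.spec.depth,
            "branching": self.spec.branching,
            "noise_rate": self.spec.noise_rate,
            "planted": [
                {
                    "n_seeds": m.n_seeds,
                    "n_connectors": m.n_connectors,
                    "extra_seed_edge_prob": m.extra_seed_edge_prob,
                }
                for m in self.spec.planted
            ],
        }
        (out / "fixture_spec.json").write_text(json.dumps(spec, indent=1))


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def _build_tree(depth: int, branching: int):
    """Complete is_a tree, level order; returns (parent map, levels)."""
    parents: dict[str, str | None] = {_term_id(0): None}
    levels: list[list[str]] = [[_term_id(0)]]
    counter = 1
    for _ in range(depth):
        level = []
        for parent in levels[-1]:
            for _ in range(branching):
                tid = _term_id(counter)
                counter += 1
                parents[tid] = parent
                level.append(tid)
        levels.append(level)
    return parents, levels


def _obo_text(parents: dict[str, str | None]) -> str:
    chunks = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(parents):
        chunks.append("[Term]")
        chunks.append(f"id: {term}")
        chunks.append(f"name: synthetic term {term}")
        if parents[term] is not None:
            chunks.append(f"is_a: {parents[term]}")
        chunks.append("")
    return "\n".join(chunks)


def generate_fixture(spec: FixtureSpec, outdir=None) -> Fixture:
    """Generate a fixture with planted modules; optionally serialize it."""
    ss = np.random.SeedSequence(spec.seed)
    graph_ss, annot_ss = ss.spawn(2)
    graph_seed = int(graph_ss.generate_state(1)[0] % 2**31)
    rng = np.random.default_rng(annot_ss)

    # -- background graph ---------------------------------------------
    if spec.model == "er":
        g = nx.gnp_random_graph(spec.n_nodes, spec.edge_prob, seed=graph_seed)
    elif spec.model == "ba":
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.ba_edges, seed=graph_seed)
    else:
        raise ValueError(f"unknown graph model: {spec.model!r}")

    # -- ontology -------------------------------------------------------
    parents, levels = _build_tree(spec.depth, spec.branching)
    leaf_parents = levels[-2]
    if len(leaf_parents) < len(spec.planted):
        raise ValueError("ontology too small for the requested planted modules")
    stride = max(1, len(leaf_parents) // max(1, len(spec.planted)))
    children: dict[str, list[str]] = {}
    for t, p in parents.items():
        if p is not None:
            children.setdefault(p, []).append(t)

    planted_terms: list[str] = []
    related_terms: dict[str, str] = {}
    planted_parents: set[str] = set()
    for i in range(len(spec.planted)):
        parent = leaf_parents[(i * stride) % len(leaf_parents)]
        if parent in planted_parents:
            raise ValueError("not enough leaf parents for disjoint planted modules")
        planted_parents.add(parent)
        leaves = sorted(children[parent])
        planted_terms.append(leaves[0])
        related_terms[leaves[0]] = leaves[1]
    noise_leaves = sorted(
        t for t in levels[-1] if parents[t] not in planted_parents
    )

    # -- plant modules --------------------------------------------------
    annotations: dict[int, str] = {}
    truth_members: dict[str, set[int]] = {}
    offset = 0
    planted_nodes: set[int] = set()
    for i, mod in enumerate(spec.planted):
        seeds = list(range(offset, offset + mod.n_seeds))
        conns = list(range(offset + mod.n_seeds, offset + mod.size))
        offset += mod.size
        block = set(seeds) | set(conns)
        planted_nodes |= block
        # controlled internal wiring: clear background edges inside the block
        for u in block:
            for v in list(g[u]):
                if v in block:
                    g.remove_edge(u, v)
        # bridges: connector j is the unique geodesic between seeds j, j+1
        for j, c in enumerate(conns):
            g.add_edge(seeds[j], c)
            g.add_edge(c, seeds[j + 1])
        # remaining consecutive seeds attach directly (module stays connected)
        for j in range(mod.n_connectors, mod.n_seeds - 1):
            g.add_edge(seeds[j], seeds[j + 1])
        if mod.extra_seed_edge_prob > 0:
            for a in range(mod.n_seeds):
                for b in range(a + 2, mod.n_seeds):
                    if rng.random() < mod.extra_seed_edge_prob:
                        g.add_edge(seeds[a], seeds[b])
        # cut competing length-2 paths so each bridge geodesic is unique
        for j, c in enumerate(conns):
            a, b = seeds[j], seeds[j + 1]
            for x in (set(g[a]) & set(g[b])) - {c}:
                g.remove_edge(x, b)
        term = planted_terms[i]
        truth_members[term] = block
        for s in seeds:
            annotations[s] = term
        for c in conns:
            annotations[c] = related_terms[term]

    # -- annotation noise on background nodes ---------------------------
    for v in range(spec.n_nodes):
        if v in planted_nodes:
            continue
        if noise_leaves and rng.random() < spec.noise_rate:
            annotations[v] = noise_leaves[rng.integers(len(noise_leaves))]

    # off-network padding proteins carrying the related terms
    padding: list[tuple[str, str]] = []
    for i, term in enumerate(planted_terms):
        for j in range(spec.n_related_padding):
            padding.append((f"X{i:02d}{j:02d}", related_terms[term]))
    for j in range(spec.n_filler if noise_leaves else 0):
        padding.append((f"Y{j:04d}", noise_leaves[j % len(noise_leaves)]))

    # -- render to the production text formats and reload ---------------
    def name(v: int) -> str:
        return f"P{v:04d}"

    edge_lines = sorted(
        f"{name(min(u, v))}\t{name(max(u, v))}" for u, v in g.edges
    )
    network_text = "\n".join(edge_lines) + "\n"
    obo_text = _obo_text(parents)
    annot_lines = sorted(
        [f"{name(v)}\t{t}" for v, t in annotations.items()]
        + [f"{p}\t{t}" for p, t in padding]
    )
    annotation_text = "\n".join(annot_lines) + "\n"

    net = load_edge_list(io.StringIO(network_text), dialect="generic")
    dag = load_obo(io.StringIO(obo_text))
    corpus = load_annotations(io.StringIO(annotation_text), dag)

    truth = GroundTruth(
        members={
            t: frozenset(name(v) for v in ms) for t, ms in truth_members.items()
        },
        related_terms=related_terms,
        all_nodes=net.nodes,
    )
    fixture = Fixture(
        spec=spec,
        net=net,
        dag=dag,
        corpus=corpus,
        truth=truth,
        files={
            "network.tsv": network_text,
            "ontology.obo": obo_text,
            "annotations.tsv": annotation_text,
        },
    )
    if outdir is not None:
        fixture.write(outdir)
    return fixture


def generate_query(
    truth: GroundTruth,
    term: str,
    n_members: int,
    n_decoys: int,
    seed: int,
) -> list[str]:
    """Sample a query protein set: planted members plus uniform decoys."""
    if term not in truth.members:
        raise KeyError(f"term {term} was not planted")
    members = sorted(truth.members[term])
    if n_members > len(members):
        raise ValueError(
            f"requested {n_members} members but only {len(members)} planted"
        )
    non_members = sorted(truth.all_nodes - truth.members[term])
    if n_decoys > len(non_members):
        raise ValueError("requested more decoys than non-member nodes")
    rng = np.random.default_rng(seed)
    picked = [members[i] for i in rng.choice(len(members), n_members, replace=False)]
    picked += [
        non_members[i] for i in rng.choice(len(non_members), n_decoys, replace=False)
    ]
    return sorted(picked)


def build_added_value_fixture():
    """Deterministic hand-built fixture demonstrating added-value terms.

    Six five-protein modules (3 seeds + 2 bridging connectors each) form
    a ring-shaped 30-node network.  Module seeds carry a rare leaf term;
    connectors carry a *common* sibling term padded with many
    off-network proteins, so a query made of the two connectors of the
    first module is annotation-wise unremarkable (standard enrichment
    finds nothing) yet sits squarely inside that module (network
    enrichment flags the module's term, which no query protein carries).

    Returns ``(net, dag, corpus, query, planted_term)``.
    """
    n_modules = 6
    parents: dict[str, str | None] = {_term_id(0): None}
    planted, related = [], []
    tid = 1
    for i in range(n_modules):
        b = _term_id(tid)
        t = _term_id(tid + 1)
        t2 = _term_id(tid + 2)
        tid += 3
        parents[b] = _term_id(0)
        parents[t] = b
        parents[t2] = b
        planted.append(t)
        related.append(t2)

    edges = []
    annot = []
    pad_counter = 0
    for i in range(n_modules):
        base = i * 5
        s = [f"P{base + j:04d}" for j in range(3)]
        c = [f"P{base + 3:04d}", f"P{base + 4:04d}"]
        edges += [(s[0], c[0]), (c[0], s[1]), (s[1], c[1]), (c[1], s[2])]
        # ring link to the next module keeps the network in one component
        nxt = ((i + 1) % n_modules) * 5
        edges.append((s[2], f"P{nxt:04d}"))
        annot += [(p, planted[i]) for p in s]
        annot += [(p, related[i]) for p in c]
        # off-network padding proteins make the related term common
        n_pad = 22 if i == 0 else 10
        for _ in range(n_pad):
            annot.append((f"X{pad_counter:04d}", related[i]))
            pad_counter += 1

    network_text = "\n".join(f"{a}\t{b}" for a, b in edges) + "\n"
    annotation_text = "\n".join(f"{p}\t{t}" for p, t in sorted(annot)) + "\n"
    net = load_edge_list(io.StringIO(network_text), dialect="generic")
    dag = load_obo(io.StringIO(_obo_text(parents)))
    corpus = load_annotations(io.StringIO(annotation_text), dag)
    query = ["P0003", "P0004"]  # the two connectors of the first module
    return net, dag, corpus, query, planted[0]
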
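"""Ontology handling: OBO parsing, annotation propagation, information
content and Lin semantic similarity.

The enrichment pipeline needs three things from the ontology side:

* a rooted DAG of terms (``is_a``/``part_of`` parent edges only, the
  relations along which GO Biological Process annotations propagate);
* an annotation corpus mapping proteins to terms, with the transitive
  ancestor closure ("a protein annotated with a term is implicitly
  annotated with all its ancestors");
* Lin's information-theoretic semantic similarity between terms, and the
  derived *maximum semantic similarity* of a protein against a reference
  term, which ranks connecting nodes during module minimization.

Information content is computed over the propagated corpus:
``ic(t) = -ln(n_t / n_total)`` where ``n_t`` counts proteins carrying ``t``
after propagation and ``n_total`` counts all annotated proteins.  Terms
annotating no protein have undefined information content and are excluded
from similarity computations.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

log = logging.getLogger(__name__)

#: relations that define ancestry (annotation propagation conventions)
PARENT_RELATIONS = ("is_a", "part_of")


class OboParseError(ValueError):
    """Raised for malformed OBO input; carries the offending line number."""


class OntologyValidationError(ValueError):
    """Raised when the parsed ontology violates DAG requirements."""


def _prevalidate_obo_lines(lines: Iterable[str]) -> None:
    """Cheap structural scan so malformed stanza lines are reported by number.

    obonet is permissive; this guards the contract that a tag line inside a
    stanza must be ``key: value``.
    """
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].strip() if not raw.startswith("!") else ""
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            continue
        if ":" not in line:
            raise OboParseError(
                f"malformed OBO tag line {lineno}: {raw.strip()!r}"
            )


class OntologyDag:
    """Rooted DAG of ontology terms linked by is_a/part_of parent edges.

    Parameters
    ----------
    parents:
        Mapping term -> set of parent term ids.  Terms appearing only as
        parents are added automatically.
    names:
        Optional term -> human-readable name.
    alt_ids:
        Optional alias -> primary id (``alt_id`` tags in OBO).
    """

    def __init__(
        self,
        parents: Mapping[str, set[str]],
        names: Mapping[str, str] | None = None,
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self._parents: dict[str, frozenset[str]] = {}
        all_terms: set[str] = set(parents)
        for ps in parents.values():
            all_terms.update(ps)
        for term in all_terms:
            self._parents[term] = frozenset(parents.get(term, ()))
        self.names: dict[str, str] = dict(names or {})
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._validate()

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        for child, ps in self._parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyValidationError(
                f"ontology relations contain a cycle: {cycle}"
            )

    # -- queries -------------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._parents)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self._parents.items() if not ps)

    def __contains__(self, term: str) -> bool:
        return term in self._parents or term in self.alt_ids

    def __len__(self) -> int:
        return len(self._parents)

    def resolve(self, term: str) -> str:
        """Resolve an alt_id alias to its primary term id."""
        if term in self._parents:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown term: {term}")

    def parents(self, term: str) -> frozenset[str]:
        return self._parents[self.resolve(term)]

    def ancestors(self, term: str, include_self: bool = False) -> frozenset[str]:
        """All terms reachable via parent edges (strict unless include_self)."""
        term = self.resolve(term)
        if term not in self._ancestor_cache:
            acc: set[str] = set()
            stack = list(self._parents[term])
            while stack:
                t = stack.pop()
                if t not in acc:
                    acc.add(t)
                    stack.extend(self._parents[t])
            self._ancestor_cache[term] = frozenset(acc)
        anc = self._ancestor_cache[term]
        return anc | {term} if include_self else anc

    def is_ancestor(self, candidate: str, term: str) -> bool:
        """True iff *candidate* is a strict ancestor of *term*."""
        return self.resolve(candidate) in self.ancestors(term)


def load_obo(path) -> OntologyDag:
    """Parse an OBO 1.2 file into an :class:`OntologyDag`.

    Obsolete terms are excluded; ``alt_id`` tags are kept as aliases;
    only ``is_a`` and ``part_of`` relations become parent edges.
    *path* may be a filesystem path or a readable text file object.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            text = fh.read()
    _prevalidate_obo_lines(text.splitlines())
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)

    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        if "name" in data:
            names[term] = data["name"]
        for alias in data.get("alt_id", ()):
            alt_ids[alias] = term
    for child, parent, rel in graph.edges(keys=True):
        if rel in PARENT_RELATIONS:
            parents.setdefault(child, set()).add(parent)
    return OntologyDag(parents, names=names, alt_ids=alt_ids)


@dataclass(frozen=True)
class TermInformation:
    """Per-term annotation frequency and information content."""

    term: str
    frequency: int
    ic: float


class AnnotationCorpus:
    """Protein→term annotations with ancestor closure and inverse maps.

    ``direct`` holds the annotations as stated in the source file;
    ``propagated`` adds every ancestor of every direct term; ``per_term``
    inverts the propagated map and is the basis for term frequencies,
    information content and enrichment backgrounds.
    """

    def __init__(self, direct: Mapping[str, set[str]], dag: OntologyDag) -> None:
        self.dag = dag
        self.direct: dict[str, frozenset[str]] = {
            p: frozenset(dag.resolve(t) for t in ts) for p, ts in direct.items() if ts
        }
        self.propagated: dict[str, frozenset[str]] = {}
        per_term: dict[str, set[str]] = {}
        per_term_direct: dict[str, set[str]] = {}
        for protein, terms in self.direct.items():
            closure: set[str] = set()
            for t in terms:
                closure |= dag.ancestors(t, include_self=True)
                per_term_direct.setdefault(t, set()).add(protein)
            self.propagated[protein] = frozenset(closure)
            for t in closure:
                per_term.setdefault(t, set()).add(protein)
        self.per_term: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in per_term.items()
        }
        self.per_term_direct: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in per_term_direct.items()
        }
        self._ic_cache: dict[str, float] = {}

    # -- basic queries -------------------------------------------------

    @property
    def proteins(self) -> frozenset[str]:
        """All proteins with at least one annotation."""
        return frozenset(self.propagated)

    def annotated_terms(self) -> frozenset[str]:
        """Terms annotating at least one protein (defined information content)."""
        return frozenset(self.per_term)

    def frequency(self, term: str) -> int:
        return len(self.per_term.get(self.dag.resolve(term), ()))

    # -- information content and similarity ----------------------------

    def information_content(self, term: str) -> float:
        """``-ln(frequency / n_annotated_proteins)``; undefined for unused terms."""
        term = self.dag.resolve(term)
        if term in self._ic_cache:
            return self._ic_cache[term]
        freq = self.frequency(term)
        if freq == 0:
            raise KeyError(
                f"term {term} annotates no protein; information content undefined"
            )
        ic = -math.log(freq / len(self.propagated))
        self._ic_cache[term] = ic
        return ic

    def term_information(self, term: str) -> TermInformation:
        term = self.dag.resolve(term)
        return TermInformation(term, self.frequency(term), self.information_content(term))

    def lin_similarity(self, t1: str, t2: str) -> float:
        """Lin similarity ``2*ic(MICA)/(ic(t1)+ic(t2))`` in [0, 1].

        The most informative common ancestor (MICA) search includes the two
        terms themselves.  Returns 0 when the terms share no ancestor
        (disjoint roots) or when both have zero information content.
        """
        t1 = self.dag.resolve(t1)
        t2 = self.dag.resolve(t2)
        ic1 = self.information_content(t1)
        ic2 = self.information_content(t2)
        common = self.dag.ancestors(t1, include_self=True) & self.dag.ancestors(
            t2, include_self=True
        )
        common &= self.annotated_terms()
        if not common:
            log.debug("terms %s and %s share no common ancestor", t1, t2)
            return 0.0
        mica_ic = max(self.information_content(t) for t in common)
        denom = ic1 + ic2
        if denom == 0.0:
            return 0.0
        return 2.0 * mica_ic / denom

    def max_semantic_similarity(
        self, protein: str, reference: str, use_propagated: bool = False
    ) -> float:
        """Highest Lin score between the protein's terms and *reference*.

        Candidates default to the protein's direct terms; ancestors added
        by propagation only dilute the maximum, but ``use_propagated=True``
        scores the full closure instead.  Unannotated proteins score 0 so
        that connecting nodes without any annotation remain rankable.
        """
        source = self.propagated if use_propagated else self.direct
        terms = source.get(protein)
        if not terms:
            return 0.0
        return max(self.lin_similarity(t, reference) for t in terms)


# -- module-level operation wrappers (stable functional surface) --------


def load_annotations(path, dag: OntologyDag) -> AnnotationCorpus:
    """Load protein→term annotations from GAF 2.x or two-column TSV.

    Format is sniffed: lines starting with ``!`` or rows with >= 15
    tab-separated fields are treated as GAF (column 2 = protein id,
    column 4 = qualifier, column 5 = term id; NOT-qualified rows dropped).
    Otherwise each non-comment row must be ``protein<TAB>term``.
    Annotations to terms absent from *dag* are dropped with a warning.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    direct: dict[str, set[str]] = {}
    n_unknown = 0
    n_not = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.split("\t")
        if len(fields) >= 15:  # GAF row
            protein, qualifier, term = fields[1], fields[3], fields[4]
            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
        elif len(fields) == 2:
            protein, term = fields[0].strip(), fields[1].strip()
        else:
            raise ValueError(
                f"annotation line {lineno}: expected 2-column TSV or GAF row, "
                f"got {len(fields)} fields"
            )
        if term not in dag:
            n_unknown += 1
            continue
        direct.setdefault(protein, set()).add(term)
    if n_unknown:
        log.warning("dropped %d annotations to unknown terms", n_unknown)
    if n_not:
        log.info("dropped %d NOT-qualified GAF rows", n_not)
    if not direct:
        raise ValueError("annotation corpus is empty after filtering")
    return AnnotationCorpus(direct, dag)


def information_content(term: str, corpus: AnnotationCorpus) -> float:
    return corpus.information_content(term)


def lin_similarity(t1: str, t2: str, corpus: AnnotationCorpus) -> float:
    return corpus.lin_similarity(t1, t2)


def max_semantic_similarity(
    protein: str, reference: str, corpus: AnnotationCorpus, use_propagated: bool = False
) -> float:
    return corpus.max_semantic_similarity(protein, reference, use_propagated)
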
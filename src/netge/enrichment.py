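"""Overrepresentation tests against annotations and against modules.

Both the standard and the network-based enrichment are one-sided
Fisher's exact tests (hypergeometric upper tail) with Bonferroni
correction.  The standard test asks whether a term's annotated proteins
are overrepresented in the input set relative to all annotated proteins;
the network test replaces "annotated proteins" with "module members",
which lets it surface terms carried by none of the input proteins — the
added-value terms, flagged ``is_new_term``.

The tail probability is computed with exact integer arithmetic:

    p = sum_{j=k}^{min(K,n)} C(K,j) C(N-K,n-j) / C(N,n)

so results are reproducible to full float precision at any fixture
scale.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .modules import FunctionModule
from .ontology import AnnotationCorpus, OntologyDag

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for a one-sided overrepresentation test.

    N: universe size; K: universe proteins positive for the term;
    n: input proteins inside the universe; k: positive input proteins.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid contingency table {self}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"invalid contingency table {self}")


def fisher_upper_tail_fraction(table: ContingencyTable) -> Fraction:
    """Exact hypergeometric upper-tail probability P(X >= k) as a Fraction."""
    N, K, n, k = table.N, table.K, table.n, table.k
    numerator = sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    )
    return Fraction(numerator, math.comb(N, n))


def fisher_upper_tail(table: ContingencyTable) -> float:
    """One-sided Fisher (overrepresentation) p-value for *table*."""
    return float(fisher_upper_tail_fraction(table))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    mode: str  # "standard" | "network"
    table: ContingencyTable
    p_raw: float
    p_corrected: float
    is_new_term: bool
    members: tuple[str, ...]  # input proteins realizing k

    @property
    def sort_key(self):
        return (self.p_corrected, self.p_raw, self.term)


class ComparisonClass(enum.Enum):
    """Outcome classes when comparing standard vs network enrichment."""

    NONE_SIGNIFICANT = "none_significant"
    SAME_TERMS = "same_terms"
    NET_MORE_KNOWN_TERMS = "net_more_known_terms"
    NET_NEW_TERMS = "net_new_terms"


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def standard_enrichment(
    input_proteins: Iterable[str],
    corpus: AnnotationCorpus,
    alpha: float = 0.05,
    bonferroni: str = "tested",
) -> list[EnrichmentResult]:
    """Fisher overrepresentation of input proteins in propagated annotations.

    The universe is every protein with at least one annotation.  Terms
    with no overlapping input protein are not tested; the Bonferroni
    factor is the number of tested terms (``bonferroni="tested"``) or
    the number of annotated terms (``bonferroni="universe"``).
    Returns results with corrected p <= alpha, most significant first.
    """
    universe = corpus.proteins
    inp = frozenset(input_proteins) & universe
    if not inp:
        log.warning("no input protein has any annotation; empty result")
        return []
    candidates = {
        term: corpus.per_term[term] & inp
        for term in corpus.per_term
        if corpus.per_term[term] & inp
    }
    m = len(candidates) if bonferroni == "tested" else len(corpus.per_term)
    results = []
    for term, hits in candidates.items():
        table = ContingencyTable(
            N=len(universe), K=len(corpus.per_term[term]), n=len(inp), k=len(hits)
        )
        p = fisher_upper_tail(table)
        results.append(
            EnrichmentResult(
                term=term,
                mode="standard",
                table=table,
                p_raw=p,
                p_corrected=_bonferroni(p, m),
                is_new_term=False,
                members=tuple(sorted(hits)),
            )
        )
    results = [r for r in results if r.p_corrected <= alpha]
    results.sort(key=lambda r: r.sort_key)
    return results


def network_enrichment(
    input_proteins: Iterable[str],
    modules: dict[str, FunctionModule],
    corpus: AnnotationCorpus,
    alpha: float = 0.05,
    bonferroni: str = "tested",
) -> list[EnrichmentResult]:
    """Fisher overrepresentation of input proteins in module memberships.

    The universe is the union of all module member sets.  A result is
    flagged ``is_new_term`` when no input protein carries the term in
    its propagated annotations — the network method's added value.
    """
    universe: set[str] = set()
    for module in modules.values():
        universe |= module.members
    inp = frozenset(input_proteins) & universe
    if not inp:
        log.warning("no input protein belongs to any module; empty result")
        return []
    candidates = {
        term: modules[term].members & inp
        for term in modules
        if modules[term].members & inp
    }
    m = len(candidates) if bonferroni == "tested" else len(modules)
    input_annotations: set[str] = set()
    for p in input_proteins:
        input_annotations |= corpus.propagated.get(p, frozenset())
    results = []
    for term, hits in candidates.items():
        table = ContingencyTable(
            N=len(universe), K=len(modules[term].members), n=len(inp), k=len(hits)
        )
        p = fisher_upper_tail(table)
        results.append(
            EnrichmentResult(
                term=term,
                mode="network",
                table=table,
                p_raw=p,
                p_corrected=_bonferroni(p, m),
                is_new_term=term not in input_annotations,
                members=tuple(sorted(hits)),
            )
        )
    results = [r for r in results if r.p_corrected <= alpha]
    results.sort(key=lambda r: r.sort_key)
    return results


def deduplicate_ancestors(
    results: Sequence[EnrichmentResult],
    dag: OntologyDag,
    reference_set: Sequence[EnrichmentResult] | None = None,
) -> list[EnrichmentResult]:
    """Drop results whose term is a strict ancestor of a reference term.

    With ``reference_set=None`` the list is made non-redundant against
    itself (keep the most specific term on each ancestry path); with a
    reference set — typically the standard-enrichment results when
    evaluating the network results — any term that is an ancestor of a
    reference term is removed.  Order is preserved.
    """
    ref_terms = {r.term for r in (reference_set if reference_set is not None else results)}
    out = []
    for r in results:
        if any(r.term != t and dag.is_ancestor(r.term, t) for t in ref_terms):
            continue
        out.append(r)
    return out


def classify_comparison(
    se: Sequence[EnrichmentResult],
    ne: Sequence[EnrichmentResult],
    input_proteins: Iterable[str],
    corpus: AnnotationCorpus,
    dag: OntologyDag,
) -> ComparisonClass:
    """Classify a standard-vs-network comparison into one of four outcomes.

    A network term counts as *added* only if it is neither among the
    standard terms nor an ancestor of one.  Added terms absent from the
    propagated annotations of every input protein make the outcome
    ``NET_NEW_TERMS``; other added terms make it
    ``NET_MORE_KNOWN_TERMS``; no added terms and nothing significant at
    all is ``NONE_SIGNIFICANT``; otherwise ``SAME_TERMS``.
    """
    if not se and not ne:
        return ComparisonClass.NONE_SIGNIFICANT
    se_terms = {r.term for r in se}
    added = [
        r
        for r in deduplicate_ancestors(ne, dag, reference_set=se)
        if r.term not in se_terms
    ]
    input_annotations: set[str] = set()
    for p in input_proteins:
        input_annotations |= corpus.propagated.get(p, frozenset())
    if any(r.term not in input_annotations for r in added):
        return ComparisonClass.NET_NEW_TERMS
    if added:
        return ComparisonClass.NET_MORE_KNOWN_TERMS
    return ComparisonClass.SAME_TERMS


def results_to_tsv(
    results: Sequence[EnrichmentResult], dag: OntologyDag | None = None
) -> str:
    """Render results as the documented TSV (one row per term)."""
    header = (
        "term_id\tterm_name\tmode\tN\tK\tn\tk\tp_raw\tp_bonferroni\t"
        "is_new_term\tmember_ids"
    )
    rows = [header]
    for r in results:
        name = dag.names.get(r.term, "") if dag is not None else ""
        rows.append(
            "\t".join(
                [
                    r.term,
                    name,
                    r.mode,
                    str(r.table.N),
                    str(r.table.K),
                    str(r.table.n),
                    str(r.table.k),
                    f"{r.p_raw:.6g}",
                    f"{r.p_corrected:.6g}",
                    str(r.is_new_term).lower(),
                    ",".join(r.members),
                ]
            )
        )
    return "\n".join(rows) + "\n"
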
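"""The added-value mechanism: enriching a term no input protein carries.

The hand-built fixture contains six small function modules.  The query
is the two *connecting* proteins of the first module: they are not
annotated with the module's term, only with a common related term, so
annotation-based enrichment finds nothing.  Module-based enrichment
still places both query proteins inside the module and flags the
module's term as new.
"""

from netge import (
    build_added_value_fixture,
    build_all_modules,
    classify_comparison,
    network_enrichment,
    standard_enrichment,
)

net, dag, corpus, query, planted_term = build_added_value_fixture()
modules, _ = build_all_modules(net, corpus)
print(f"{len(modules)} modules accepted; query = {query}")
print(f"query annotations: {sorted(set().union(*(corpus.direct[p] for p in query)))}")

se = standard_enrichment(query, corpus)
ne = network_enrichment(query, modules, corpus)
print("standard enrichment results:", se)
for r in ne:
    print(
        f"network enrichment: {r.term}  p_bonf={r.p_corrected:.4f}  "
        f"new_term={r.is_new_term}"
    )
print("comparison class:", classify_comparison(se, ne, query, corpus, dag).value)
assert ne[0].term == planted_term and ne[0].is_new_term
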
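import io
import textwrap

import pytest
from hypothesis import HealthCheck, settings

from netge import load_annotations, load_obo
from netge.network import InteractionNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


CHAIN_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: test

    [Term]
    id: GO:0000001
    name: root

    [Term]
    id: GO:0000002
    name: A
    is_a: GO:0000001

    [Term]
    id: GO:0000003
    name: C
    is_a: GO:0000002
    """
)


@pytest.fixture
def chain_dag():
    """R <- A <- C chain ontology."""
    return load_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def chain_corpus(chain_dag):
    """10 proteins: |C|=2 (subset of A), |A|=5, |R|=10 after propagation."""
    rows = []
    for i in range(2):
        rows.append(f"p{i}\tGO:0000003")
    for i in range(2, 5):
        rows.append(f"p{i}\tGO:0000002")
    for i in range(5, 10):
        rows.append(f"p{i}\tGO:0000001")
    return load_annotations(io.StringIO("\n".join(rows)), chain_dag)


@pytest.fixture
def diamond_net():
    """s and t joined by two parallel 2-hop paths through u and v."""
    return InteractionNetwork.from_edges(
        [("s", "u"), ("u", "t"), ("s", "v"), ("v", "t")]
    )


@pytest.fixture
def detour_net():
    """Two length-2 paths (via u, v) plus one length-3 path (via w, x)."""
    return InteractionNetwork.from_edges(
        [("s", "u"), ("u", "t"), ("s", "v"), ("v", "t"), ("s", "w"), ("w", "x"), ("x", "t")]
    )
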
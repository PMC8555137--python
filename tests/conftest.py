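import math

import networkx as nx
import numpy as np
import pytest

from anchornet.network_io import Interaction, InteractionNetwork


@pytest.fixture
def toy_network():
    """a--x--t1, x--t2 plus direct shortcuts a--t1, a--t2.

    Confidences chosen so edge lengths are exactly 1 (edges via x) and 1.5
    (direct edges), giving the classic local/global trade-off: the direct
    edges shorten each terminal's path (1.5 < 2) at a higher per-terminal
    edge cost.
    """
    e = math.exp
    return InteractionNetwork([
        Interaction("a", "x", e(-1)),
        Interaction("x", "t1", e(-1)),
        Interaction("x", "t2", e(-1)),
        Interaction("a", "t1", e(-1.5)),
        Interaction("a", "t2", e(-1.5)),
    ])


def random_instance(rng, n_lo=5, n_hi=12, p=0.3, p_dense_cap=0.2,
                    alphas=(0.0, 0.25, 0.5)):
    """One random small query instance (or None if infeasible)."""
    from anchornet.errors import QueryError
    from anchornet.reconstruct import QueryInstance

    n = int(rng.integers(n_lo, n_hi + 1))
    prob = p if n <= 11 else p_dense_cap
    g = nx.gnp_random_graph(n, prob, seed=int(rng.integers(2**31 - 1)))
    net = InteractionNetwork(nodes=[f"v{i}" for i in range(n)])
    for u, v in g.edges:
        net.add_interaction(Interaction(
            f"v{u}", f"v{v}", float(rng.uniform(0.05, 1.0))))
    na = int(rng.integers(1, 3))
    nt = int(rng.integers(1, 4))
    if na + nt > n:
        return None
    pick = list(rng.choice(n, size=na + nt, replace=False))
    anchors = {f"v{i}" for i in pick[:na]}
    terminals = {f"v{i}" for i in pick[na:]}
    alpha = alphas[int(rng.integers(len(alphas)))]
    try:
        return QueryInstance(net, anchors, terminals, alpha)
    except QueryError:
        return None


@pytest.fixture(scope="session")
def small_corpus():
    """One deterministic synthetic corpus shared by the slower ML tests."""
    from anchornet.benchmark import BenchmarkConfig, generate_corpus

    return generate_corpus(BenchmarkConfig(seed=0))


KGML_FIXTURE = """<?xml version="1.0"?>
<pathway name="path:toy01" org="toy" number="01" title="Toy signaling">
  <entry id="1" name="toy:A" type="gene"/>
  <entry id="2" name="toy:B" type="gene"/>
  <entry id="3" name="cpd:C00001" type="compound"/>
  <entry id="4" name="toy:D" type="gene"/>
  <entry id="5" name="toy:E" type="gene"/>
  <entry id="6" name="undefined" type="group">
    <component id="4"/>
    <component id="5"/>
  </entry>
  <entry id="7" name="toy:F" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel"/>
  <relation entry1="2" entry2="3" type="PCrel"/>
  <relation entry1="3" entry2="7" type="PCrel"/>
  <relation entry1="2" entry2="6" type="PPrel"/>
  <relation entry1="6" entry2="7" type="PPrel"/>
</pathway>
"""

OBO_FIXTURE = """format-version: 1.2

[Term]
id: MI:0001
name: interaction detection method

[Term]
id: MI:0045
name: experimental interaction detection
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0401
name: biochemical
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0090
name: protein complementation assay
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0018
name: two hybrid
is_a: MI:0090 ! protein complementation assay

[Term]
id: MI:0006
name: anti bait coimmunoprecipitation
is_a: MI:0401 ! biochemical
is_a: MI:0090 ! protein complementation assay
"""


@pytest.fixture
def kgml_file(tmp_path):
    path = tmp_path / "toy.kgml"
    path.write_text(KGML_FIXTURE)
    return path


@pytest.fixture
def obo_file(tmp_path):
    path = tmp_path / "mi.obo"
    path.write_text(OBO_FIXTURE)
    return path


@pytest.fixture
def ontology(obo_file):
    from anchornet.network_io import MethodOntology

    return MethodOntology.from_obo(obo_file)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
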
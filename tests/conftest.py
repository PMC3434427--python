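import random

import pytest

from ontoir import Concept, OntologyDAG, intrinsic_ic, t8_dag

T8_OBO = """\
format-version: 1.2
ontology: t8-demo

[Term]
id: R
name: root

[Term]
id: A
name: branch a
is_a: R

[Term]
id: B
name: branch b
is_a: R

[Term]
id: A1
name: a one
is_a: A

[Term]
id: A2
name: a two
is_a: A

[Term]
id: A1a
name: a one a
is_a: A1

[Term]
id: A1b
name: a one b
is_a: A1

[Term]
id: B1
name: b one
is_a: B
"""


@pytest.fixture(scope="session")
def t8():
    return t8_dag()


@pytest.fixture(scope="session")
def t8_ic(t8):
    return intrinsic_ic(t8)


@pytest.fixture
def t8_obo_path(tmp_path):
    path = tmp_path / "t8.obo"
    path.write_text(T8_OBO)
    return path


def random_dag(rng: random.Random, n_concepts: int, extra_edge_prob: float = 0.3) -> OntologyDAG:
    """Random single-rooted DAG: a spanning tree plus extra child->ancestor edges.

    Extra edges go from a node to a non-descendant with larger topological
    rank reversed — i.e. each node may gain additional parents among earlier
    nodes — keeping the graph acyclic and single-rooted.
    """
    ids = [f"N{i:02d}" for i in range(n_concepts)]
    edges = set()
    for i in range(1, n_concepts):
        parent = ids[rng.randrange(i)]
        edges.add((ids[i], parent))
    for i in range(2, n_concepts):
        if rng.random() < extra_edge_prob:
            parent = ids[rng.randrange(1, i)]
            edges.add((ids[i], parent))
    return OntologyDAG([Concept(id=c) for c in ids], sorted(edges))


def closure_matrix(dag: OntologyDAG):
    """Brute-force reachability oracle: iterate one-step expansion to fixpoint.

    Returns reach[c] = set of concepts reachable from c along child->parent
    edges (i.e. the strict-ancestor closure), computed without networkx.
    """
    nodes = sorted(dag.graph.nodes)
    parents = {c: set(dag.graph.successors(c)) for c in nodes}
    reach = {c: set(parents[c]) for c in nodes}
    changed = True
    while changed:
        changed = False
        for c in nodes:
            new = set()
            for p in reach[c]:
                new |= parents[p]
            if not new <= reach[c]:
                reach[c] |= new
                changed = True
    return reach
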
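"""Concept–concept proximity and distance measures.

Three proximities in [0, 1] are usable for retrieval scoring:

* ``jaccard`` — overlap of the two concepts' reflexive hyponym sets, gated
  to 0 unless one concept subsumes the other.  Cheap, and directly
  interpretable: >0 exactly when a hyponym/hypernym substitution happened.
* ``lin`` — 2·IC(MICA)/(IC(C1)+IC(C2)), the IC-normalised common-ancestor
  similarity (the default measure).
* ``resnik`` — IC(MICA) alone; bounded by 1 when the intrinsic IC is used.

Two graph distances are provided for comparison but deliberately kept out
of the retrieval pipeline (they are distances, not [0,1] proximities):

* ``path_penalized`` — shortest undirected is-a path where every change of
  direction (up vs down) costs an extra K.
* ``isa`` — a descendant-set distance satisfying the metric axioms.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List

from .errors import ContractError, NoPathError
from .ontology import ICTable, OntologyDAG, mica

PROXIMITY_MEASURES = ("jaccard", "lin", "resnik")


@dataclass
class SimilarityConfig:
    """Which proximity retrieval uses, and with which IC table."""

    measure: str = "lin"
    direction_change_penalty: float = 0.0  # the K factor for the path distance
    ic_mode: str = "intrinsic"

    def __post_init__(self):
        if self.measure not in PROXIMITY_MEASURES + ("path_penalized", "d_isa"):
            raise ContractError(f"unknown measure {self.measure!r}")
        if self.direction_change_penalty < 0:
            raise ContractError("direction change penalty K must be >= 0")
        if self.ic_mode not in ("intrinsic", "corpus"):
            raise ContractError(f"unknown ic_mode {self.ic_mode!r}")


@dataclass
class IsaPath:
    """An undirected is-a path with its edge count and direction changes."""

    nodes: List[str]
    length: int
    direction_changes: int


def prox_jaccard(dag: OntologyDAG, c1: str, c2: str) -> float:
    """Jaccard overlap of reflexive hyponym sets, 0 without a hyponym relation.

    Equals 1 iff the concepts are identical; symmetric; in [0, 1].
    """
    h1 = dag.reflexive_hyponyms([c1])
    h2 = dag.reflexive_hyponyms([c2])
    if c1 not in h2 and c2 not in h1:
        return 0.0
    return len(h1 & h2) / len(h1 | h2)


def prox_lin(dag: OntologyDAG, ic: ICTable, c1: str, c2: str) -> float:
    """IC-normalised common-ancestor proximity: 2·IC(MICA)/(IC(C1)+IC(C2)).

    The degenerate 0/0 case (both arguments are the root) is defined as 1
    for identical concepts and 0 otherwise, preserving the "=1 iff equal"
    convention.
    """
    denom = ic[c1] + ic[c2]
    if denom == 0.0:
        return 1.0 if c1 == c2 else 0.0
    m = mica(dag, ic, c1, c2)
    return 2.0 * ic[m] / denom


def prox_resnik(dag: OntologyDAG, ic: ICTable, c1: str, c2: str) -> float:
    """IC of the most informative common ancestor (in [0,1] for intrinsic IC)."""
    return ic[mica(dag, ic, c1, c2)]


def dist_path_penalized(dag: OntologyDAG, c1: str, c2: str, K: float = 0.0) -> float:
    """Shortest undirected is-a path, charging K per change of direction.

    A path segment climbing towards ancestors is "up", one descending is
    "down"; every up/down flip within the path adds K to its cost, so large
    K forces paths through a single common ancestor or descendant.  With
    K = 0 this is the plain shortest-path distance.

    Implemented as Dijkstra over (concept, arrival-direction) states; the
    distance is exact without enumerating paths.
    """
    if K < 0:
        raise ContractError("K must be >= 0")
    dag._check(c1)
    dag._check(c2)
    if c1 == c2:
        return 0.0
    g = dag.graph  # edges child -> parent
    # state: (cost, node, direction) with direction in {"up", "down"}
    heap = [(0.0, c1, None)]
    best = {}
    while heap:
        cost, node, direction = heapq.heappop(heap)
        if node == c2:
            return cost
        key = (node, direction)
        if key in best and best[key] <= cost:
            continue
        best[key] = cost
        for parent in g.successors(node):  # climb: direction "up"
            step = cost + 1.0 + (K if direction == "down" else 0.0)
            if best.get((parent, "up"), float("inf")) > step:
                heapq.heappush(heap, (step, parent, "up"))
        for child in g.predecessors(node):  # descend: direction "down"
            step = cost + 1.0 + (K if direction == "up" else 0.0)
            if best.get((child, "down"), float("inf")) > step:
                heapq.heappush(heap, (step, child, "down"))
    raise NoPathError(f"{c1!r} and {c2!r} are not connected in the is-a graph")


def dist_isa(dag: OntologyDAG, c1: str, c2: str) -> int:
    """Descendant-set distance on the is-a graph.

    |hypo(ancEx(C1,C2)) ∪ hypo({C1}) ∪ hypo({C2})| − |hypo({C1}) ∩ hypo({C2})|
    with reflexive hyponym sets.  Zero iff the concepts coincide; symmetric.
    """
    h1 = dag.reflexive_hyponyms([c1])
    h2 = dag.reflexive_hyponyms([c2])
    h_ancex = dag.reflexive_hyponyms(dag.exclusive_ancestors(c1, c2))
    return len(h_ancex | h1 | h2) - len(h1 & h2)


def pairwise_similarity(dag, ic, pairs, measure: str, K: float = 0.0):
    """Batch evaluation: yield (c1, c2, measure, value) rows for a TSV export."""
    for c1, c2 in pairs:
        if measure == "jaccard":
            v = prox_jaccard(dag, c1, c2)
        elif measure == "lin":
            v = prox_lin(dag, ic, c1, c2)
        elif measure == "resnik":
            v = prox_resnik(dag, ic, c1, c2)
        elif measure == "path_penalized":
            v = dist_path_penalized(dag, c1, c2, K)
        elif measure == "d_isa":
            v = dist_isa(dag, c1, c2)
        else:
            raise ContractError(f"unknown measure {measure!r}")
        yield (c1, c2, measure, v)


def proximity(dag: OntologyDAG, ic: ICTable, c1: str, c2: str, cfg: SimilarityConfig) -> float:
    """Dispatch to the configured [0,1] proximity (the retrieval entry point)."""
    if cfg.measure == "jaccard":
        return prox_jaccard(dag, c1, c2)
    if cfg.measure == "lin":
        return prox_lin(dag, ic, c1, c2)
    if cfg.measure == "resnik":
        return prox_resnik(dag, ic, c1, c2)
    raise ContractError(
        f"measure {cfg.measure!r} is a distance, not a [0,1] proximity; "
        f"retrieval accepts one of {PROXIMITY_MEASURES}"
    )
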
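"""Is-a ontology model: DAG set algebra and information-content tables.

The ontology is the backbone of concept-based retrieval: a single-rooted
directed acyclic graph whose edges are subsumption (*is-a*) relations, as in
the Gene Ontology or MeSH.  This module loads OBO flat files, exposes the
hyponym/ancestor set algebra that every proximity measure is built on, and
computes per-concept information content (IC) either intrinsically (from the
DAG shape alone) or extensionally (from annotation frequencies in a corpus).

Conventions
-----------
* *strict* hyponyms/ancestors exclude the concept itself; *reflexive* sets
  include it.  Proximity measures on descendant overlap use the reflexive
  sets; the intrinsic IC formula counts strict hyponyms (which is what pins
  the root at 0 and leaves at 1).
* Edges are stored child -> parent, so graph-descendants are ancestors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Set

import networkx as nx
import obonet

from .errors import (
    DegenerateOntologyError,
    EmptyOntologyError,
    FormatError,
    LookupError_,
    NoCommonAncestorError,
    StructuralError,
)

logger = logging.getLogger(__name__)

ARTIFICIAL_ROOT = "ONTOIR:ROOT"


@dataclass(frozen=True)
class Concept:
    """A single ontology concept (a CURIE-style id plus its label)."""

    id: str
    name: str = ""
    obsolete: bool = False


@dataclass
class LoaderConfig:
    """Options for :func:`load_obo`.

    include_part_of
        Also follow ``relationship: part_of`` edges (off by default: the
        subsumption backbone is the only relation shared by all ontologies).
    allow_multiroot
        Join multiple namespace roots under an artificial root instead of
        rejecting the file; needed e.g. for the full Gene Ontology with its
        three namespaces.
    """

    include_part_of: bool = False
    allow_multiroot: bool = False


class OntologyDAG:
    """Concepts plus acyclic is-a edges, with cached descendant set algebra.

    Parameters
    ----------
    concepts
        Concept records; obsolete ones may be present but carry no edges and
        are excluded from ``max_con``.
    isa_edges
        ``(child_id, parent_id)`` pairs.  The resulting graph must be acyclic
        and single-rooted.
    """

    def __init__(self, concepts: Iterable[Concept], isa_edges: Iterable[tuple]):
        self.concepts: Dict[str, Concept] = {}
        for c in concepts:
            if c.id in self.concepts:
                raise StructuralError(f"duplicate concept id {c.id!r}")
            self.concepts[c.id] = c
        active = [cid for cid, c in self.concepts.items() if not c.obsolete]
        if not active:
            raise EmptyOntologyError("ontology has no non-obsolete concepts")

        g = nx.DiGraph()
        g.add_nodes_from(active)
        for child, parent in isa_edges:
            for cid in (child, parent):
                if cid not in self.concepts:
                    raise LookupError_(f"edge references unknown concept {cid!r}")
                if self.concepts[cid].obsolete:
                    raise StructuralError(f"obsolete concept {cid!r} carries an is-a edge")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise StructuralError(f"is-a relation contains a cycle: {cycle}")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise StructuralError(
                f"ontology must have exactly one root, found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )
        self.graph = g  # edges child -> parent
        self.root: str = roots[0]
        self._hypo_cache: Dict[str, FrozenSet[str]] = {}
        self._anc_cache: Dict[str, FrozenSet[str]] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def max_con(self) -> int:
        """Number of non-obsolete concepts (the ontology size used by IC)."""
        return self.graph.number_of_nodes()

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.graph

    def __len__(self) -> int:
        return self.max_con

    def _check(self, concept_id: str) -> None:
        if concept_id not in self.graph:
            raise LookupError_(f"unknown concept id {concept_id!r}")

    # -- set algebra -------------------------------------------------------

    def strict_hyponyms(self, concept_id: str) -> FrozenSet[str]:
        """All concepts reachable by reversed is-a edges, excluding the concept."""
        self._check(concept_id)
        cached = self._hypo_cache.get(concept_id)
        if cached is None:
            cached = frozenset(nx.ancestors(self.graph, concept_id))
            self._hypo_cache[concept_id] = cached
        return cached

    def reflexive_hyponyms(self, concept_ids: Iterable[str]) -> FrozenSet[str]:
        """hypo(S): every concept that is a (reflexive) hyponym of some member of S."""
        out: Set[str] = set()
        for cid in concept_ids:
            out.add(cid)
            out |= self.strict_hyponyms(cid)
        return frozenset(out)

    def strict_ancestors(self, concept_id: str) -> FrozenSet[str]:
        """All concepts reachable by is-a edges, excluding the concept itself."""
        self._check(concept_id)
        cached = self._anc_cache.get(concept_id)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, concept_id))
            self._anc_cache[concept_id] = cached
        return cached

    def reflexive_ancestors(self, concept_id: str) -> FrozenSet[str]:
        return self.strict_ancestors(concept_id) | {concept_id}

    def exclusive_ancestors(self, c1: str, c2: str) -> FrozenSet[str]:
        """ancEx: strict ancestors of either concept but not of both."""
        return self.strict_ancestors(c1) ^ self.strict_ancestors(c2)

    def leaves(self) -> FrozenSet[str]:
        return frozenset(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)


# -- OBO loading ----------------------------------------------------------


def load_obo(path, config: LoaderConfig | None = None) -> OntologyDAG:
    """Load an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Only ``is_a`` edges are kept (``relationship: part_of`` too if enabled);
    obsolete terms are recorded but stripped of edges and excluded from
    ``max_con``.  Multi-rooted files are rejected unless
    ``config.allow_multiroot`` joins the roots under an artificial one.
    """
    config = config or LoaderConfig()
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError/KeyError
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc
    if raw.number_of_nodes() == 0:
        raise EmptyOntologyError(f"OBO file {path} defines no terms")

    concepts = []
    obsolete_ids = set()
    for node, data in raw.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        if obsolete:
            obsolete_ids.add(node)
        concepts.append(Concept(id=node, name=data.get("name", ""), obsolete=obsolete))
    if obsolete_ids:
        logger.warning("dropping %d obsolete term(s) from the DAG", len(obsolete_ids))

    wanted = {"is_a"} | ({"part_of"} if config.include_part_of else set())
    edges = []
    dropped_rels = set()
    for child, parent, rel in raw.edges(keys=True):
        if child in obsolete_ids or parent in obsolete_ids:
            continue
        if rel in wanted:
            edges.append((child, parent))
        else:
            dropped_rels.add(rel)
    if dropped_rels:
        logger.warning("ignoring relationship type(s): %s", ", ".join(sorted(dropped_rels)))

    # multiroot handling needs a peek at root count before constructing
    g = nx.DiGraph()
    g.add_nodes_from(n for n in raw.nodes if n not in obsolete_ids)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise StructuralError(f"is-a relation in {path} contains a cycle")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) > 1:
        if not config.allow_multiroot:
            raise StructuralError(
                f"{path} has {len(roots)} roots; pass allow_multiroot to join them"
            )
        concepts.append(Concept(id=ARTIFICIAL_ROOT, name="artificial root"))
        edges.extend((r, ARTIFICIAL_ROOT) for r in roots)
        logger.warning("joined %d roots under %s", len(roots), ARTIFICIAL_ROOT)
    return OntologyDAG(concepts, edges)


# -- information content ---------------------------------------------------


@dataclass
class ICTable:
    """Per-concept information content.

    ``intrinsic`` mode values lie in [0, 1] (0 at the root, 1 at leaves);
    ``corpus`` mode values are -log annotation probabilities in [0, +inf),
    natural log.
    """

    mode: str
    values: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, concept_id: str) -> float:
        try:
            return self.values[concept_id]
        except KeyError:
            raise LookupError_(f"no IC value for concept {concept_id!r}") from None

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.values

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mode: {self.mode}\n")
            for cid in sorted(self.values):
                fh.write(f"{cid}\t{self.values[cid]:.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "ICTable":
        mode = "intrinsic"
        values: Dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if "mode:" in line:
                        mode = line.split("mode:", 1)[1].strip()
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
                try:
                    values[parts[0]] = float(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad IC value {parts[1]!r}") from exc
        return cls(mode=mode, values=values)


def intrinsic_ic(dag: OntologyDAG) -> ICTable:
    """Intrinsic IC: 1 - log(|strict hyponyms| + 1) / log(max_con).

    A concept's specificity is inversely proportional to the number of
    concepts it subsumes, so the root scores 0 and every leaf scores 1.
    The log base cancels in the ratio.
    """
    n = dag.max_con
    if n < 2:
        raise DegenerateOntologyError(
            f"intrinsic IC undefined for an ontology of {n} concept(s)"
        )
    log_n = math.log(n)
    values = {
        cid: 1.0 - math.log(len(dag.strict_hyponyms(cid)) + 1) / log_n
        for cid in dag.graph.nodes
    }
    return ICTable(mode="intrinsic", values=values)


def corpus_ic(dag: OntologyDAG, corpus) -> ICTable:
    """Corpus IC: -log P(C), where P(C) is the fraction of documents
    annotated by C or one of its strict hyponyms.

    Concepts never seen in the corpus get probability 1/(2N) (add-half
    smoothing) rather than infinite IC, which keeps Resnik/Lin finite.
    """
    n_docs = len(corpus.documents)
    if n_docs == 0:
        raise DegenerateOntologyError("corpus IC requires a non-empty corpus")
    # annotation sets per doc, resolved once
    doc_sets = [frozenset(rec.annotation) for rec in corpus.documents.values()]
    floor = 1.0 / (2.0 * n_docs)
    values: Dict[str, float] = {}
    for cid in dag.graph.nodes:
        closure = dag.reflexive_hyponyms([cid])
        hits = sum(1 for s in doc_sets if s & closure)
        p = hits / n_docs if hits else floor
        values[cid] = -math.log(p)
    return ICTable(mode="corpus", values=values)


def mica(dag: OntologyDAG, ic: ICTable, c1: str, c2: str) -> str:
    """Most informative common ancestor of two concepts.

    Considers reflexive ancestors (a concept is its own ancestor here, so
    mica(C, C) = C).  Ties on IC break lexicographically by id for
    determinism.
    """
    common = dag.reflexive_ancestors(c1) & dag.reflexive_ancestors(c2)
    if not common:
        raise NoCommonAncestorError(f"{c1!r} and {c2!r} share no ancestor")
    return min(common, key=lambda cid: (-ic[cid], cid))


# module-level functional aliases matching the operation names
def strict_hyponyms(dag: OntologyDAG, c: str) -> FrozenSet[str]:
    return dag.strict_hyponyms(c)


def reflexive_hyponyms(dag: OntologyDAG, s: Iterable[str]) -> FrozenSet[str]:
    return dag.reflexive_hyponyms(s)


def strict_ancestors(dag: OntologyDAG, c: str) -> FrozenSet[str]:
    return dag.strict_ancestors(c)


def exclusive_ancestors(dag: OntologyDAG, c1: str, c2: str) -> FrozenSet[str]:
    return dag.exclusive_ancestors(c1, c2)
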
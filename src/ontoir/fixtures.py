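"""Deterministic synthetic ontologies, corpora, queries and judgements.

Real evaluation collections for concept-based retrieval (MeSH-indexed
abstract sets, GO-annotated genomes) are external and large, so the test
and benchmark inputs here are generated: a random single-rooted is-a tree,
documents annotated with small concept sets, and topics whose relevant
documents are *planted* — some annotated with exact query concepts, some
only with hyponyms (or hypernyms) of them.  The hyponym-only documents
realise the silence scenario: invisible to verbatim Boolean matching,
retrievable through semantic proximity.

Everything is emitted in the package's external formats (OBO, TSV, query
JSON, TREC qrels) so fixtures exercise the parsers end to end, and every
generator is a pure function of its spec and seed.

The canonical 8-concept "T8" ontology used throughout the documentation::

        R
       / \\
      A   B
     / \\   \\
    A1  A2  B1
   /  \\
  A1a  A1b
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

from .corpus import CorpusIndex, DocumentRecord
from .errors import ContractError
from .evaluation import Qrels
from .ontology import Concept, OntologyDAG
from .retrieval import Query

T8_EDGES = [
    ("A", "R"), ("B", "R"),
    ("A1", "A"), ("A2", "A"),
    ("A1a", "A1"), ("A1b", "A1"),
    ("B1", "B"),
]


def t8_dag() -> OntologyDAG:
    """The canonical 8-concept documentation ontology."""
    ids = ["R", "A", "B", "A1", "A2", "A1a", "A1b", "B1"]
    return OntologyDAG([Concept(id=i, name=f"concept {i}") for i in ids], T8_EDGES)


def dag_to_obo(dag: OntologyDAG, path) -> None:
    """Serialise a DAG as a minimal OBO 1.2 flat file (deterministic order)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic-fixture\n")
        for cid in sorted(dag.concepts):
            concept = dag.concepts[cid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {cid}\n")
            if concept.name:
                fh.write(f"name: {concept.name}\n")
            if concept.obsolete:
                fh.write("is_obsolete: true\n")
                continue
            for parent in sorted(dag.graph.successors(cid)):
                fh.write(f"is_a: {parent}\n")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic benchmark bundle.

    The defaults describe a small but non-trivial collection: a 120-concept
    tree, 200 documents carrying 2–4 annotations, and 10 topics whose
    relevant documents split evenly between exact-annotated and
    hyponym-only (the silence case); no hypernym-only or merely-random
    relevant documents.  ``relevance_plan`` gives the (exact, hyponym-only,
    hypernym-only, random) proportions of each topic's document block.
    """

    n_concepts: int = 120
    max_children: int = 4
    n_docs: int = 200
    annotations_per_doc: Tuple[int, int] = (2, 4)
    n_queries: int = 10
    relevance_plan: Tuple[float, float, float, float] = (0.5, 0.5, 0.0, 0.0)
    seed: int = 0
    max_concepts_per_query: int = 3

    def __post_init__(self):
        if self.n_concepts < 2:
            raise ContractError("need at least 2 concepts")
        if min(self.max_children, self.n_docs, self.n_queries) < 1:
            raise ContractError("counts must be positive")
        lo, hi = self.annotations_per_doc
        if not (1 <= lo <= hi):
            raise ContractError("annotations_per_doc must be a valid positive range")
        if any(p < 0 for p in self.relevance_plan):
            raise ContractError("relevance plan proportions must be non-negative")
        if abs(sum(self.relevance_plan) - 1.0) > 1e-9:
            raise ContractError("relevance plan proportions must sum to 1")


def _concept_id(i: int) -> str:
    return f"T:{i:04d}"


def generate_dag(spec: FixtureSpec) -> OntologyDAG:
    """Random single-rooted tree with at most ``max_children`` per node."""
    rng = random.Random(spec.seed)
    ids = [_concept_id(i) for i in range(1, spec.n_concepts + 1)]
    children_count = {ids[0]: 0}
    edges = []
    for cid in ids[1:]:
        candidates = sorted(n for n, k in children_count.items() if k < spec.max_children)
        parent = rng.choice(candidates)
        children_count[parent] += 1
        children_count[cid] = 0
        edges.append((cid, parent))
    return OntologyDAG([Concept(id=i, name=f"synthetic concept {i}") for i in ids], edges)


def generate_corpus(dag: OntologyDAG, spec: FixtureSpec) -> CorpusIndex:
    """Documents with uniform-random concept annotations of bounded size."""
    rng = random.Random(spec.seed + 1)
    concepts = sorted(dag.graph.nodes)
    lo, hi = spec.annotations_per_doc
    index = CorpusIndex()
    for i in range(1, spec.n_docs + 1):
        k = min(rng.randint(lo, hi), len(concepts))
        annotation = set(rng.sample(concepts, k))
        index.add(DocumentRecord(doc_id=f"d{i:04d}", annotation=annotation))
    return index


def _select_query_concepts(dag, candidates, rng, spec):
    """Pick per-query concept sets with pairwise-disjoint hyponym subtrees.

    Disjoint subtrees make cross-topic documents incomparable to a topic's
    concepts, which is what turns the planted relevance into a guarantee
    rather than a tendency.
    """
    claimed: set = set()
    queries: List[List[str]] = []
    pool = candidates[:]
    rng.shuffle(pool)
    it = iter(pool)
    for _ in range(spec.n_queries):
        want = rng.randint(1, spec.max_concepts_per_query)
        chosen: List[str] = []
        for cid in it:
            subtree = dag.reflexive_hyponyms([cid])
            if subtree & claimed:
                continue
            chosen.append(cid)
            claimed |= subtree
            if len(chosen) == want:
                break
        if not chosen:
            raise ContractError("ontology too small for the requested topic count")
        queries.append(chosen)
    return queries


def generate_topics(
    dag: OntologyDAG, corpus: CorpusIndex, spec: FixtureSpec, max_retries: int = 20
) -> Tuple[Dict[str, Query], Qrels]:
    """Sample topics and plant their relevant documents into the corpus.

    Each topic gets 1..3 query concepts, each with at least one strict
    hyponym and a hyponym subtree disjoint from every other topic's.  The
    corpus is split into equal per-topic blocks; within a block the
    relevance plan decides how many documents are re-annotated to contain
    an exact query concept, only strict hyponyms of one, or only strict
    ancestors.  All remaining documents (the plan's "random" share and any
    leftover) are re-annotated from a background pool of concepts that are
    comparable to no topic concept, so a document is relevant to a topic
    exactly when it was planted for it.  The corpus is modified in place.

    Retries with fresh topic draws (bounded) if a draw is infeasible, e.g.
    a hypernym share was requested for a concept whose only ancestor is
    the root.
    """
    candidates = sorted(
        cid
        for cid in dag.graph.nodes
        if cid != dag.root and dag.strict_hyponyms(cid)
    )
    if not candidates:
        raise ContractError("no concept with a strict hyponym; enlarge the ontology")
    last_err = None
    for attempt in range(max_retries):
        rng = random.Random(spec.seed + 2 + 1000 * attempt)
        try:
            return _plant(dag, corpus, spec, rng, candidates)
        except ContractError as err:
            last_err = err
    raise ContractError(f"could not realise the relevance plan: {last_err}")


def _plant(dag, corpus, spec, rng, candidates):
    query_concepts = _select_query_concepts(dag, candidates, rng, spec)
    forbidden = set()
    for concepts in query_concepts:
        for cid in concepts:
            forbidden |= dag.reflexive_hyponyms([cid])
            forbidden |= dag.strict_ancestors(cid)
    background = sorted(set(dag.graph.nodes) - forbidden)
    if not background:
        raise ContractError("no background concepts incomparable to all topics")

    doc_ids = sorted(corpus.documents)
    block = len(doc_ids) // spec.n_queries
    if block < 1:
        raise ContractError("fewer documents than topics")
    p_exact, p_hypo, p_hyper, _ = spec.relevance_plan
    lo, hi = spec.annotations_per_doc

    def background_annotation():
        k = min(rng.randint(lo, hi), len(background))
        return set(rng.sample(background, k))

    queries: Dict[str, Query] = {}
    relevant: Dict[str, set] = {}
    planted: set = set()
    for qi, concepts in enumerate(query_concepts):
        qid = f"q{qi + 1:02d}"
        queries[qid] = Query(terms=[(cid, 1.0) for cid in concepts])
        relevant[qid] = set()
        block_docs = doc_ids[qi * block : (qi + 1) * block]
        # cumulative rounding so the three planted shares never exceed the block
        n_exact = round(p_exact * block)
        n_hypo = round((p_exact + p_hypo) * block) - n_exact
        n_hyper = round((p_exact + p_hypo + p_hyper) * block) - n_exact - n_hypo
        cursor = 0
        for j in range(n_exact):
            doc_id = block_docs[cursor]; cursor += 1
            qt = concepts[j % len(concepts)]
            ann = {qt} | set(rng.sample(background, min(rng.randint(0, 2), len(background))))
            corpus.documents[doc_id].annotation = ann
            relevant[qid].add(doc_id); planted.add(doc_id)
        for j in range(n_hypo):
            doc_id = block_docs[cursor]; cursor += 1
            qt = concepts[j % len(concepts)]
            hypos = sorted(dag.strict_hyponyms(qt))
            k = min(rng.randint(1, 2), len(hypos))
            ann = set(rng.sample(hypos, k))
            ann |= set(rng.sample(background, min(rng.randint(0, 2), len(background))))
            corpus.documents[doc_id].annotation = ann
            relevant[qid].add(doc_id); planted.add(doc_id)
        for j in range(n_hyper):
            doc_id = block_docs[cursor]; cursor += 1
            qt = concepts[j % len(concepts)]
            safe_anc = sorted(dag.strict_ancestors(qt) - forbidden_others(dag, query_concepts, qi) - {dag.root})
            if not safe_anc:
                raise ContractError(f"no usable strict ancestor for {qt!r}")
            ann = set(rng.sample(safe_anc, min(rng.randint(1, 2), len(safe_anc))))
            corpus.documents[doc_id].annotation = ann
            relevant[qid].add(doc_id); planted.add(doc_id)
    # everything not planted becomes background-only, hence irrelevant everywhere
    for doc_id in doc_ids:
        if doc_id not in planted:
            corpus.documents[doc_id].annotation = background_annotation()
    corpus.rebuild_inverted()
    return queries, Qrels(relevant=relevant)


def forbidden_others(dag, query_concepts, qi):
    """Concepts comparable to some *other* topic's concepts."""
    out = set()
    for qj, concepts in enumerate(query_concepts):
        if qj == qi:
            continue
        for cid in concepts:
            out |= dag.reflexive_hyponyms([cid])
            out |= dag.strict_ancestors(cid)
    return out


def generate_bundle(spec: FixtureSpec, outdir) -> dict:
    """Emit a complete benchmark bundle to ``outdir``.

    Files: ``fixture.obo``, ``corpus.tsv``, ``queries/<qid>.json``,
    ``qrels.txt`` and ``manifest.json``.  Same spec (and seed) → byte-
    identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag = generate_dag(spec)
    corpus = generate_corpus(dag, spec)
    queries, qrels = generate_topics(dag, corpus, spec)

    dag_to_obo(dag, outdir / "fixture.obo")
    corpus.to_tsv(outdir / "corpus.tsv")
    qdir = outdir / "queries"
    qdir.mkdir(exist_ok=True)
    for qid in sorted(queries):
        queries[qid].to_json(qdir / f"{qid}.json")
    qrels.to_trec(outdir / "qrels.txt")
    manifest = {
        "n_concepts": spec.n_concepts,
        "max_children": spec.max_children,
        "n_docs": spec.n_docs,
        "annotations_per_doc": list(spec.annotations_per_doc),
        "n_queries": spec.n_queries,
        "relevance_plan": list(spec.relevance_plan),
        "seed": spec.seed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"dag": dag, "corpus": corpus, "queries": queries, "qrels": qrels}
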
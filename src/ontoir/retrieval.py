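"""Three-stage relevance scoring (Retrieval Status Value, RSV).

Stage 1 is a concept–concept proximity (see :mod:`ontoir.similarity`).
Stage 2 lifts it to a concept–document proximity with the max operator:
a query concept matches a document as well as its best-matching annotation
concept.  This asymmetry is deliberate — a document is never penalised for
carrying annotations outside the query.  Stage 3 aggregates the per-query-
concept scores u_t into one RSV with the weighted Yager power mean

    RSV = ( sum_t p_t · u_t^q )^(1/q),    sum_t p_t = 1,

a compromise operator: min(u) <= RSV <= max(u) for every finite q.  The
exponent q is the user's AND/OR cursor — q → −∞ is a strict conjunction
(min), q → +∞ a disjunction (max), q = 1 the arithmetic and q → 0 the
geometric mean.

Each scored document keeps one :class:`ElementaryMatch` per query concept
(best annotation concept, proximity, and whether it was an exact, hyponym,
hypernym or unrelated match) so a result can always be explained.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from lxml import etree

from .corpus import CorpusIndex, DocumentRecord
from .errors import ContractError, FormatError, QueryValidationError
from .ontology import ICTable, OntologyDAG
from .similarity import SimilarityConfig, proximity

WEIGHT_TOL = 1e-9

# tie-break priority among equal-proximity document concepts
_RELATION_RANK = {"exact": 0, "hyponym": 1, "hypernym": 2, "other": 3}


@dataclass
class Query:
    """Weighted query concepts.

    Raw weights may be on any non-negative scale (e.g. 100 vs 50); they are
    normalised internally so only ratios matter.
    """

    terms: List[Tuple[str, float]]

    def __post_init__(self):
        if not self.terms:
            raise ContractError("query must have at least one concept")
        ids = [cid for cid, _ in self.terms]
        if len(set(ids)) != len(ids):
            raise ContractError("duplicate concept ids in query")
        if any(w < 0 for _, w in self.terms):
            raise ContractError("query weights must be non-negative")
        total = sum(w for _, w in self.terms)
        if total == 0:
            raise ContractError("query weights sum to zero")
        self._total = total

    @property
    def concept_ids(self) -> List[str]:
        return [cid for cid, _ in self.terms]

    @property
    def normalized_weights(self) -> List[float]:
        """The p_t: raw weights scaled to sum to 1."""
        return [w / self._total for _, w in self.terms]

    @classmethod
    def from_json(cls, path) -> Tuple["Query", dict]:
        """Read the query JSON dialect; returns (query, remaining parameters).

        Expected shape::

            {"concepts": [{"id": "GO:0048821", "weight": 100}, ...],
             "measure": "lin", "q": 2.0, "top_k": 20, "rsv_threshold": 0.1}

        Keys other than ``concepts`` are passed back for the caller to apply.
        """
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: invalid JSON: {exc}") from exc
        if "concepts" not in data or not isinstance(data["concepts"], list):
            raise FormatError(f"{path}: missing 'concepts' list")
        terms = []
        for entry in data["concepts"]:
            if "id" not in entry:
                raise FormatError(f"{path}: query concept entry lacks 'id'")
            terms.append((entry["id"], float(entry.get("weight", 1.0))))
        params = {k: v for k, v in data.items() if k != "concepts"}
        return cls(terms=terms), params

    def to_json(self, path, **params) -> None:
        data = {"concepts": [{"id": cid, "weight": w} for cid, w in self.terms]}
        data.update(params)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class AggregationSpec:
    """The Yager exponent q, or one of the symbolic limits.

    ``q`` may be any finite real, or one of the strings ``"min"``, ``"max"``,
    ``"geometric"`` for the q → −∞, +∞ and 0 limits.
    """

    q: object = 2.0

    def __post_init__(self):
        if isinstance(self.q, str):
            if self.q not in ("min", "max", "geometric"):
                raise ContractError(f"unknown symbolic q {self.q!r}")
        else:
            q = float(self.q)
            if not math.isfinite(q):
                raise ContractError("q must be finite; use 'min'/'max' for the limits")
            self.q = q


@dataclass
class ElementaryMatch:
    """How one query concept matched a document: the u_t plus its explanation."""

    query_concept: str
    best_doc_concept: Optional[str]
    proximity: float
    relation: str  # exact | hyponym | hypernym | other


@dataclass
class ScoredDocument:
    doc_id: str
    rsv: float
    matches: List[ElementaryMatch]


@dataclass
class ResultSet:
    query: Query
    parameters: Dict[str, object]
    ranked: List[ScoredDocument] = field(default_factory=list)


# -- stage 2: concept-document proximity ----------------------------------


def relation_tag(dag: OntologyDAG, qc: str, dc: str) -> str:
    """Classify a document concept w.r.t. a query concept.

    exact if identical, hyponym if it specialises the query concept,
    hypernym if it generalises it, other in all remaining cases.
    """
    if dc == qc:
        return "exact"
    if dc in dag.strict_hyponyms(qc):
        return "hyponym"
    if qc in dag.strict_hyponyms(dc):
        return "hypernym"
    return "other"


def concept_doc_proximity(
    dag: OntologyDAG,
    ic: ICTable,
    doc: DocumentRecord,
    qc: str,
    cfg: SimilarityConfig,
) -> ElementaryMatch:
    """u_t = max over the document's annotation concepts of pi(Q_t, D_i).

    Ties on proximity prefer exact > hyponym > hypernym > other, then the
    lexicographically smallest id, so explanations are deterministic.
    """
    best = None
    for dc in sorted(doc.annotation):
        p = proximity(dag, ic, qc, dc, cfg)
        rel = relation_tag(dag, qc, dc)
        key = (-p, _RELATION_RANK[rel], dc)
        if best is None or key < best[0]:
            best = (key, dc, p, rel)
    _, dc, p, rel = best
    return ElementaryMatch(query_concept=qc, best_doc_concept=dc, proximity=p, relation=rel)


# -- stage 3: Yager aggregation --------------------------------------------


def aggregate(scores: Sequence[float], weights: Sequence[float], spec: AggregationSpec) -> float:
    """Weighted Yager power mean of elementary scores.

    Finite q != 0 gives (sum p_t s_t^q)^(1/q); q = 0 (or "geometric") the
    weighted geometric mean; "max"/"min" the +/- infinity limits.  Any zero
    score with q < 0 yields 0 by continuity with the min limit.
    """
    if len(scores) == 0:
        raise ContractError("cannot aggregate an empty score vector")
    if len(scores) != len(weights):
        raise ContractError("scores and weights must have equal length")
    if abs(sum(weights) - 1.0) > WEIGHT_TOL:
        raise ContractError(f"weights must sum to 1 (got {sum(weights)!r})")
    if any(s < 0 or s > 1 for s in scores):
        raise ContractError("elementary scores must lie in [0, 1]")

    q = spec.q
    if q == "max":
        return max(scores)
    if q == "min":
        return min(scores)
    # |q| below ~1e-9 underflows s**q to 1.0 in double precision; dispatch to
    # the geometric limit, whose distance from the true value is O(q)
    if q == "geometric" or abs(q) < 1e-9:
        if any(s == 0.0 for s in scores):
            return 0.0
        return math.exp(sum(p * math.log(s) for s, p in zip(scores, weights)))
    if q < 0 and any(s == 0.0 for s in scores):
        return 0.0
    # factor out the extreme score so (s/m)**q never overflows
    m = max(scores) if q > 0 else min(scores)
    if m == 0.0:
        return 0.0
    total = sum(p * (s / m) ** q for s, p in zip(scores, weights))
    return m * total ** (1.0 / q)


# -- document scoring and search -------------------------------------------


def score_document(
    dag: OntologyDAG,
    ic: ICTable,
    query: Query,
    doc: DocumentRecord,
    cfg: SimilarityConfig,
    spec: AggregationSpec,
) -> ScoredDocument:
    """Full three-stage score of one document against a weighted query."""
    matches = [concept_doc_proximity(dag, ic, doc, qc, cfg) for qc in query.concept_ids]
    rsv = aggregate([m.proximity for m in matches], query.normalized_weights, spec)
    return ScoredDocument(doc_id=doc.doc_id, rsv=rsv, matches=matches)


def search(
    index: CorpusIndex,
    dag: OntologyDAG,
    ic: ICTable,
    query: Query,
    cfg: SimilarityConfig | None = None,
    spec: AggregationSpec | None = None,
    top_k: int = 1000,
    rsv_threshold: float = 0.0,
) -> ResultSet:
    """Score every document, filter by RSV threshold, rank, truncate.

    Query concepts missing from the ontology are a hard error (a batch run
    has no auto-completion to catch typos).  Ranking is by descending RSV
    with doc_id tie-break, so output order is total and reproducible.
    """
    cfg = cfg or SimilarityConfig()
    spec = spec or AggregationSpec()
    if not index.documents:
        raise ContractError("cannot search an empty corpus")
    missing = [cid for cid in query.concept_ids if cid not in dag]
    if missing:
        raise QueryValidationError(missing)
    scored = [
        score_document(dag, ic, query, doc, cfg, spec)
        for doc in index.documents.values()
    ]
    kept = [s for s in scored if s.rsv >= rsv_threshold]
    kept.sort(key=lambda s: (-s.rsv, s.doc_id))
    params = {
        "measure": cfg.measure,
        "ic_mode": cfg.ic_mode,
        "q": spec.q,
        "top_k": top_k,
        "rsv_threshold": rsv_threshold,
    }
    return ResultSet(query=query, parameters=params, ranked=kept[:top_k])


# -- export / import --------------------------------------------------------


def export_results(rs: ResultSet, fmt: str, path) -> None:
    """Write a result set as CSV, XML or JSON.

    CSV is flat (one row per document, per-term proximity/relation columns);
    XML and JSON carry the full nested structure including parameters, and
    the JSON form round-trips through :func:`read_results_json`.
    """
    if fmt == "csv":
        _export_csv(rs, path)
    elif fmt == "json":
        _export_json(rs, path)
    elif fmt == "xml":
        _export_xml(rs, path)
    else:
        raise ContractError(f"unknown export format {fmt!r}")


def _export_csv(rs: ResultSet, path) -> None:
    qids = rs.query.concept_ids
    header = ["doc_id", "rsv"]
    for cid in qids:
        header += [f"prox[{cid}]", f"match[{cid}]", f"relation[{cid}]"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for doc in rs.ranked:
            row = [doc.doc_id, f"{doc.rsv:.12g}"]
            by_qc = {m.query_concept: m for m in doc.matches}
            for cid in qids:
                m = by_qc[cid]
                row += [f"{m.proximity:.12g}", m.best_doc_concept or "", m.relation]
            w.writerow(row)


def _result_dict(rs: ResultSet) -> dict:
    return {
        "query": {"concepts": [{"id": cid, "weight": w} for cid, w in rs.query.terms]},
        "parameters": rs.parameters,
        "results": [
            {
                "doc_id": d.doc_id,
                "rsv": d.rsv,
                "matches": [
                    {
                        "query_concept": m.query_concept,
                        "best_doc_concept": m.best_doc_concept,
                        "proximity": m.proximity,
                        "relation": m.relation,
                    }
                    for m in d.matches
                ],
            }
            for d in rs.ranked
        ],
    }


def _export_json(rs: ResultSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(_result_dict(rs), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_results_json(path) -> ResultSet:
    """Reconstruct a :class:`ResultSet` written by the JSON exporter."""
    with open(path) as fh:
        data = json.load(fh)
    query = Query(terms=[(e["id"], e["weight"]) for e in data["query"]["concepts"]])
    ranked = [
        ScoredDocument(
            doc_id=d["doc_id"],
            rsv=d["rsv"],
            matches=[
                ElementaryMatch(
                    query_concept=m["query_concept"],
                    best_doc_concept=m["best_doc_concept"],
                    proximity=m["proximity"],
                    relation=m["relation"],
                )
                for m in d["matches"]
            ],
        )
        for d in data["results"]
    ]
    return ResultSet(query=query, parameters=data["parameters"], ranked=ranked)


def _export_xml(rs: ResultSet, path) -> None:
    root = etree.Element("resultset")
    q = etree.SubElement(root, "query")
    for cid, w in rs.query.terms:
        etree.SubElement(q, "concept", id=cid, weight=repr(w))
    params = etree.SubElement(root, "parameters")
    for k, v in sorted(rs.parameters.items()):
        etree.SubElement(params, "param", name=k, value=str(v))
    docs = etree.SubElement(root, "results")
    for d in rs.ranked:
        de = etree.SubElement(docs, "document", id=d.doc_id, rsv=f"{d.rsv:.12g}")
        for m in d.matches:
            etree.SubElement(
                de,
                "match",
                query_concept=m.query_concept,
                best_doc_concept=m.best_doc_concept or "",
                proximity=f"{m.proximity:.12g}",
                relation=m.relation,
            )
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")


# -- semantic map layout -----------------------------------------------------


def map_layout(rs: ResultSet) -> List[Tuple[str, float, float]]:
    """Polar coordinates for a semantic map: the query sits at the origin and
    a document's radius is 1 - RSV, so the most relevant documents cluster
    around it.  Angles spread uniformly in rank order.

    Returns (doc_id, radius, angle) triples; deterministic for a given
    result set.
    """
    if not rs.ranked:
        raise ContractError("cannot lay out an empty result set")
    n = len(rs.ranked)
    return [
        (doc.doc_id, 1.0 - doc.rsv, 2.0 * math.pi * i / n)
        for i, doc in enumerate(rs.ranked)
    ]


def export_layout_json(rs: ResultSet, path) -> None:
    rows = [
        {"doc_id": d, "radius": r, "angle": a} for d, r, a in map_layout(rs)
    ]
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1)
        fh.write("\n")
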
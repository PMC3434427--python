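"""Concept-annotated document corpora.

A document is anything indexed by a set of ontology concepts: a gene
annotated with GO terms, a PubMed abstract indexed with MeSH headings.
Two plain-text input formats are supported: a two-column TSV
(``doc_id<TAB>concept_id``, one annotation per line) and GAF 2.x gene
association files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Set

from .errors import ContractError, FormatError
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)


@dataclass
class DocumentRecord:
    """A document id plus its concept annotation set."""

    doc_id: str
    annotation: Set[str]
    metadata: Optional[str] = None

    def __post_init__(self):
        if not self.annotation:
            raise ContractError(f"document {self.doc_id!r} has an empty annotation set")


@dataclass
class CorpusIndex:
    """Documents plus an inverted concept -> doc_id index."""

    documents: Dict[str, DocumentRecord] = field(default_factory=dict)
    inverted: Dict[str, Set[str]] = field(default_factory=dict)

    def add(self, record: DocumentRecord) -> None:
        self.documents[record.doc_id] = record
        for cid in record.annotation:
            self.inverted.setdefault(cid, set()).add(record.doc_id)

    def rebuild_inverted(self) -> None:
        """Recompute the inverted index from the documents (after mutation)."""
        self.inverted = {}
        for rec in self.documents.values():
            for cid in rec.annotation:
                self.inverted.setdefault(cid, set()).add(rec.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for doc_id in sorted(self.documents):
                for cid in sorted(self.documents[doc_id].annotation):
                    fh.write(f"{doc_id}\t{cid}\n")


def _assemble(pairs, dag: Optional[OntologyDAG], source: str) -> CorpusIndex:
    raw: Dict[str, Set[str]] = {}
    for doc_id, cid in pairs:
        raw.setdefault(doc_id, set()).add(cid)
    if not raw:
        raise FormatError(f"{source}: no documents found")
    index = CorpusIndex()
    n_dropped = 0
    for doc_id in sorted(raw):
        annotation = raw[doc_id]
        if dag is not None:
            resolvable = {cid for cid in annotation if cid in dag}
            n_dropped += len(annotation) - len(resolvable)
            annotation = resolvable
        if not annotation:
            logger.warning("document %r lost all annotations; skipped", doc_id)
            continue
        index.add(DocumentRecord(doc_id=doc_id, annotation=annotation))
    if n_dropped:
        # semantic coverage gap: annotations that do not map onto the ontology
        logger.warning("%s: dropped %d unresolvable annotation(s)", source, n_dropped)
    if not index.documents:
        raise FormatError(f"{source}: every document lost all its annotations")
    return index


def load_corpus_tsv(path, dag: Optional[OntologyDAG] = None) -> CorpusIndex:
    """Read a ``doc_id<TAB>concept_id`` file.

    If a DAG is given, annotations that do not resolve in it are dropped
    with a warning (the document is kept as long as one annotation resolves).
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected doc_id<TAB>concept_id")
            pairs.append((parts[0], parts[1]))
    return _assemble(pairs, dag, str(path))


def load_gaf(path, dag: Optional[OntologyDAG] = None) -> CorpusIndex:
    """Read a GAF 2.x gene association file.

    Column 3 (DB object symbol) becomes the document id, column 5 the
    annotating GO id.  Rows whose qualifier contains ``NOT`` are skipped.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: GAF row has {len(cols)} columns (< 5)")
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            symbol, go_id = cols[2], cols[4]
            if not symbol or not go_id:
                raise FormatError(f"{path}:{lineno}: empty symbol or GO id")
            pairs.append((symbol, go_id))
    return _assemble(pairs, dag, str(path))
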
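"""Exception hierarchy.

Every domain failure derives from :class:`OntoIRError` so callers (and the
CLI) can distinguish contract violations from programming errors.
"""


class OntoIRError(Exception):
    """Base class for all domain errors raised by this package."""


class FormatError(OntoIRError):
    """Input file could not be parsed (OBO, TSV, GAF, query JSON, qrels)."""


class StructuralError(OntoIRError):
    """Ontology violates a structural requirement (cycle, multiple roots)."""


class EmptyOntologyError(OntoIRError):
    """Ontology contains no usable (non-obsolete) concepts."""


class DegenerateOntologyError(OntoIRError):
    """Ontology too small for the requested computation (e.g. max_con < 2)."""


class LookupError_(OntoIRError):
    """A concept or document identifier does not resolve."""


class NoCommonAncestorError(OntoIRError):
    """Concept pair has no common ancestor (disconnected multi-root DAG)."""


class NoPathError(OntoIRError):
    """Concept pair is not connected in the undirected is-a graph."""


class ContractError(OntoIRError):
    """An operation precondition was violated by the caller."""


class QueryValidationError(OntoIRError):
    """Query refers to concepts absent from the ontology."""

    def __init__(self, missing_ids):
        self.missing_ids = sorted(missing_ids)
        super().__init__(
            "query concepts not found in ontology: " + ", ".join(self.missing_ids)
        )
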
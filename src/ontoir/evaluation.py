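"""Boolean baselines and TREC-style interpolated precision–recall evaluation.

The Boolean baselines match annotations verbatim — no ontology expansion —
which is exactly what makes them blind to documents annotated only with
hyponyms or hypernyms of the query concepts ("silence").  The benchmark
harness retrieves with each configured engine, computes a per-query
interpolated precision–recall curve and macro-averages the curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Set, Tuple

from .corpus import CorpusIndex
from .errors import ContractError, FormatError
from .ontology import ICTable, OntologyDAG
from .retrieval import AggregationSpec, Query, search
from .similarity import SimilarityConfig

#: the TREC-standard interpolation grid
GRID_11 = tuple(i / 10 for i in range(11))
#: variant excluding recall 0.0 ("ten recall points")
GRID_10 = tuple(i / 10 for i in range(1, 11))


@dataclass
class Qrels:
    """Relevance judgements: query_id -> set of relevant doc_ids."""

    relevant: Dict[str, Set[str]]

    def for_query(self, query_id: str) -> Set[str]:
        try:
            rel = self.relevant[query_id]
        except KeyError:
            raise ContractError(f"no relevance judgements for query {query_id!r}") from None
        if not rel:
            raise ContractError(f"empty relevance set for query {query_id!r}")
        return rel

    @classmethod
    def from_trec(cls, path) -> "Qrels":
        """Read TREC qrels lines: ``qid 0 docid rel`` (whitespace-separated)."""
        relevant: Dict[str, Set[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 'qid 0 docid rel'")
                qid, _, docid, rel = parts
                try:
                    is_rel = int(rel) > 0
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad relevance flag {rel!r}") from exc
                relevant.setdefault(qid, set())
                if is_rel:
                    relevant[qid].add(docid)
        return cls(relevant=relevant)

    def to_trec(self, path) -> None:
        with open(path, "w") as fh:
            for qid in sorted(self.relevant):
                for docid in sorted(self.relevant[qid]):
                    fh.write(f"{qid} 0 {docid} 1\n")


@dataclass
class PRCurve:
    """Interpolated precision at fixed ascending recall points."""

    recall_points: Tuple[float, ...]
    precisions: Tuple[float, ...]

    def __post_init__(self):
        if len(self.recall_points) != len(self.precisions):
            raise ContractError("recall and precision vectors differ in length")
        if list(self.recall_points) != sorted(self.recall_points):
            raise ContractError("recall points must be ascending")


def boolean_search(index: CorpusIndex, query: Query, mode: str) -> Set[str]:
    """Verbatim Boolean retrieval over the inverted index.

    AND keeps documents annotated with *every* query concept, OR with at
    least one; weights are ignored and no ontology expansion happens, so a
    document annotated only with a hyponym of a query concept is missed.
    """
    if mode not in ("AND", "OR"):
        raise ContractError(f"Boolean mode must be AND or OR, got {mode!r}")
    postings = [index.inverted.get(cid, set()) for cid in query.concept_ids]
    if mode == "AND":
        result = set.intersection(*postings) if postings else set()
    else:
        result = set.union(*postings) if postings else set()
    return result


def interpolated_pr(
    ranked: Sequence[str],
    relevant: Set[str],
    points: Sequence[float] = GRID_11,
) -> PRCurve:
    """TREC interpolation: precision at recall r is the maximum precision
    attained at any rank whose recall is >= r (0 if that recall is never
    reached)."""
    if not relevant:
        raise ContractError("relevant set must be non-empty")
    n_rel = len(relevant)
    # (recall, precision) at each rank where recall can only grow
    rp = []
    hits = 0
    for rank, doc_id in enumerate(ranked, start=1):
        if doc_id in relevant:
            hits += 1
            rp.append((hits / n_rel, hits / rank))
    precisions = []
    for r in points:
        attained = [p for rec, p in rp if rec >= r - 1e-12]
        precisions.append(max(attained) if attained else 0.0)
    return PRCurve(recall_points=tuple(points), precisions=tuple(precisions))


def mean_pr(curves: Sequence[PRCurve]) -> PRCurve:
    """Macro-average: pointwise arithmetic mean over same-grid curves."""
    if not curves:
        raise ContractError("cannot average zero curves")
    grid = curves[0].recall_points
    for c in curves[1:]:
        if c.recall_points != grid:
            raise ContractError("cannot average curves with different recall grids")
    n = len(curves)
    means = tuple(sum(c.precisions[i] for c in curves) / n for i in range(len(grid)))
    return PRCurve(recall_points=grid, precisions=means)


def run_benchmark(
    index: CorpusIndex,
    dag: OntologyDAG,
    ic: ICTable,
    queries: Dict[str, Query],
    qrels: Qrels,
    configs: Sequence[dict],
    points: Sequence[float] = GRID_11,
    top_k: int = 1000,
    rsv_threshold: float = 0.0,
) -> Dict[str, PRCurve]:
    """Compare retrieval configurations on one corpus.

    Each config is either ``{"semantic": (measure, q)}`` — the three-stage
    semantic engine — or ``{"boolean": "AND"|"OR"}``.  Semantic runs use
    the given top_k and RSV threshold (defaults: 1000 and 0.0, i.e. no
    filtering); Boolean result sets are ranked by doc_id for the purpose
    of the PR computation.  Returns config-label -> macro-averaged curve.
    """
    results: Dict[str, PRCurve] = {}
    for config in configs:
        label, ranked_per_query = _run_config(
            config, index, dag, ic, queries, top_k, rsv_threshold
        )
        curves = [
            interpolated_pr(ranked_per_query[qid], qrels.for_query(qid), points)
            for qid in sorted(queries)
        ]
        results[label] = mean_pr(curves)
    return results


def _run_config(config, index, dag, ic, queries, top_k, rsv_threshold):
    if "semantic" in config:
        measure, q = config["semantic"]
        label = f"semantic-{measure}-q{q}"
        cfg = SimilarityConfig(measure=measure)
        spec = AggregationSpec(q=q)
        ranked = {
            qid: [d.doc_id for d in search(
                index, dag, ic, query, cfg, spec, top_k=top_k, rsv_threshold=rsv_threshold
            ).ranked]
            for qid, query in queries.items()
        }
    elif "boolean" in config:
        mode = config["boolean"]
        label = f"boolean-{mode}"
        ranked = {
            qid: sorted(boolean_search(index, query, mode))
            for qid, query in queries.items()
        }
    else:
        raise ContractError(f"config must name 'semantic' or 'boolean': {config!r}")
    return label, ranked


def benchmark_table_tsv(results: Dict[str, PRCurve], path) -> None:
    """Write the benchmark as TSV rows (config, recall, mean precision)."""
    with open(path, "w") as fh:
        fh.write("config\trecall\tmean_precision\n")
        for label in sorted(results):
            curve = results[label]
            for r, p in zip(curve.recall_points, curve.precisions):
                fh.write(f"{label}\t{r:.1f}\t{p:.6f}\n")


def plot_benchmark(results: Dict[str, PRCurve], path) -> None:
    """Optional matplotlib rendering of the PR curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label in sorted(results):
        curve = results[label]
        ax.plot(curve.recall_points, curve.precisions, marker="o", label=label)
    ax.set_xlabel("recall")
    ax.set_ylabel("interpolated precision")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
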
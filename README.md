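# ontoir — ontology-based information retrieval

`ontoir` ranks concept-annotated documents against weighted concept
queries using the subsumption (*is-a*) structure of a domain ontology.
The documents can be anything indexed by ontology concepts: genes
annotated with Gene Ontology terms, biomedical abstracts indexed with
MeSH headings. Its purpose is to avoid the *silence* of Boolean search —
a relevant document missed because it is annotated with a hyponym or
hypernym of a query concept rather than the concept itself — while
keeping every score explainable: each retrieved document carries, per
query concept, the best-matching annotation concept, its proximity, and
whether it was an exact, hyponym or hypernym match.

## The model

Relevance is computed in three stages.

**Stage 1 — concept–concept proximity.** The default is the descendant-
overlap measure: with `hypo({C})` the reflexive hyponym set of concept
`C`,

    π_JD(C1, C2) = |hypo({C1}) ∩ hypo({C2})| / |hypo({C1}) ∪ hypo({C2})|

if one concept subsumes the other, and 0 otherwise; so `π_JD = 1` iff
`C1 = C2` and `π_JD = 0` iff the concepts have no hyponym relationship.
Lin and Resnik proximities are also available, driven by an intrinsic
information content computed from the DAG alone,

    IC(C) = 1 − log(|hypo_strict(C)| + 1) / log(max_con),

which is 0 at the root and 1 at every leaf (`max_con` = number of
concepts). A corpus-frequency IC (`−log P(C)`) can be used instead.

**Stage 2 — concept–document proximity.** A query concept `Q_t` matches
document `D` as well as its best annotation concept:
`u_t = π(Q_t, D) = max_i π(Q_t, D_i)`. A document is never penalised for
annotations outside the query.

**Stage 3 — aggregation.** The per-concept scores are combined into one
Retrieval Status Value with the weighted Yager power mean

    RSV = ( Σ_t p_t · u_t^q )^(1/q),     Σ_t p_t = 1,

where the `p_t` are the normalised query weights and `q` is the user's
AND/OR cursor: `q → −∞` is min (strict conjunction), `q → +∞` is max
(disjunction), `q = 1` the arithmetic and `q → 0` the geometric mean.
For every finite `q` the RSV is a compromise:
`min u_t ≤ RSV ≤ max u_t`. Defaults are `measure=lin`, `q = 2.0`,
`top_k = 1000`, `rsv_threshold = 0.0`.

The package also ships Boolean AND/OR baselines, TREC-style interpolated
precision–recall evaluation (11- or 10-point grids, macro-averaged), and
seeded generators for synthetic ontologies, corpora, topics and
relevance judgements that plant hyponym-only-annotated relevant
documents — the silence scenario — by construction.

## Worked example

The 8-concept documentation ontology `T8` (root `R`; `A` and `B` below
it; `A1`, `A2` below `A`; `A1a`, `A1b` below `A1`; `B1` below `B`):

```python
from ontoir import (AggregationSpec, DocumentRecord, Query,
                    SimilarityConfig, intrinsic_ic, score_document, t8_dag)

dag = t8_dag()
ic = intrinsic_ic(dag)
query = Query([("A1", 0.5), ("B", 0.5)])
doc = DocumentRecord("d", {"A", "B1"})
scored = score_document(dag, ic, query, doc,
                        SimilarityConfig(measure="jaccard"),
                        AggregationSpec(q=2.0))
print(round(scored.rsv, 6))
for m in scored.matches:
    print(m.query_concept, "->", m.best_doc_concept, round(m.proximity, 3), m.relation)
```

prints

```
0.552268
A1 -> A 0.6 hypernym
B -> B1 0.5 hyponym
```

The document carries neither `A1` nor `B`, so both Boolean modes miss it
entirely; semantically it scores `u_1 = π_JD(A1, A) = 3/5` (the document
generalises `A1`) and `u_2 = π_JD(B, B1) = 1/2` (it specialises `B`),
and the quadratic mean of (0.6, 0.5) at equal weights is
`√(0.5·0.36 + 0.5·0.25) ≈ 0.5523`.

The same pipeline from the shell:

```sh
ontoir generate --outdir bundle --seed 42
ontoir eval --ontology bundle/fixture.obo --corpus bundle/corpus.tsv \
    --queries-dir bundle/queries --qrels bundle/qrels.txt \
    --semantic jaccard:2.0 --and --or --output bench.tsv
```

`bench.tsv` then holds one interpolated-precision row per recall point
and configuration; on the generated benchmark the semantic run keeps
precision 1.0 at every recall point while Boolean OR drops to 0 above
recall 0.5, because half of each topic's relevant documents are
annotated only with hyponyms of the query concepts.

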
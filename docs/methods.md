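# Methods

## Scope and data model

`ontoir` implements concept-based document retrieval over a single-rooted
*is-a* DAG. Documents and queries are both sets of ontology concepts;
queries additionally carry non-negative weights. The retrieval output is a
ranked list of documents, each with a Retrieval Status Value (RSV) in
[0, 1] and one elementary-match record per query concept.

Edges are stored child → parent in a `networkx.DiGraph`; OBO parsing is
delegated to `obonet`. Only `is_a` edges are used by default
(`relationship: part_of` optionally), obsolete terms are kept as records
but stripped of edges and excluded from the concept count, and a
multi-rooted file is rejected unless the loader is asked to join the roots
under an artificial one. Descendant/ancestor sets are cached per concept.

## Strict versus reflexive hyponym sets

The package distinguishes two descendant notions because the formulas
require both:

* the **intrinsic information content** uses *strict* hyponym counts,
  `IC(C) = 1 − log(|hypo_strict(C)|+1)/log(max_con)`. The strict reading
  is forced by the boundary values: the root must score 0 (it strictly
  subsumes `max_con − 1` concepts, and `log(max_con)/log(max_con) = 1`)
  and a leaf must score 1 (`log 1 = 0`).
* the **descendant-overlap proximity** uses *reflexive* sets, since the
  self-proximity must be 1; it is gated to 0 when neither concept
  subsumes the other, so a positive value always witnesses an exact,
  hyponym or hypernym relation. This gate is what makes the
  explanation tags faithful.

Logs are natural throughout; both formulas above are base-invariant
ratios, and the corpus IC (`−log P(C)`, with `P(C)` the fraction of
documents annotated by `C` or a strict hyponym) is documented as
natural-log units. Concepts unseen in the corpus receive probability
`1/(2N)` (add-half smoothing) instead of infinite IC, which keeps Lin and
Resnik finite everywhere.

The most informative common ancestor (MICA) is taken over reflexive
ancestors, so `MICA(C, C) = C`; IC ties break lexicographically by
concept id so results are reproducible across runs and platforms.

The Lin proximity `2·IC(MICA)/(IC(C1)+IC(C2))` has one degenerate case,
root versus root (0/0); it is defined as 1 for identical concepts and 0
otherwise, preserving the "equals 1 iff equal" convention.

## Distances kept out of retrieval

Two graph distances are provided for comparison only: the
direction-change-penalised shortest path (parameter `K ≥ 0` per up/down
flip, computed exactly by Dijkstra over (concept, arrival-direction)
states rather than path enumeration) and a descendant-set distance
`|hypo(ancEx(C1,C2)) ∪ hypo({C1}) ∪ hypo({C2})| − |hypo({C1}) ∩ hypo({C2})|`
over reflexive sets, where `ancEx` is the symmetric difference of the
strict ancestor sets. The published layout of the latter formula admits
more than one reading of the cardinality grouping; the reading above is
implemented, verified against explicit set construction on small
fixtures, and deliberately isolated from the RSV pipeline, which accepts
only the [0, 1] proximities (jaccard, lin, resnik-intrinsic).

## Aggregation

The weighted Yager power mean `(Σ p_t u_t^q)^(1/q)` is evaluated with the
standard stable form, factoring out the extreme score so `(s/m)^q` never
overflows. Conventions at the edges:

* `|q| < 1e-9` dispatches to the weighted geometric mean — below that
  threshold `s^q` rounds to 1.0 in double precision while the true value
  differs from the geometric limit by O(q);
* any zero score with `q < 0` (or in the geometric case) yields 0, the
  continuity convention shared with the min limit;
* the symbolic spellings `"min"`, `"max"`, `"geometric"` select the
  limits exactly.

Weights are validated to sum to 1 within 1e-9; queries normalise raw
weights internally, so only their ratios matter (scaling every weight by
a constant provably leaves every RSV unchanged, and the tests assert it).

Defaults mirror the package's reference experiment settings: Lin
proximity, `q = 2.0`, `top_k = 1000`, RSV threshold 0.0 (no filtering).

## Ranking, explanations, exports

All documents are scored; an inverted-index candidate pre-filter would be
a pure optimisation and is not applied, so no result can depend on it.
Ranking is descending RSV with doc_id tie-break. Among a document's
annotation concepts tying on proximity, the explanation prefers
exact > hyponym > hypernym > other, then the smallest id. Query concepts
absent from the ontology are a hard error rather than silently dropped: a
batch interface has no auto-completion to catch typos. Results export to
CSV (flat), XML and JSON (nested, with parameters); the JSON form
round-trips bit-faithfully through the bundled reader. The semantic-map
layout places the query at the origin with radius `1 − RSV` and angles
uniform in rank order.

## Evaluation protocol

Boolean AND/OR baselines match annotations verbatim over the inverted
index; their result sets are ranked by doc_id for the precision–recall
computation (they define no scores, and any fixed order gives the same
recall ceiling). Interpolated precision at recall `r` is the maximum
precision at any rank with recall ≥ r, on the standard 11-point grid
0.0–1.0 by default; a 10-point grid (0.1–1.0) is available since
protocols are sometimes quoted as "ten recall points". Curves are
macro-averaged over queries. Documents retrieved with RSV = 0 at
threshold 0 count as retrieved, ranked after all positive-RSV documents.

## Synthetic benchmark and what it shows

The fixture generator emulates a MeSH/GO-style evaluation collection at
desk scale: a random single-rooted tree (default 120 concepts, ≤ 4
children per node), 200 documents with 2–4 annotations, and 10 topics of
1–3 concepts each. Relevant documents are *planted*: per topic, the
relevance plan (default 0.5 exact-annotated, 0.5 hyponym-only) rewrites a
block of documents so that half contain a query concept verbatim and half
contain only strict hyponyms of one. Topic concepts are chosen with
pairwise-disjoint hyponym subtrees, and all unplanted documents are
annotated from a background pool comparable to no topic concept. Those
two constraints turn the headline comparison into a construction-level
guarantee rather than a statistical tendency: hyponym-only relevant
documents are invisible to both Boolean modes but receive RSV > 0 under
the descendant-overlap proximity with `q > 0`, every irrelevant document
scores exactly 0, and therefore the semantic interpolated-precision curve
dominates both Boolean curves pointwise, Boolean OR recall is capped at
the exact-annotated share (0.5), and semantic recall is 1 at full depth.

What the generator does *not* emulate: realistic term-frequency
distributions, multi-label semantic overlap between topics, annotation
noise, or the partial concept-mapping coverage of real collections.
Passing the benchmark therefore demonstrates the mechanism (silence
avoidance and correct ordering), not retrieval quality on a real corpus;
on real data the semantic and Boolean curves both degrade and their gap
narrows with the ontology's annotation coverage.

Generators emit files in the external formats (OBO, TSV, query JSON,
TREC qrels) so the parsers are exercised end to end; all randomness flows
from the spec's single integer seed, and infeasible topic draws trigger
bounded re-draws (20) rather than silent plan degradation. Planting
mutates the passed corpus in place and rebuilds its inverted index.

## Problem sizes

The default test-and-benchmark sizes — 120-concept ontologies, 200
documents, 10 topics, property checks over 100 random DAGs of ≤ 20
concepts and 1000 random score vectors — were chosen so the full suite
exercises every code path in a few seconds while keeping each guarantee
non-trivial (multi-level trees, multi-concept topics, even per-topic
blocks). Larger ontologies and corpora scale linearly in documents and,
through cached closure sets, near-linearly in concepts.

## Known limitations

* Only subsumption (and optionally `part_of`) is interpreted; other OBO
  relationship types are dropped with a warning.
* Corpus IC depends on annotation frequencies and is therefore no longer
  bounded by 1; Resnik under corpus IC is excluded from retrieval, which
  requires proximities in [0, 1].
* The descendant-set distance implements one reading of an ambiguous
  published formula (see above) and should not be compared across tools
  without checking which reading they use.
* Interactive query building (auto-completion, ontology browsing,
  graphical re-weighting) is out of scope; the CLI and library cover the
  scoring, explanation and evaluation layers.
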
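"""Three-stage RSV scoring, ranking, explanations and exports."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoir import (
    AggregationSpec,
    CorpusIndex,
    DocumentRecord,
    Query,
    SimilarityConfig,
    aggregate,
    concept_doc_proximity,
    export_results,
    map_layout,
    read_results_json,
    relation_tag,
    score_document,
    search,
)
from ontoir.errors import ContractError, QueryValidationError
from ontoir.retrieval import export_layout_json

JACCARD = SimilarityConfig(measure="jaccard")
Q2 = AggregationSpec(q=2.0)

unit_scores = st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6)


@pytest.fixture
def t8_corpus():
    index = CorpusIndex()
    index.add(DocumentRecord("d1", {"A1"}))
    index.add(DocumentRecord("d2", {"A"}))
    index.add(DocumentRecord("d3", {"B1"}))
    return index


class TestQuery:
    def test_weights_normalised(self):
        q = Query([("A", 100.0), ("B", 50.0)])
        assert q.normalized_weights == pytest.approx([2 / 3, 1 / 3])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ContractError):
            Query([("A", 1.0), ("A", 2.0)])

    @pytest.mark.parametrize("terms", [[], [("A", -1.0)], [("A", 0.0)]])
    def test_invalid_terms_rejected(self, terms):
        with pytest.raises(ContractError):
            Query(terms)

    def test_json_round_trip(self, tmp_path):
        q = Query([("A1", 0.5), ("B", 0.5)])
        path = tmp_path / "query.json"
        q.to_json(path, measure="jaccard", q=2.0)
        loaded, params = Query.from_json(path)
        assert loaded.terms == q.terms
        assert params == {"measure": "jaccard", "q": 2.0}


class TestRelationTag:
    @pytest.mark.parametrize(
        "qc, dc, expected",
        [
            ("A1", "A1", "exact"),
            ("A1", "A1a", "hyponym"),
            ("A1", "A", "hypernym"),
            ("A1", "B1", "other"),
        ],
    )
    def test_examples(self, t8, qc, dc, expected):
        assert relation_tag(t8, qc, dc) == expected


class TestConceptDocProximity:
    def test_exact_annotation_dominates(self, t8, t8_ic):
        doc = DocumentRecord("d", {"A1", "B1"})
        m = concept_doc_proximity(t8, t8_ic, doc, "A1", JACCARD)
        assert m.proximity == 1.0 and m.relation == "exact"

    def test_best_comparable_concept_wins(self, t8, t8_ic):
        doc = DocumentRecord("d", {"A", "B1"})
        m = concept_doc_proximity(t8, t8_ic, doc, "A1", JACCARD)
        assert m.proximity == pytest.approx(0.6)
        assert m.best_doc_concept == "A" and m.relation == "hypernym"

    def test_incomparable_document_scores_zero(self, t8, t8_ic):
        doc = DocumentRecord("d", {"B1"})
        m = concept_doc_proximity(t8, t8_ic, doc, "A1", JACCARD)
        assert m.proximity == 0.0 and m.relation == "other"


class TestAggregate:
    def test_arithmetic_mean_at_q_one(self):
        assert aggregate([0.6, 0.2], [0.5, 0.5], AggregationSpec(q=1)) == pytest.approx(0.4)

    def test_quadratic_mean(self):
        assert aggregate([0.6, 0.2], [0.5, 0.5], Q2) == pytest.approx(math.sqrt(0.2))

    def test_weighted_arithmetic_mean(self):
        assert aggregate([0.6, 0.2], [0.75, 0.25], AggregationSpec(q=1)) == pytest.approx(0.5)

    @pytest.mark.parametrize("q", [-3, -1, 0, 1, 2, 10, "min", "max", "geometric"])
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_boundary_conditions(self, q, n):
        spec = AggregationSpec(q=q)
        weights = [1 / n] * n
        assert aggregate([1.0] * n, weights, spec) == pytest.approx(1.0)
        assert aggregate([0.0] * n, weights, spec) == pytest.approx(0.0)

    def test_zero_score_with_negative_q_is_zero(self):
        assert aggregate([0.0, 0.9], [0.5, 0.5], AggregationSpec(q=-2)) == 0.0

    def test_geometric_dispatch_at_q_zero(self):
        expected = math.sqrt(0.4 * 0.9)
        assert aggregate([0.4, 0.9], [0.5, 0.5], AggregationSpec(q=0.0)) == pytest.approx(expected)

    def test_contract_errors(self):
        with pytest.raises(ContractError):
            aggregate([], [], Q2)
        with pytest.raises(ContractError):
            aggregate([0.5], [0.9], Q2)

    @given(scores=unit_scores, q=st.floats(-20, 20))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_compromise_convexity(self, scores, q):
        weights = [1 / len(scores)] * len(scores)
        value = aggregate(scores, weights, AggregationSpec(q=q))
        assert min(scores) - 1e-9 <= value <= max(scores) + 1e-9

    @given(scores=unit_scores, q1=st.floats(-10, 10), q2=st.floats(-10, 10))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_power_mean_monotone_in_q(self, scores, q1, q2):
        if q1 > q2:
            q1, q2 = q2, q1
        weights = [1 / len(scores)] * len(scores)
        low = aggregate(scores, weights, AggregationSpec(q=q1))
        high = aggregate(scores, weights, AggregationSpec(q=q2))
        assert low <= high + 1e-9

    @given(scores=unit_scores, idx=st.integers(0, 5), bump=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_each_score(self, scores, idx, bump):
        idx %= len(scores)
        weights = [1 / len(scores)] * len(scores)
        bumped = list(scores)
        bumped[idx] = min(1.0, bumped[idx] + bump)
        before = aggregate(scores, weights, Q2)
        after = aggregate(bumped, weights, Q2)
        assert after >= before - 1e-12

    @given(scores=unit_scores, q=st.floats(0.1, 10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_uniform_weights_match_unweighted_form(self, scores, q):
        n = len(scores)
        weighted = aggregate(scores, [1 / n] * n, AggregationSpec(q=q))
        unweighted = (sum(s**q for s in scores) / n) ** (1 / q)
        assert weighted == pytest.approx(unweighted, abs=1e-12)


class TestScoreDocument:
    def test_worked_example(self, t8, t8_ic):
        query = Query([("A1", 0.5), ("B", 0.5)])
        doc = DocumentRecord("d", {"A", "B1"})
        scored = score_document(t8, t8_ic, query, doc, JACCARD, Q2)
        assert scored.rsv == pytest.approx(math.sqrt(0.5 * 0.36 + 0.5 * 0.25), abs=1e-12)
        tags = {(m.query_concept, m.best_doc_concept, m.relation) for m in scored.matches}
        assert tags == {("A1", "A", "hypernym"), ("B", "B1", "hyponym")}

    def test_exact_annotation_scores_one(self, t8, t8_ic):
        query = Query([("A1", 1.0), ("B", 1.0)])
        doc = DocumentRecord("d", {"A1", "B"})
        assert score_document(t8, t8_ic, query, doc, JACCARD, Q2).rsv == pytest.approx(1.0)

    def test_disjoint_document_scores_zero(self, t8, t8_ic):
        query = Query([("A1", 1.0)])
        doc = DocumentRecord("d", {"B1"})
        assert score_document(t8, t8_ic, query, doc, JACCARD, Q2).rsv == 0.0

    def test_rsv_between_match_extremes(self, t8, t8_ic):
        query = Query([("A1", 2.0), ("B", 1.0)])
        doc = DocumentRecord("d", {"A", "B1"})
        scored = score_document(t8, t8_ic, query, doc, JACCARD, Q2)
        proxs = [m.proximity for m in scored.matches]
        assert min(proxs) <= scored.rsv <= max(proxs)

    def test_exact_match_dominance(self, t8, t8_ic):
        query = Query([("A1", 0.5), ("B", 0.5)])
        generalised = DocumentRecord("d", {"A", "B1"})
        exact = DocumentRecord("d", {"A1", "B1"})
        assert (
            score_document(t8, t8_ic, query, exact, JACCARD, Q2).rsv
            >= score_document(t8, t8_ic, query, generalised, JACCARD, Q2).rsv
        )


class TestSearch:
    def test_threshold_filters_and_ranks(self, t8, t8_ic, t8_corpus):
        rs = search(t8_corpus, t8, t8_ic, Query([("A1", 1.0)]), JACCARD, Q2,
                    top_k=20, rsv_threshold=0.1)
        assert [(d.doc_id, pytest.approx(d.rsv)) for d in rs.ranked] == [
            ("d1", pytest.approx(1.0)), ("d2", pytest.approx(0.6))]

    def test_zero_threshold_keeps_zero_scores_at_tail(self, t8, t8_ic, t8_corpus):
        rs = search(t8_corpus, t8, t8_ic, Query([("A1", 1.0)]), JACCARD, Q2,
                    top_k=20, rsv_threshold=0.0)
        assert [d.doc_id for d in rs.ranked] == ["d1", "d2", "d3"]
        assert rs.ranked[-1].rsv == 0.0

    def test_top_k_truncates(self, t8, t8_ic, t8_corpus):
        rs = search(t8_corpus, t8, t8_ic, Query([("A1", 1.0)]), JACCARD, Q2,
                    top_k=1, rsv_threshold=0.0)
        assert [d.doc_id for d in rs.ranked] == ["d1"]

    def test_unknown_query_concept_is_hard_error(self, t8, t8_ic, t8_corpus):
        with pytest.raises(QueryValidationError) as err:
            search(t8_corpus, t8, t8_ic, Query([("GO:404", 1.0)]), JACCARD, Q2)
        assert "GO:404" in str(err.value)

    def test_weight_rescaling_leaves_rsv_unchanged(self, t8, t8_ic, t8_corpus):
        base = search(t8_corpus, t8, t8_ic, Query([("A1", 1.0), ("B", 3.0)]), JACCARD, Q2)
        scaled = search(t8_corpus, t8, t8_ic, Query([("A1", 100.0), ("B", 300.0)]), JACCARD, Q2)
        assert [d.doc_id for d in base.ranked] == [d.doc_id for d in scaled.ranked]
        for a, b in zip(base.ranked, scaled.ranked):
            assert a.rsv == pytest.approx(b.rsv, abs=1e-15)


class TestExport:
    @pytest.fixture
    def result_set(self, t8, t8_ic, t8_corpus):
        return search(t8_corpus, t8, t8_ic, Query([("A1", 0.5), ("B", 0.5)]),
                      JACCARD, Q2, top_k=20, rsv_threshold=0.0)

    def test_csv_has_header_and_one_row_per_document(self, result_set, tmp_path):
        path = tmp_path / "out.csv"
        export_results(result_set, "csv", path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + len(result_set.ranked)
        assert lines[0].startswith("doc_id,rsv,")

    def test_json_round_trip_preserves_ranking_and_scores(self, result_set, tmp_path):
        path = tmp_path / "out.json"
        export_results(result_set, "json", path)
        loaded = read_results_json(path)
        assert [d.doc_id for d in loaded.ranked] == [d.doc_id for d in result_set.ranked]
        for a, b in zip(loaded.ranked, result_set.ranked):
            assert abs(a.rsv - b.rsv) < 1e-12
            assert [m.relation for m in a.matches] == [m.relation for m in b.matches]

    def test_xml_is_well_formed(self, result_set, tmp_path):
        from lxml import etree

        path = tmp_path / "out.xml"
        export_results(result_set, "xml", path)
        tree = etree.parse(str(path))
        assert len(tree.findall(".//document")) == len(result_set.ranked)

    def test_empty_result_set_exports(self, t8, t8_ic, t8_corpus, tmp_path):
        rs = search(t8_corpus, t8, t8_ic, Query([("A1", 1.0)]), JACCARD, Q2,
                    top_k=5, rsv_threshold=2.0)
        assert rs.ranked == []
        export_results(rs, "csv", tmp_path / "e.csv")
        export_results(rs, "json", tmp_path / "e.json")
        export_results(rs, "xml", tmp_path / "e.xml")
        assert (tmp_path / "e.csv").read_text().count("\n") == 1
        assert read_results_json(tmp_path / "e.json").ranked == []


class TestMapLayout:
    def test_radius_complements_rsv_and_angles_spread(self, t8, t8_ic):
        index = CorpusIndex()
        for i, ann in enumerate([{"A1"}, {"A"}, {"A1a"}, {"B1"}], start=1):
            index.add(DocumentRecord(f"d{i}", ann))
        rs = search(index, t8, t8_ic, Query([("A1", 1.0)]), JACCARD, Q2,
                    top_k=10, rsv_threshold=0.0)
        layout = map_layout(rs)
        assert len(layout) == 4
        assert layout[0][1] == pytest.approx(1.0 - rs.ranked[0].rsv)
        assert layout[0][1] == pytest.approx(0.0)  # exact match sits at the origin
        angles = [a for _, _, a in layout]
        assert angles == pytest.approx([0, math.pi / 2, math.pi, 3 * math.pi / 2])
        zero_rsv = [r for d, r, a in layout if d == "d4"]
        assert zero_rsv == [pytest.approx(1.0)]

    def test_layout_json_export(self, t8, t8_ic, t8_corpus, tmp_path):
        import json

        rs = search(t8_corpus, t8, t8_ic, Query([("A1", 1.0)]), JACCARD, Q2)
        path = tmp_path / "layout.json"
        export_layout_json(rs, path)
        rows = json.loads(path.read_text())
        assert {row["doc_id"] for row in rows} == {"d1", "d2", "d3"}
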
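import pytest

from medireader import annotator
from medireader.annotator import (AnnotatedDocument, annotate_document,
                                  render_html, select_by_policy)
from medireader.ner import Mention


def M(start, end, surface="x", etype="Disease"):
    return Mention(surface, etype, start, end)


class TestPolicy:
    def test_high_literacy_keeps_only_difficult(self):
        mentions = [(M(0, 1), "easy"), (M(2, 3), "medium"),
                    (M(4, 5), "difficult")]
        kept = select_by_policy(mentions, "high")
        assert [lab for _, lab in kept] == ["difficult"]

    def test_low_literacy_keeps_medium_and_difficult(self):
        mentions = [(M(0, 1), "easy"), (M(2, 3), "medium"),
                    (M(4, 5), "difficult")]
        kept = select_by_policy(mentions, "low")
        assert [lab for _, lab in kept] == ["medium", "difficult"]

    def test_easy_never_kept_and_order_preserved(self):
        mentions = [(M(i, i + 1), lab) for i, lab in
                    enumerate(["difficult", "easy", "medium", "difficult"])]
        for literacy in ("low", "high"):
            kept = select_by_policy(mentions, literacy)
            assert all(lab != "easy" for _, lab in kept)
            starts = [m.start for m, _ in kept]
            assert starts == sorted(starts)

    def test_empty_input(self):
        assert select_by_policy([], "low") == []

    def test_unknown_literacy_rejected(self):
        with pytest.raises(ValueError):
            select_by_policy([], "medium-ish")


class TestOverlapResolution:
    def test_longest_span_wins_leftmost_tie(self):
        mentions = [M(0, 4), M(2, 10), M(5, 9)]
        resolved = annotator._resolve_overlaps(mentions)
        assert [(m.start, m.end) for m in resolved] == [(2, 10)]
        # ties: two length-4 spans, overlapping -> leftmost kept
        resolved = annotator._resolve_overlaps([M(2, 6), M(0, 4)])
        assert [(m.start, m.end) for m in resolved] == [(0, 4)]

    def test_disjoint_spans_all_kept_sorted(self):
        resolved = annotator._resolve_overlaps([M(5, 9), M(0, 4)])
        assert [(m.start, m.end) for m in resolved] == [(0, 4), (5, 9)]


@pytest.fixture(scope="module")
def pipeline(trained_tagger, trained_classifier, kb_index, synth_kb,
             ner_corpus):
    sentences, _ = ner_corpus
    text = " ".join(" ".join(s.tokens) for s in sentences[:6])
    return dict(text=text, tagger=trained_tagger, clf=trained_classifier,
                index=kb_index, kb=synth_kb)


class TestAnnotateDocument:
    def test_spans_reconstruct_surfaces(self, pipeline):
        doc = annotate_document(pipeline["text"], "low", pipeline["tagger"],
                                pipeline["clf"], pipeline["index"],
                                pipeline["kb"])
        assert doc.annotations, "fixture document should produce annotations"
        for a in doc.annotations:
            assert 0 <= a.start < a.end <= len(doc.text)
            assert doc.text[a.start:a.end] == a.surface

    def test_annotations_sorted_and_non_overlapping(self, pipeline):
        doc = annotate_document(pipeline["text"], "low", pipeline["tagger"],
                                pipeline["clf"], pipeline["index"],
                                pipeline["kb"])
        spans = [(a.start, a.end) for a in doc.annotations]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_low_literacy_superset_of_high(self, pipeline):
        low = annotate_document(pipeline["text"], "low", pipeline["tagger"],
                                pipeline["clf"], pipeline["index"],
                                pipeline["kb"])
        high = annotate_document(pipeline["text"], "high", pipeline["tagger"],
                                 pipeline["clf"], pipeline["index"],
                                 pipeline["kb"])
        high_spans = {(a.start, a.end) for a in high.annotations}
        low_spans = {(a.start, a.end) for a in low.annotations}
        assert high_spans <= low_spans
        assert all(a.difficulty == "difficult" for a in high.annotations)
        assert all(a.difficulty in ("medium", "difficult")
                   for a in low.annotations)

    def test_no_stopword_surfaces(self, pipeline):
        doc = annotate_document(pipeline["text"], "low", pipeline["tagger"],
                                pipeline["clf"], pipeline["index"],
                                pipeline["kb"])
        for a in doc.annotations:
            assert not pipeline["kb"].is_stopword(a.surface)

    def test_related_concepts_resolve_in_kb(self, pipeline):
        doc = annotate_document(pipeline["text"], "low", pipeline["tagger"],
                                pipeline["clf"], pipeline["index"],
                                pipeline["kb"])
        for a in doc.annotations:
            assert a.concept_id in pipeline["kb"]
            for _, rid, _name in a.related:
                assert rid in pipeline["kb"]

    def test_byte_identical_repeat_runs(self, pipeline):
        docs = [annotate_document(pipeline["text"], "low",
                                  pipeline["tagger"], pipeline["clf"],
                                  pipeline["index"], pipeline["kb"])
                for _ in range(2)]
        assert docs[0].to_json() == docs[1].to_json()

    def test_plain_document_yields_no_annotations(self, pipeline):
        text = "the visit was on review today and remains stable"
        doc = annotate_document(text, "low", pipeline["tagger"],
                                pipeline["clf"], pipeline["index"],
                                pipeline["kb"])
        assert doc.annotations == [] and doc.text == text

    def test_oversized_document_rejected(self, pipeline):
        cfg = annotator.PipelineConfig(max_doc_chars=10)
        with pytest.raises(ValueError, match="exceed"):
            annotate_document("x" * 11, "low", pipeline["tagger"],
                              pipeline["clf"], pipeline["index"],
                              pipeline["kb"], config=cfg)

    def test_missing_artifact_named(self, pipeline):
        with pytest.raises(ValueError, match="tagger"):
            annotate_document("text", "low", None, pipeline["clf"],
                              pipeline["index"], pipeline["kb"])

    def test_html_rendering_contains_highlights(self, pipeline):
        doc = annotate_document(pipeline["text"], "low", pipeline["tagger"],
                                pipeline["clf"], pipeline["index"],
                                pipeline["kb"])
        html = render_html(doc)
        assert html.startswith("<!DOCTYPE html>")
        assert html.count("<mark") == len(doc.annotations)


def test_document_json_schema_round_trips():
    import json
    doc = AnnotatedDocument(text="ab", literacy="high", annotations=[],
                            metadata={"seed": 0})
    obj = json.loads(doc.to_json())
    assert set(obj) == {"text", "literacy", "annotations", "metadata"}
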
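"""End-to-end pipeline: tag, filter, link, and annotate a medical document.

The pipeline runs: entity tagging -> medical stop-word removal -> overlap
resolution (longest span wins, leftmost on ties) -> term-difficulty
classification -> literacy policy filter -> candidate generation -> word
sense disambiguation -> depth-1 relation expansion. Readers with high
health literacy see annotations only on difficult terms; readers with low
health literacy see annotations on medium and difficult terms; easy terms
are never annotated.

Offsets are 0-based, half-open, over Unicode code points. Output is
canonical JSON (sorted keys); an optional self-contained HTML rendering
with inline highlights is presentational only.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import dataclass, field

from .difficulty import DifficultyClassifier
from .kb import TAXONOMIC_RELATIONS, KnowledgeBase
from .linker import NGramIndex, SenseModel, candidates, rank_candidates
from .ner import Mention, TaggerModel, tokenize_with_offsets

__all__ = ["Annotation", "AnnotatedDocument", "PipelineConfig",
           "select_by_policy", "annotate_document", "render_html"]

POLICY = {"high": {"difficult"}, "low": {"medium", "difficult"}}


@dataclass
class Annotation:
    start: int
    end: int
    surface: str
    concept_id: str
    difficulty: str
    definition: str
    related: list[tuple[str, str, str]]   # (relation_type, concept id, name)

    def to_json(self) -> dict:
        return {
            "start": self.start, "end": self.end, "surface": self.surface,
            "concept_id": self.concept_id, "difficulty": self.difficulty,
            "definition": self.definition,
            "related": [list(r) for r in self.related],
        }


@dataclass
class AnnotatedDocument:
    text: str
    literacy: str
    annotations: list[Annotation]
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        obj = {
            "text": self.text,
            "literacy": self.literacy,
            "annotations": [a.to_json() for a in self.annotations],
            "metadata": self.metadata,
        }
        return json.dumps(obj, sort_keys=True, ensure_ascii=False)


@dataclass
class PipelineConfig:
    k: int = 25
    wsd_window: int = 5
    relation_depth: int = 1
    relation_types: frozenset = frozenset(TAXONOMIC_RELATIONS | {"associative"})
    max_doc_chars: int = 200_000
    seed: int = 0


def select_by_policy(mentions: list[tuple[Mention, str]],
                     literacy: str) -> list[tuple[Mention, str]]:
    """Keep the mentions a reader at this literacy level needs annotated.

    High literacy: only difficult terms. Low literacy: medium and difficult.
    Easy terms are never kept. Input order is preserved.
    """
    if literacy not in POLICY:
        raise ValueError(f"literacy must be one of {sorted(POLICY)}, "
                         f"got {literacy!r}")
    keep = POLICY[literacy]
    return [(m, lab) for m, lab in mentions if lab in keep]


def _resolve_overlaps(mentions: list[Mention]) -> list[Mention]:
    """Longest span wins; ties break leftmost. Result sorted, non-overlapping."""
    chosen: list[Mention] = []
    for m in sorted(mentions, key=lambda m: (-(m.end - m.start), m.start)):
        if all(m.end <= c.start or m.start >= c.end for c in chosen):
            chosen.append(m)
    return sorted(chosen, key=lambda m: m.start)


def annotate_document(text: str, literacy: str, tagger: TaggerModel,
                      classifier: DifficultyClassifier, index: NGramIndex,
                      kb: KnowledgeBase, sense_model: SenseModel | None = None,
                      config: PipelineConfig | None = None) -> AnnotatedDocument:
    """Annotate ``text`` for a reader at the given literacy level.

    Deterministic given fixed model artifacts: repeated runs produce
    byte-identical JSON. Mentions with empty candidate sets are dropped.
    """
    cfg = config or PipelineConfig()
    if text is None:
        raise ValueError("text must not be None")
    if len(text) > cfg.max_doc_chars:
        raise ValueError(
            f"document has {len(text)} characters, exceeding the configured "
            f"limit of {cfg.max_doc_chars}")
    for name, artifact in [("tagger", tagger), ("difficulty classifier",
                           classifier), ("index", index), ("kb", kb)]:
        if artifact is None:
            raise ValueError(f"missing pipeline artifact: {name}")
    sense_model = sense_model or SenseModel(kb, window=cfg.wsd_window)

    mentions = _resolve_overlaps(tagger.tag_text(text))
    mentions = [m for m in mentions if not kb.is_stopword(m.surface)]

    labeled = [(m, classifier.predict(m.surface)) for m in mentions]
    selected = select_by_policy(labeled, literacy)

    toks = tokenize_with_offsets(text)
    annotations: list[Annotation] = []
    for mention, label in selected:
        cset = candidates(index, mention.surface, k=cfg.k)
        if not cset.candidates:
            continue
        # context = full token sequence with the mention position marked
        pos = next((i for i, (_, s, e) in enumerate(toks)
                    if s >= mention.start and e <= mention.end), None)
        linked = rank_candidates(cset, [t for t, _, _ in toks],
                                 sense_model, mention_position=pos)
        concept = kb.concepts[linked.concept_id]
        related = []
        for rid in sorted(kb.neighborhood(concept.id, cfg.relation_types,
                                          depth=cfg.relation_depth)):
            rtypes = sorted(t for t, tgt in concept.relations if tgt == rid)
            rtype = rtypes[0] if rtypes else "related"
            related.append((rtype, rid, kb.concepts[rid].name))
        annotations.append(Annotation(
            start=mention.start, end=mention.end, surface=mention.surface,
            concept_id=concept.id, difficulty=label,
            definition=concept.definition, related=related))

    annotations.sort(key=lambda a: a.start)
    return AnnotatedDocument(
        text=text, literacy=literacy, annotations=annotations,
        metadata={"k": cfg.k, "relation_depth": cfg.relation_depth,
                  "seed": cfg.seed, "n_tagged": len(mentions)})


def render_html(doc: AnnotatedDocument) -> str:
    """Self-contained HTML view with inline highlighted annotations."""
    parts = ["<!DOCTYPE html><html><head><meta charset='utf-8'>",
             "<style>mark{background:#cde5ff;border-radius:3px;padding:0 2px}",
             ".tip{font-size:0.85em;color:#333}</style></head><body><p>"]
    cursor = 0
    for a in doc.annotations:
        parts.append(_html.escape(doc.text[cursor:a.start]))
        tip = a.definition or a.concept_id
        parts.append(f"<mark title=\"{_html.escape(tip, quote=True)}\">"
                     f"{_html.escape(doc.text[a.start:a.end])}</mark>")
        cursor = a.end
    parts.append(_html.escape(doc.text[cursor:]))
    parts.append("</p><hr><ul>")
    for a in doc.annotations:
        rel = "; ".join(f"{t}: {name}" for t, _, name in a.related)
        parts.append(f"<li class='tip'><b>{_html.escape(a.surface)}</b> "
                     f"({a.difficulty}) — {_html.escape(a.definition)}"
                     f"{' — ' + _html.escape(rel) if rel else ''}</li>")
    parts.append("</ul></body></html>")
    return "".join(parts)
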
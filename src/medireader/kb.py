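"""License-free medical knowledge-base schema and operations.

A :class:`KnowledgeBase` plays the role that UMLS-plus-Wikidata plays in a
production deployment: a collection of concepts, each with a canonical name,
aliases, a plain-language definition, semantic types, and taxonomic /
associative relations (``instance_of``, ``subclass_of``, ``part_of``,
``has_part``, ``associative:<label>``). The on-disk format is JSONL, one
concept per line, so large vocabularies can be streamed.

Alias lookup goes through :func:`normalize`: NFC Unicode normalization,
case-folding and whitespace collapse. No stemming — stemming merges distinct
concepts unpredictably.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

logger = logging.getLogger(__name__)

TAXONOMIC_RELATIONS = frozenset({"instance_of", "subclass_of", "part_of", "has_part"})

_WS = re.compile(r"\s+")


class KBError(ValueError):
    """Raised for malformed KB files, duplicate ids or dangling relations."""


def normalize(s: str) -> str:
    """Normalize an alias surface: NFC, casefold, collapse whitespace.

    Idempotent: ``normalize(normalize(s)) == normalize(s)``.
    """
    return _WS.sub(" ", unicodedata.normalize("NFC", s).casefold()).strip()


@dataclass
class Concept:
    id: str
    name: str
    aliases: list[str] = field(default_factory=list)
    definition: str = ""
    semtypes: list[str] = field(default_factory=list)
    relations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise KBError("concept id must be non-empty")
        if not self.name:
            raise KBError(f"concept {self.id!r}: name must be non-empty")

    def all_surfaces(self) -> list[str]:
        """Canonical name plus aliases, deduplicated, order-preserving."""
        seen, out = set(), []
        for s in [self.name, *self.aliases]:
            key = normalize(s)
            if key not in seen:
                seen.add(key)
                out.append(s)
        return out

    def to_json(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "aliases": list(self.aliases),
            "definition": self.definition,
            "semtypes": list(self.semtypes),
            "relations": [{"type": t, "target": tgt} for t, tgt in self.relations],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Concept":
        rels = [(r["type"], r["target"]) for r in obj.get("relations", [])]
        return cls(
            id=obj["id"],
            name=obj["name"],
            aliases=list(obj.get("aliases", [])),
            definition=obj.get("definition", ""),
            semtypes=list(obj.get("semtypes", [])),
            relations=rels,
        )


class KnowledgeBase:
    """Indexed collection of :class:`Concept` with alias and relation access."""

    def __init__(self, concepts: list[Concept] | None = None,
                 stopwords: set[str] | None = None, strict: bool = False):
        self.concepts: dict[str, Concept] = {}
        self.alias_index: dict[str, set[str]] = {}
        self.stopwords: set[str] = set(stopwords or ())
        for c in concepts or []:
            self.add(c)
        self.validate(strict=strict)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts

    def __getitem__(self, cid: str) -> Concept:
        return self.concepts[cid]

    def add(self, concept: Concept) -> None:
        if concept.id in self.concepts:
            raise KBError(f"duplicate concept id {concept.id!r}")
        self.concepts[concept.id] = concept
        for surface in concept.all_surfaces():
            self.alias_index.setdefault(normalize(surface), set()).add(concept.id)

    def validate(self, strict: bool = False) -> None:
        """Check relation integrity; drop (or abort on) dangling targets."""
        for c in self.concepts.values():
            kept = []
            for rtype, target in c.relations:
                if target in self.concepts:
                    kept.append((rtype, target))
                elif strict:
                    raise KBError(
                        f"concept {c.id!r}: relation {rtype!r} targets "
                        f"unknown concept {target!r}")
                else:
                    logger.warning("dropping dangling relation %s -[%s]-> %s",
                                   c.id, rtype, target)
            c.relations = kept

    def lookup_alias(self, surface: str) -> set[str]:
        """All concept ids whose alias set contains the normalized surface."""
        return set(self.alias_index.get(normalize(surface), ()))

    def neighborhood(self, cid: str, relation_types: set[str] | None = None,
                     depth: int = 1) -> set[str]:
        """Concept ids reachable from ``cid`` within ``depth`` hops.

        Follows outgoing edges whose type is in ``relation_types`` (default:
        taxonomic plus associative). The start concept itself is excluded.
        """
        if cid not in self.concepts:
            raise KeyError(f"unknown concept id {cid!r}")
        if depth < 0:
            raise ValueError("depth must be >= 0")

        def follow(rtype: str) -> bool:
            if relation_types is None:
                return True
            return rtype in relation_types or (
                rtype.startswith("associative:") and "associative" in relation_types)

        frontier = {cid}
        reached: set[str] = set()
        for _ in range(depth):
            nxt: set[str] = set()
            for node in frontier:
                for rtype, target in self.concepts[node].relations:
                    if follow(rtype) and target not in reached and target != cid:
                        nxt.add(target)
            nxt -= reached
            if not nxt:
                break
            reached |= nxt
            frontier = nxt
        return reached

    def is_stopword(self, surface: str) -> bool:
        return normalize(surface) in self.stopwords

    def equal_content(self, other: "KnowledgeBase") -> bool:
        """Order-insensitive structural equality (for round-trip checks)."""
        if set(self.concepts) != set(other.concepts):
            return False
        for cid, c in self.concepts.items():
            o = other.concepts[cid]
            if (c.name != o.name or sorted(c.aliases) != sorted(o.aliases)
                    or c.definition != o.definition
                    or sorted(c.semtypes) != sorted(o.semtypes)
                    or sorted(c.relations) != sorted(o.relations)):
                return False
        return True


def load_stopwords(path: str | Path | None = None) -> set[str]:
    """Load the stop-word resource (one token per line, ``#`` comments)."""
    if path is None:
        text = _ilres.files("medireader.resources").joinpath(
            "stopwords.txt").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.add(normalize(line))
    return words


def load_kb(path: str | Path, strict: bool = False,
            stopwords_path: str | Path | None = None) -> KnowledgeBase:
    """Load a JSONL knowledge base; see module docstring for the schema.

    In strict mode a relation whose target id does not resolve aborts the
    load; otherwise such relations are logged and dropped.
    """
    path = Path(path)
    concepts = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise KBError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            concepts.append(Concept.from_json(obj))
    return KnowledgeBase(concepts, stopwords=load_stopwords(stopwords_path),
                         strict=strict)


def write_kb(kb: KnowledgeBase, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for cid in sorted(kb.concepts):
            fh.write(json.dumps(kb.concepts[cid].to_json(), sort_keys=True) + "\n")
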
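"""Shared domain types.

All character offsets are 0-based, half-open, and counted in Unicode code
points of the NFC-normalized *mined text* of a record (title + " " +
abstract).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Optional, Tuple

#: Closed vocabulary of bioentity classes.
ENTITY_CLASSES = frozenset({"protein", "gene", "taxon", "tissue", "cell_type"})

#: Classes that participate in co-occurrence pairing.
PAIRABLE_CLASSES = frozenset({"protein", "gene"})


@dataclass(frozen=True)
class Sentence:
    """One sentence of a record's mined text.

    ``start``/``end`` index into the mined text; ``text`` equals
    ``mined_text[start:end]``.
    """

    index: int
    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty sentence span [{self.start}, {self.end})")

    def contains_span(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class AbstractRecord:
    """One article: PMID, title, abstract and its sentence segmentation."""

    pmid: str
    title: str
    abstract: str
    sentences: Tuple[Sentence, ...] = field(default_factory=tuple)

    @property
    def text(self) -> str:
        """Mined text: title and abstract joined by a single space."""
        if self.abstract:
            return f"{self.title} {self.abstract}"
        return self.title

    @classmethod
    def build(cls, pmid: str, title: str, abstract: str) -> "AbstractRecord":
        """Create a record with NFC-normalized text and computed sentences."""
        from litcooc.corpus_io import split_sentences  # local: avoid cycle

        title = unicodedata.normalize("NFC", title or "").strip()
        abstract = unicodedata.normalize("NFC", abstract or "").strip()
        rec = cls(pmid=pmid, title=title, abstract=abstract)
        rec.sentences = tuple(split_sentences(rec.text))
        return rec

    def sentence_of_span(self, start: int, end: int) -> Optional[Sentence]:
        """The unique sentence fully containing ``[start, end)``, if any."""
        for sent in self.sentences:
            if sent.contains_span(start, end):
                return sent
        return None


@dataclass(frozen=True)
class EntityMention:
    """A located bioentity hit in a record's mined text."""

    pmid: str
    sentence_index: int
    start: int
    end: int
    surface: str
    normalized: str
    entity_class: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("mention span must be non-empty")
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity class {self.entity_class!r}")


@dataclass(frozen=True)
class TermMention:
    """A located biointeraction trigger-term hit.

    ``match_mode`` is ``"exact"`` for whole-token dictionary matches and
    ``"permissive"`` for stem-prefix matches that are not exact.
    """

    pmid: str
    sentence_index: int
    start: int
    end: int
    surface: str
    term: str
    match_mode: str

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact", "permissive"):
            raise ValueError(f"unknown match mode {self.match_mode!r}")


@dataclass(frozen=True)
class ConceptMention:
    """A located biological-concept hit (annotation only, never paired)."""

    pmid: str
    sentence_index: int
    start: int
    end: int
    surface: str
    concept: str


@dataclass(frozen=True)
class Cooccurrence:
    """An unordered pair of distinct normalized names in one abstract.

    ``type`` is the reliability tier: 1 (exact trigger strictly between
    the names in one sentence), 2 (exact trigger anywhere in a shared
    sentence), 3 (only permissive trigger hits in a shared sentence),
    4 (same abstract only).  ``entity_a < entity_b`` lexicographically.
    """

    pmid: str
    entity_a: str
    entity_b: str
    type: int
    evidence_sentence_index: Optional[int]
    terms: Tuple[str, ...]
    concepts: Tuple[str, ...]
    evidence_text: str = ""

    def __post_init__(self) -> None:
        if self.entity_a >= self.entity_b:
            raise ValueError("pair must be stored in lexicographic order")
        if self.type not in (1, 2, 3, 4):
            raise ValueError(f"invalid co-occurrence type {self.type}")
        if (self.type in (1, 2, 3)) != (self.evidence_sentence_index is not None):
            raise ValueError("evidence sentence present iff type in {1,2,3}")

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.entity_a, self.entity_b)


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    """Order a pair of names lexicographically."""
    return (a, b) if a < b else (b, a)
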
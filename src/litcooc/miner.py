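"""Classify co-mentioned protein/gene pairs into reliability types 1-4.

Type criteria, from most to least reliable:

1. both names in one sentence with an exact trigger term strictly
   between them;
2. both names in one sentence with an exact trigger term anywhere;
3. both names in one sentence with only permissive (stem-prefix) trigger
   hits;
4. both names anywhere in the abstract (same sentence not required).

One co-occurrence is reported per (pmid, pair) at the minimal qualifying
type; the evidence sentence is the earliest sentence achieving it.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from itertools import combinations
from pathlib import Path
from typing import Dict, IO, Iterable, List, Optional, Sequence, Set, Tuple, Union

from litcooc.lexicon import Lexicon
from litcooc.model import (
    PAIRABLE_CLASSES,
    AbstractRecord,
    ConceptMention,
    Cooccurrence,
    EntityMention,
    TermMention,
    canonical_pair,
)

logger = logging.getLogger(__name__)


def classify_pair_in_sentence(
    mention_a: EntityMention,
    mention_b: EntityMention,
    sentence_terms: Sequence[TermMention],
) -> Optional[int]:
    """Type of a single mention pair within one sentence, or ``None``.

    "Strictly between" means the term span lies inside the open interval
    between the earlier mention's end and the later mention's start.
    Raises ``ValueError`` if the mentions are in different sentences.
    """
    if mention_a.sentence_index != mention_b.sentence_index:
        raise ValueError("mentions must lie in the same sentence")
    earlier, later = sorted((mention_a, mention_b), key=lambda m: m.start)
    exact = [t for t in sentence_terms if t.match_mode == "exact"]
    if any(t.start >= earlier.end and t.end <= later.start for t in exact):
        return 1
    if exact:
        return 2
    if sentence_terms:
        return 3
    return None


def _sentence_evidence_terms(
    type_: int,
    mentions_a: Sequence[EntityMention],
    mentions_b: Sequence[EntityMention],
    sentence_terms: Sequence[TermMention],
) -> List[TermMention]:
    """Term mentions satisfying the given type's criterion in a sentence."""
    exact = [t for t in sentence_terms if t.match_mode == "exact"]
    if type_ == 1:
        keep = []
        for ma in mentions_a:
            for mb in mentions_b:
                earlier, later = sorted((ma, mb), key=lambda m: m.start)
                keep.extend(
                    t for t in exact if t.start >= earlier.end and t.end <= later.start
                )
        return sorted(set(keep), key=lambda t: t.start)
    if type_ == 2:
        return list(exact)
    if type_ == 3:
        return [t for t in sentence_terms if t.match_mode == "permissive"]
    return []


def mine_abstract(
    record: AbstractRecord,
    entity_mentions: Sequence[EntityMention],
    term_mentions: Sequence[TermMention],
    concept_mentions: Sequence[ConceptMention] = (),
) -> List[Cooccurrence]:
    """Mine all typed co-occurrences of one abstract.

    Every unordered pair of distinct normalized protein/gene names with at
    least one mention each is reported exactly once, at the minimum type
    over all same-sentence mention combinations (4 when no sentence is
    shared).  Concepts from the evidence sentence (types 1-3) or the whole
    abstract (type 4) are attached as annotations.  Output is sorted by
    pair.
    """
    pairable = [m for m in entity_mentions if m.entity_class in PAIRABLE_CLASSES]
    by_name: Dict[str, List[EntityMention]] = defaultdict(list)
    for m in pairable:
        by_name[m.normalized].append(m)
    terms_by_sentence: Dict[int, List[TermMention]] = defaultdict(list)
    for t in term_mentions:
        terms_by_sentence[t.sentence_index].append(t)

    results: List[Cooccurrence] = []
    for name_a, name_b in combinations(sorted(by_name), 2):
        best_type: Optional[int] = None
        best_sentence: Optional[int] = None
        best_terms: List[TermMention] = []
        sent_a = defaultdict(list)
        sent_b = defaultdict(list)
        for m in by_name[name_a]:
            sent_a[m.sentence_index].append(m)
        for m in by_name[name_b]:
            sent_b[m.sentence_index].append(m)
        for sent_idx in sorted(set(sent_a) & set(sent_b)):
            sentence_terms = terms_by_sentence.get(sent_idx, [])
            type_here: Optional[int] = None
            for ma in sent_a[sent_idx]:
                for mb in sent_b[sent_idx]:
                    t = classify_pair_in_sentence(ma, mb, sentence_terms)
                    if t is not None and (type_here is None or t < type_here):
                        type_here = t
            if type_here is not None and (best_type is None or type_here < best_type):
                best_type = type_here
                best_sentence = sent_idx
                best_terms = _sentence_evidence_terms(
                    type_here, sent_a[sent_idx], sent_b[sent_idx], sentence_terms
                )
                if best_type == 1:
                    break
        if best_type is None:
            type_ = 4
            evidence_idx = None
            evidence_text = ""
            concepts = sorted({c.concept for c in concept_mentions})
        else:
            type_ = best_type
            evidence_idx = best_sentence
            evidence_text = record.sentences[best_sentence].text
            concepts = sorted(
                {c.concept for c in concept_mentions if c.sentence_index == best_sentence}
            )
        a, b = canonical_pair(name_a, name_b)
        results.append(
            Cooccurrence(
                pmid=record.pmid,
                entity_a=a,
                entity_b=b,
                type=type_,
                evidence_sentence_index=evidence_idx,
                terms=tuple(sorted({t.term for t in best_terms})),
                concepts=tuple(concepts),
                evidence_text=evidence_text,
            )
        )
    results.sort(key=lambda c: (c.entity_a, c.entity_b))
    return results


def mine_record(
    record: AbstractRecord,
    lexicon: Lexicon,
    entity_mentions: Optional[Sequence[EntityMention]] = None,
) -> List[Cooccurrence]:
    """Tag one record (unless external tags are supplied) and mine it."""
    from litcooc.tagger import tag_concepts, tag_entities, tag_terms

    if entity_mentions is None:
        entity_mentions = tag_entities(record, lexicon)
    return mine_abstract(
        record,
        entity_mentions,
        tag_terms(record, lexicon),
        tag_concepts(record, lexicon),
    )


def abstract_tax_ids(record: AbstractRecord, lexicon: Lexicon) -> Set[int]:
    """NCBI tax ids of all taxon mentions in a record."""
    from litcooc.tagger import tag_entities

    ids: Set[int] = set()
    for m in tag_entities(record, lexicon):
        if m.entity_class == "taxon":
            tax_id = lexicon.resolve_taxon(m.normalized)
            if tax_id is not None:
                ids.add(tax_id)
    return ids


def filter_by_taxon(
    cooccurrences: Iterable[Cooccurrence],
    records: Sequence[AbstractRecord],
    tax_id: int,
    lexicon: Lexicon,
) -> List[Cooccurrence]:
    """Keep co-occurrences whose abstract mentions the given taxon.

    A co-occurrence is retained iff its abstract contains at least one
    taxon mention resolving to ``tax_id``.  Pure filter; an unknown
    ``tax_id`` legally selects nothing.
    """
    matching = {r.pmid for r in records if tax_id in abstract_tax_ids(r, lexicon)}
    return [c for c in cooccurrences if c.pmid in matching]


def select_type(
    cooccurrences: Iterable[Cooccurrence], max_type: int
) -> List[Cooccurrence]:
    """Order-preserving filter keeping co-occurrences with type <= max_type."""
    if max_type not in (1, 2, 3, 4):
        raise ValueError("max_type must be in {1, 2, 3, 4}")
    return [c for c in cooccurrences if c.type <= max_type]


# ---------------------------------------------------------------------------
# co-occurrence TSV (the miner output consumed by the summary generator)
# ---------------------------------------------------------------------------

COOC_COLUMNS = (
    "pmid",
    "entity_a",
    "entity_b",
    "type",
    "sentence_index",
    "terms",
    "concepts",
    "evidence_sentence_text",
)


def write_cooccurrence_tsv(
    cooccurrences: Iterable[Cooccurrence], destination: Union[str, Path, IO[str]]
) -> int:
    own = isinstance(destination, (str, Path))
    fh: IO[str] = open(destination, "w", encoding="utf-8", newline="") if own else destination
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COOC_COLUMNS)
        n = 0
        for c in cooccurrences:
            writer.writerow(
                [
                    c.pmid,
                    c.entity_a,
                    c.entity_b,
                    c.type,
                    "" if c.evidence_sentence_index is None else c.evidence_sentence_index,
                    ";".join(c.terms),
                    ";".join(c.concepts),
                    c.evidence_text,
                ]
            )
            n += 1
        return n
    finally:
        if own:
            fh.close()


def read_cooccurrence_tsv(source: Union[str, Path, IO[str]]) -> List[Cooccurrence]:
    """Read a miner output TSV; malformed rows are skipped with a warning."""
    own = isinstance(source, (str, Path))
    fh: IO[str] = open(source, "r", encoding="utf-8", newline="") if own else source
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and tuple(header) != COOC_COLUMNS:
            raise ValueError(f"unexpected co-occurrence header: {header!r}")
        rows: List[Cooccurrence] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                pmid, a, b, type_s, sent_s, terms_s, concepts_s, evidence = row
                rows.append(
                    Cooccurrence(
                        pmid=pmid,
                        entity_a=a,
                        entity_b=b,
                        type=int(type_s),
                        evidence_sentence_index=int(sent_s) if sent_s else None,
                        terms=tuple(t for t in terms_s.split(";") if t),
                        concepts=tuple(c for c in concepts_s.split(";") if c),
                        evidence_text=evidence,
                    )
                )
            except (ValueError, TypeError) as exc:
                logger.warning("co-occurrence line %d malformed (%s), skipped", lineno, exc)
        return rows
    finally:
        if own:
            fh.close()
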
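"""Dictionary-based tagging of bioentities, trigger terms and concepts.

This is the pipeline's stand-in for an external NER stage; externally
produced tags can be imported through the interchange TSV instead, in
which case they *replace* dictionary entity tagging for those records.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from litcooc.lexicon import Lexicon, tokenize_with_spans
from litcooc.model import AbstractRecord, ConceptMention, EntityMention, TermMention

logger = logging.getLogger(__name__)


def _greedy_matches(
    tokens: Sequence[Tuple[str, int, int]],
    dictionary: Mapping[str, object],
    max_width: int,
) -> List[Tuple[int, int, int, int, str]]:
    """Left-to-right longest-match over a token sequence.

    Returns ``(tok_start_idx, tok_end_idx, char_start, char_end, key)``
    tuples.  At each position the longest dictionary n-gram wins and the
    matched tokens are consumed, so matches never overlap and ties go to
    the leftmost candidate.
    """
    folded = [tok.casefold() for tok, _, _ in tokens]
    out = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for width in range(min(max_width, n - i), 0, -1):
            key = " ".join(folded[i : i + width])
            if key in dictionary:
                out.append((i, i + width, tokens[i][1], tokens[i + width - 1][2], key))
                i += width
                matched = True
                break
        if not matched:
            i += 1
    return out


def tag_entities(record: AbstractRecord, lexicon: Lexicon) -> List[EntityMention]:
    """Tag bioentity mentions sentence by sentence.

    Matching is case-insensitive, whole-token-boundary anchored,
    left-to-right longest-match; mentions are returned in
    ``(sentence_index, start)`` order and never overlap.  Pure function of
    (record text, lexicon).
    """
    mentions: List[EntityMention] = []
    text = record.text
    for sent in record.sentences:
        tokens = [
            (tok, sent.start + s, sent.start + e)
            for tok, s, e in tokenize_with_spans(sent.text)
        ]
        for _, _, start, end, key in _greedy_matches(
            tokens, lexicon.bioentities, lexicon.max_entity_tokens
        ):
            _, normalized, entity_class = lexicon.bioentities[key]
            mentions.append(
                EntityMention(
                    pmid=record.pmid,
                    sentence_index=sent.index,
                    start=start,
                    end=end,
                    surface=text[start:end],
                    normalized=normalized,
                    entity_class=entity_class,
                )
            )
    return mentions


def tag_terms(record: AbstractRecord, lexicon: Lexicon) -> List[TermMention]:
    """Tag trigger-term mentions in both exact and permissive modes.

    Each matched span is reported once with the strongest mode (exact
    preferred); permissive hits are single tokens whose case-folded form
    starts with a term's stem.
    """
    mentions: List[TermMention] = []
    text = record.text
    for sent in record.sentences:
        tokens = [
            (tok, sent.start + s, sent.start + e)
            for tok, s, e in tokenize_with_spans(sent.text)
        ]
        exact = _greedy_matches(tokens, lexicon.interaction_terms, lexicon.max_term_tokens)
        exact_spans = []
        for _, _, start, end, key in exact:
            exact_spans.append((start, end))
            mentions.append(
                TermMention(
                    pmid=record.pmid,
                    sentence_index=sent.index,
                    start=start,
                    end=end,
                    surface=text[start:end],
                    term=lexicon.interaction_terms[key],
                    match_mode="exact",
                )
            )
        for tok, start, end in tokens:
            if any(s < end and start < e for s, e in exact_spans):
                continue
            candidates = lexicon.permissive_terms_for_token(tok)
            if candidates:
                mentions.append(
                    TermMention(
                        pmid=record.pmid,
                        sentence_index=sent.index,
                        start=start,
                        end=end,
                        surface=text[start:end],
                        term=candidates[0],
                        match_mode="permissive",
                    )
                )
    mentions.sort(key=lambda m: (m.sentence_index, m.start))
    return mentions


def tag_concepts(record: AbstractRecord, lexicon: Lexicon) -> List[ConceptMention]:
    """Tag biological-concept mentions (annotation only, never paired)."""
    mentions: List[ConceptMention] = []
    text = record.text
    for sent in record.sentences:
        tokens = [
            (tok, sent.start + s, sent.start + e)
            for tok, s, e in tokenize_with_spans(sent.text)
        ]
        for _, _, start, end, key in _greedy_matches(
            tokens, lexicon.concepts, lexicon.max_concept_tokens
        ):
            mentions.append(
                ConceptMention(
                    pmid=record.pmid,
                    sentence_index=sent.index,
                    start=start,
                    end=end,
                    surface=text[start:end],
                    concept=lexicon.concepts[key],
                )
            )
    return mentions


def import_external_tags(
    tags_by_pmid: Mapping[str, Iterable[EntityMention]],
    records: Sequence[AbstractRecord],
) -> Dict[str, List[EntityMention]]:
    """Attach externally produced entity tags to records.

    Spans are re-validated: rows for unknown PMIDs and spans that cross a
    sentence boundary (or fall outside the mined text) are dropped with a
    warning.  The result replaces dictionary entity tagging for the
    covered records.
    """
    by_pmid = {r.pmid: r for r in records}
    out: Dict[str, List[EntityMention]] = {}
    for pmid, mentions in tags_by_pmid.items():
        record = by_pmid.get(pmid)
        if record is None:
            logger.warning("external tags for unknown PMID %s dropped", pmid)
            continue
        kept: List[EntityMention] = []
        for m in mentions:
            sent = record.sentence_of_span(m.start, m.end)
            if sent is None:
                logger.warning(
                    "external tag span [%d,%d) for PMID %s crosses a sentence "
                    "boundary or lies outside the text; dropped",
                    m.start,
                    m.end,
                    pmid,
                )
                continue
            kept.append(
                EntityMention(
                    pmid=pmid,
                    sentence_index=sent.index,
                    start=m.start,
                    end=m.end,
                    surface=m.surface,
                    normalized=m.normalized,
                    entity_class=m.entity_class,
                    score=m.score,
                )
            )
        kept.sort(key=lambda m: (m.sentence_index, m.start))
        out[pmid] = kept
    return out
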
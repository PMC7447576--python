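"""Read PubMed/MEDLINE XML, segment sentences, and the tag-interchange TSV.

The tag-interchange TSV is the hand-off format between an external entity
tagger and the miner: tab-separated, UTF-8, LF line endings, header row
``pmid  start  end  surface  normalized  entity_class  score``.
"""

from __future__ import annotations

import csv
import io
import logging
import re
import unicodedata
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, IO, Iterable, List, Sequence, Tuple, Union

from litcooc.model import ENTITY_CLASSES, AbstractRecord, EntityMention, Sentence

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO[bytes]]

# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

#: Tokens (case-folded, including the trailing period) that never end a
#: sentence.  Single uppercase letters followed by a period ("E.") are
#: suppressed by pattern, not by list.
ABBREVIATIONS = frozenset(
    {
        "al.",
        "approx.",
        "ca.",
        "cf.",
        "dr.",
        "e.g.",
        "et al.",
        "etc.",
        "fig.",
        "figs.",
        "i.e.",
        "no.",
        "nov.",
        "sp.",
        "spp.",
        "vs.",
    }
)

_TERMINATOR_RE = re.compile(r"[.!?]+(?=\s|$)")
_SINGLE_INITIAL_RE = re.compile(r"^[A-Za-z]\.$")


def _is_abbreviation(prefix: str) -> bool:
    m = re.search(r"(\S+)$", prefix)
    if not m:
        return True  # terminator with no preceding word: not a boundary
    token = m.group(1)
    if _SINGLE_INITIAL_RE.match(token):
        return True
    return token.casefold() in ABBREVIATIONS


def split_sentences(text: str) -> List[Sentence]:
    """Deterministic rule-based sentence segmentation.

    A terminator run (``.``, ``!``, ``?``) followed by whitespace ends a
    sentence unless the preceding token is a known abbreviation or a
    single initial ("E.").  Every non-whitespace character of ``text``
    belongs to exactly one sentence.  (The follower's case is deliberately
    ignored: gene names such as "matK" legally start a sentence.)
    """
    if not text or not text.strip():
        return []
    cuts = [0]
    for m in _TERMINATOR_RE.finditer(text):
        if _is_abbreviation(text[: m.end()]):
            continue
        cuts.append(m.end())
    if cuts[-1] != len(text):
        cuts.append(len(text))
    sentences: List[Sentence] = []
    for lo, hi in zip(cuts, cuts[1:]):
        chunk = text[lo:hi]
        stripped = chunk.strip()
        if not stripped:
            continue
        start = lo + (len(chunk) - len(chunk.lstrip()))
        end = start + len(stripped)
        sentences.append(Sentence(index=len(sentences), text=stripped, start=start, end=end))
    return sentences


# ---------------------------------------------------------------------------
# MEDLINE / PubMed XML
# ---------------------------------------------------------------------------


def _element_text(elem: ET.Element) -> str:
    return "".join(elem.itertext()).strip()


def parse_medline_xml(xml_source: Source) -> List[AbstractRecord]:
    """Parse PubMed/MEDLINE XML into abstract records, in document order.

    Accepts both ``PubmedArticleSet`` and ``MedlineCitationSet`` roots.
    Structured abstracts (multiple ``AbstractText`` children) are joined
    with a single space.  Articles without an abstract yield a record with
    an empty abstract; articles without a PMID are skipped with a warning.

    Raises :class:`xml.etree.ElementTree.ParseError` (which carries the
    line/column position) on malformed XML.
    """
    if isinstance(xml_source, (str, Path)):
        tree = ET.parse(str(xml_source))
        root = tree.getroot()
    else:
        root = ET.parse(xml_source).getroot()

    if root.tag == "MedlineCitationSet":
        citations = root.findall("MedlineCitation")
    else:
        citations = [
            art.find("MedlineCitation")
            for art in root.findall(".//PubmedArticle")
        ]

    records: List[AbstractRecord] = []
    seen = set()
    n_no_abstract = 0
    for cit in citations:
        if cit is None:
            continue
        pmid_el = cit.find("PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            logger.warning("record without PMID skipped")
            continue
        pmid = pmid_el.text.strip()
        if pmid in seen:
            logger.warning("duplicate PMID %s: keeping first occurrence", pmid)
            continue
        seen.add(pmid)
        article = cit.find("Article")
        title = ""
        abstract = ""
        if article is not None:
            title_el = article.find("ArticleTitle")
            if title_el is not None:
                title = _element_text(title_el)
            abstract_el = article.find("Abstract")
            if abstract_el is not None:
                parts = [
                    _element_text(t)
                    for t in abstract_el.findall("AbstractText")
                ]
                abstract = " ".join(p for p in parts if p)
        if not abstract:
            n_no_abstract += 1
        records.append(AbstractRecord.build(pmid=pmid, title=title, abstract=abstract))
    if n_no_abstract:
        logger.info("%d of %d records have no abstract", n_no_abstract, len(records))
    return records


# ---------------------------------------------------------------------------
# tag-interchange TSV
# ---------------------------------------------------------------------------

INTERCHANGE_COLUMNS = ("pmid", "start", "end", "surface", "normalized", "entity_class", "score")


def write_tag_interchange(
    mentions: Iterable[EntityMention], destination: Union[str, Path, IO[str]]
) -> int:
    """Write entity mentions to the interchange TSV; returns the row count."""
    own = isinstance(destination, (str, Path))
    fh: IO[str] = open(destination, "w", encoding="utf-8", newline="") if own else destination
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(INTERCHANGE_COLUMNS)
        n = 0
        for m in mentions:
            writer.writerow(
                [m.pmid, m.start, m.end, m.surface, m.normalized, m.entity_class, repr(m.score)]
            )
            n += 1
        return n
    finally:
        if own:
            fh.close()


def read_tag_interchange(
    source: Union[str, Path, IO[str]],
) -> Dict[str, List[EntityMention]]:
    """Read the interchange TSV back into mentions grouped by PMID.

    Rows with an unknown ``entity_class`` or non-numeric spans are rejected
    with a warning.  Sentence indices are unknown at this stage (-1); they
    are recomputed when the mentions are attached to records.
    """
    own = isinstance(source, (str, Path))
    fh: IO[str] = open(source, "r", encoding="utf-8", newline="") if own else source
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and tuple(header) != INTERCHANGE_COLUMNS:
            raise ValueError(f"unexpected interchange header: {header!r}")
        by_pmid: Dict[str, List[EntityMention]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(INTERCHANGE_COLUMNS):
                logger.warning("interchange line %d: wrong column count, rejected", lineno)
                continue
            pmid, start_s, end_s, surface, normalized, entity_class, score_s = row
            if entity_class not in ENTITY_CLASSES:
                logger.warning(
                    "interchange line %d: unknown entity_class %r, rejected",
                    lineno,
                    entity_class,
                )
                continue
            try:
                start, end, score = int(start_s), int(end_s), float(score_s)
            except ValueError:
                logger.warning("interchange line %d: bad numeric field, rejected", lineno)
                continue
            if end <= start:
                logger.warning("interchange line %d: empty span, rejected", lineno)
                continue
            mention = EntityMention(
                pmid=pmid,
                sentence_index=-1,
                start=start,
                end=end,
                surface=unicodedata.normalize("NFC", surface),
                normalized=unicodedata.normalize("NFC", normalized),
                entity_class=entity_class,
                score=score,
            )
            by_pmid.setdefault(pmid, []).append(mention)
        return by_pmid
    finally:
        if own:
            fh.close()


def interchange_to_string(mentions: Iterable[EntityMention]) -> str:
    buf = io.StringIO()
    write_tag_interchange(mentions, buf)
    return buf.getvalue()
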
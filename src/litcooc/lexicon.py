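"""In-memory lexicon of bioentities, trigger terms, concepts and taxa.

The whole dictionary travels as one TSV file and is loaded fully into
memory by every worker; after loading, the store is read-only.  Row
format (tab-separated, ``#`` comments allowed)::

    BIOENTITY <surface> <normalized> <entity_class>
    TERM      <trigger term>
    CONCEPT   <concept term>
    TAXON     <name> <ncbi tax id>

Lookups are case-insensitive.  "Permissive" trigger matching means
stem-prefix matching: a token hits a term when its case-folded form
starts with the term's suffix-stripped stem (minimum stem length 4).
"""

from __future__ import annotations

import hashlib
import logging
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

from litcooc.model import ENTITY_CLASSES

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[0-9A-Za-z](?:[0-9A-Za-z.\-]*[0-9A-Za-z])?")

#: Suffixes stripped (longest first) to obtain a term's stem.
STEM_SUFFIXES = ("ation", "tion", "ion", "ing", "ed", "es", "s")

MIN_STEM_LENGTH = 4


def tokenize_with_spans(text: str) -> List[Tuple[str, int, int]]:
    """Tokens of ``text`` with their (start, end) spans.

    Tokens are alphanumeric runs; internal hyphens and periods are kept
    (``PR-1``, ``PDF1.2``) but trailing punctuation is not.
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def normalize_key(surface: str) -> str:
    """Case-folded, token-normalized lookup key for a surface string."""
    return " ".join(tok.casefold() for tok, _, _ in tokenize_with_spans(surface))


def stem_term(term: str) -> str:
    """Suffix-stripped stem of a (case-folded) trigger term.

    Strips the longest matching suffix from :data:`STEM_SUFFIXES` provided
    the remainder keeps at least :data:`MIN_STEM_LENGTH` characters;
    otherwise the term is its own stem.
    """
    term = term.casefold()
    for suffix in STEM_SUFFIXES:
        if term.endswith(suffix) and len(term) - len(suffix) >= MIN_STEM_LENGTH:
            return term[: -len(suffix)]
    return term


@dataclass(frozen=True)
class Lexicon:
    """Immutable in-memory dictionary store."""

    #: lookup key -> (original surface, normalized name, entity class)
    bioentities: Dict[str, Tuple[str, str, str]]
    #: lookup key -> original trigger term
    interaction_terms: Dict[str, str]
    #: term -> stem (single-token terms only; min length enforced at load)
    term_stems: Dict[str, str]
    #: lookup key -> original concept term
    concepts: Dict[str, str]
    #: taxon synonym key -> NCBI tax id
    taxa: Dict[str, int]
    #: tax id -> sorted original synonym surfaces
    taxon_names: Dict[int, Tuple[str, ...]]
    source_digest: str = ""
    max_entity_tokens: int = field(default=1)
    max_term_tokens: int = field(default=1)
    max_concept_tokens: int = field(default=1)

    def resolve_taxon(self, name: str) -> Optional[int]:
        """Case-insensitive taxon synonym lookup; ``None`` when unknown."""
        return self.taxa.get(normalize_key(name))

    def lookup_term(self, tokens: Sequence[str], mode: str = "exact") -> List[str]:
        """Dictionary trigger terms matched by a token sequence.

        ``exact``: case-insensitive whole-token matches (multi-word terms
        match contiguous token runs).  ``permissive``: exact matches plus
        stem-prefix matches of single tokens, so exact hits are always a
        subset of permissive hits.
        """
        if mode not in ("exact", "permissive"):
            raise ValueError(f"unknown mode {mode!r}")
        folded = [t.casefold() for t in tokens]
        hits = set()
        for i in range(len(folded)):
            for width in range(1, self.max_term_tokens + 1):
                if i + width > len(folded):
                    break
                key = " ".join(folded[i : i + width])
                if key in self.interaction_terms:
                    hits.add(self.interaction_terms[key])
        if mode == "permissive":
            for tok in folded:
                for term, stem in self.term_stems.items():
                    if tok.startswith(stem):
                        hits.add(term)
        return sorted(hits)

    def permissive_terms_for_token(self, token: str) -> List[str]:
        """Terms whose stem is a prefix of the case-folded token."""
        tok = token.casefold()
        matches = [term for term, stem in self.term_stems.items() if tok.startswith(stem)]
        matches.sort(key=lambda t: (-len(self.term_stems[t]), t))
        return matches


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_lexicon(dict_file: Union[str, Path]) -> Lexicon:
    """Load the full dictionary TSV into an immutable in-memory store.

    Duplicate rows are deduplicated; rows with an unknown type tag are
    skipped with a warning; a missing file is fatal.  Loading is
    repeatable: two loads of the same file yield equal stores with the
    same ``source_digest``.
    """
    path = Path(dict_file)
    if not path.is_file():
        raise FileNotFoundError(f"lexicon file not found: {path}")

    bioentities: Dict[str, Tuple[str, str, str]] = {}
    interaction_terms: Dict[str, str] = {}
    term_stems: Dict[str, str] = {}
    concepts: Dict[str, str] = {}
    taxa: Dict[str, int] = {}
    taxon_names: Dict[int, set] = {}

    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0].strip().upper()
            if tag == "BIOENTITY" and len(fields) >= 4:
                surface, normalized, entity_class = (f.strip() for f in fields[1:4])
                if entity_class not in ENTITY_CLASSES:
                    logger.warning("line %d: unknown entity class %r, skipped", lineno, entity_class)
                    continue
                bioentities.setdefault(normalize_key(surface), (surface, normalized, entity_class))
            elif tag == "TERM" and len(fields) >= 2:
                term = fields[1].strip()
                key = normalize_key(term)
                if len(key.replace(" ", "")) < MIN_STEM_LENGTH:
                    logger.warning("line %d: trigger term %r shorter than stem minimum, skipped", lineno, term)
                    continue
                interaction_terms.setdefault(key, term)
                if " " not in key:
                    term_stems.setdefault(interaction_terms[key], stem_term(key))
            elif tag == "CONCEPT" and len(fields) >= 2:
                concept = fields[1].strip()
                concepts.setdefault(normalize_key(concept), concept)
            elif tag == "TAXON" and len(fields) >= 3:
                name = fields[1].strip()
                try:
                    tax_id = int(fields[2])
                except ValueError:
                    logger.warning("line %d: bad tax id %r, skipped", lineno, fields[2])
                    continue
                if tax_id <= 0:
                    logger.warning("line %d: non-positive tax id, skipped", lineno)
                    continue
                key = normalize_key(name)
                if key in taxa and taxa[key] != tax_id:
                    logger.warning("line %d: conflicting tax id for %r, keeping first", lineno, name)
                    continue
                taxa.setdefault(key, tax_id)
                taxon_names.setdefault(tax_id, set()).add(name)
                # taxon names are also taggable bioentities of class "taxon"
                bioentities.setdefault(key, (name, name, "taxon"))
            else:
                logger.warning("line %d: unknown row type %r, skipped", lineno, fields[0])

    def _width(keys) -> int:
        return max((k.count(" ") + 1 for k in keys), default=1)

    return Lexicon(
        bioentities=bioentities,
        interaction_terms=interaction_terms,
        term_stems=term_stems,
        concepts=concepts,
        taxa=taxa,
        taxon_names={tid: tuple(sorted(names)) for tid, names in taxon_names.items()},
        source_digest=_digest(path),
        max_entity_tokens=_width(bioentities),
        max_term_tokens=_width(interaction_terms),
        max_concept_tokens=_width(concepts),
    )


def default_lexicon_path() -> Path:
    """Path of the bundled demonstration lexicon."""
    return Path(__file__).parent / "data" / "plant_lexicon.tsv"


def export_sqlite(lexicon: Lexicon, db_path: Union[str, Path]) -> None:
    """Export the store to an SQLite file for interoperability."""
    con = sqlite3.connect(str(db_path))
    try:
        cur = con.cursor()
        cur.executescript(
            """
            DROP TABLE IF EXISTS bioentities;
            DROP TABLE IF EXISTS interaction_terms;
            DROP TABLE IF EXISTS concepts;
            DROP TABLE IF EXISTS taxa;
            CREATE TABLE bioentities (key TEXT PRIMARY KEY, surface TEXT, normalized TEXT, entity_class TEXT);
            CREATE TABLE interaction_terms (key TEXT PRIMARY KEY, term TEXT, stem TEXT);
            CREATE TABLE concepts (key TEXT PRIMARY KEY, concept TEXT);
            CREATE TABLE taxa (key TEXT PRIMARY KEY, tax_id INTEGER);
            """
        )
        cur.executemany(
            "INSERT INTO bioentities VALUES (?, ?, ?, ?)",
            [(k, s, n, c) for k, (s, n, c) in sorted(lexicon.bioentities.items())],
        )
        cur.executemany(
            "INSERT INTO interaction_terms VALUES (?, ?, ?)",
            [
                (k, t, lexicon.term_stems.get(t, ""))
                for k, t in sorted(lexicon.interaction_terms.items())
            ],
        )
        cur.executemany("INSERT INTO concepts VALUES (?, ?)", sorted(lexicon.concepts.items()))
        cur.executemany("INSERT INTO taxa VALUES (?, ?)", sorted(lexicon.taxa.items()))
        con.commit()
    finally:
        con.close()
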
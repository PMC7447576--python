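"""Seeded synthetic PubMed-XML corpora with planted, ground-truthed pairs.

Templates guarantee that each planted pair's *minimal* qualifying type is
the requested one: type-1 sentences place an exact trigger strictly
between the two names, type-2 sentences place it outside the between
interval, type-3 sentences use only a stem-variant surface that matches
permissively but not exactly, and type-4 abstracts split the names across
trigger-free sentences.  Filler and decoy tokens are verified absent from
the lexicon (also as stem-prefix matches), so mined output on an
easy-mode corpus equals the ground truth exactly.
"""

from __future__ import annotations

import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from litcooc.lexicon import Lexicon, normalize_key, tokenize_with_spans
from litcooc.model import PAIRABLE_CLASSES, AbstractRecord, canonical_pair

_STARTERS = ("Notably", "Moreover", "Overall", "Additionally", "Furthermore", "Meanwhile")
_FILLERS = (
    "study",
    "result",
    "sample",
    "field",
    "summer",
    "winter",
    "river",
    "garden",
    "window",
    "basket",
    "yellow",
    "purple",
    "mountain",
    "valley",
)
_VARIANT_SUFFIXES = ("ion", "ing", "ation", "ment", "ory")
#: fixed template words; must never hit the lexicon
_GLUE = (
    "near",
    "the",
    "were",
    "in",
    "and",
    "during",
    "within",
    "appeared",
    "occurred",
    "surveys",
    "covered",
    "populations",
    "stayed",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Plan for one synthetic corpus."""

    n_abstracts: int
    k1: int = 0
    k2: int = 0
    k3: int = 0
    k4: int = 0
    taxon_plan: Dict[int, float] = field(default_factory=dict)
    decoy_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("planted counts must be non-negative")
        if self.k1 + self.k2 + self.k3 + self.k4 > self.n_abstracts:
            raise ValueError("more planted pairs than abstracts")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValueError("decoy_rate must be in [0, 1]")
        for frac in self.taxon_plan.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("taxon fractions must be in [0, 1]")


@dataclass
class GroundTruth:
    """Expected mining results for a generated corpus."""

    #: (pmid, entity_a, entity_b, type), pair canonical
    interactions: List[Tuple[str, str, str, int]] = field(default_factory=list)
    tax_ids_by_pmid: Dict[str, Tuple[int, ...]] = field(default_factory=dict)

    def write_tsv(self, path: Union[str, Path]) -> None:
        lines = ["pmid\tentity_a\tentity_b\ttype\ttax_ids"]
        by_pmid = {p: (a, b, t) for p, a, b, t in self.interactions}
        for pmid in sorted(self.tax_ids_by_pmid, key=int):
            a, b, t = by_pmid.get(pmid, ("", "", ""))
            tax = ";".join(str(x) for x in self.tax_ids_by_pmid[pmid])
            lines.append(f"{pmid}\t{a}\t{b}\t{t}\t{tax}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _is_safe_word(word: str, lexicon: Lexicon) -> bool:
    """True when a token cannot hit the lexicon in any mode."""
    key = normalize_key(word)
    if not key or " " in key:
        return False
    if key in lexicon.bioentities or key in lexicon.interaction_terms:
        return False
    if key in lexicon.concepts or key in lexicon.taxa:
        return False
    return not any(key.startswith(stem) for stem in lexicon.term_stems.values())


def _safe_words(words: Sequence[str], lexicon: Lexicon) -> List[str]:
    safe = [w for w in words if _is_safe_word(w, lexicon)]
    if not safe:
        raise ValueError("no lexicon-safe filler words available")
    return safe


def _pairable_surfaces(lexicon: Lexicon) -> List[Tuple[str, str]]:
    """(surface, normalized) of plantable protein/gene names, deduplicated."""
    out = {}
    for surface, normalized, cls in lexicon.bioentities.values():
        if cls not in PAIRABLE_CLASSES:
            continue
        if " " in normalize_key(surface):
            continue  # single-token names keep templates unambiguous
        if any(
            normalize_key(surface).startswith(stem)
            for stem in lexicon.term_stems.values()
        ):
            continue
        out.setdefault(normalized, surface)
    return sorted((s, n) for n, s in out.items())


def permissive_only_variant(lexicon: Lexicon) -> Optional[Tuple[str, str]]:
    """A (term, surface) pair where the surface matches only permissively."""
    for key in sorted(lexicon.interaction_terms):
        term = lexicon.interaction_terms[key]
        stem = lexicon.term_stems.get(term)
        if stem is None:
            continue
        for suffix in _VARIANT_SUFFIXES:
            cand = stem + suffix
            if cand == key:
                continue
            if cand in lexicon.interaction_terms or cand in lexicon.bioentities:
                continue
            if cand in lexicon.concepts or cand in lexicon.taxa:
                continue
            return term, cand
    return None


def _decoy(rng: random.Random, lexicon: Lexicon) -> str:
    while True:
        word = "zx" + "".join(rng.choice("abcdefghijklmnopqrstuvwxyz") for _ in range(6))
        if _is_safe_word(word, lexicon):
            return word


class _AbstractBuilder:
    def __init__(self, rng: random.Random, starters: List[str], fillers: List[str]):
        self.rng = rng
        self.starters = starters
        self.fillers = fillers
        self.sentences: List[str] = []

    def starter(self) -> str:
        return self.rng.choice(self.starters)

    def filler(self) -> str:
        return self.rng.choice(self.fillers)

    def add(self, sentence: str) -> None:
        self.sentences.append(sentence)

    def text(self) -> str:
        return " ".join(self.sentences)


def _plant(
    builder: _AbstractBuilder,
    type_: int,
    surfaces: Tuple[str, str],
    exact_terms: List[str],
    variant: Optional[Tuple[str, str]],
) -> None:
    rng = builder.rng
    a, b = surfaces
    if type_ == 1:
        term = rng.choice(exact_terms)
        builder.add(f"{builder.starter()} {a} {term} {b} near the {builder.filler()}.")
    elif type_ == 2:
        term = rng.choice(exact_terms)
        builder.add(
            f"{builder.starter()} {a} and {b} were {term} in the {builder.filler()}."
        )
    elif type_ == 3:
        assert variant is not None
        builder.add(
            f"{builder.starter()} {a} and {b} {variant[1]} during the {builder.filler()}."
        )
    else:
        builder.add(f"{builder.starter()} {a} appeared within the {builder.filler()}.")
        builder.add(f"{builder.starter()} {b} appeared within the {builder.filler()}.")


def generate_corpus(
    spec: CorpusSpec,
    lexicon: Lexicon,
    out_dir: Union[str, Path],
    n_files: int = 1,
) -> Tuple[List[Path], GroundTruth]:
    """Write a seeded corpus of PubMed XML files plus its ground truth.

    Raises ``ValueError`` when the spec is infeasible for the lexicon
    (fewer than two plantable names, no exact trigger term for k1/k2, or
    no derivable permissive-only surface for k3).  The same spec and seed
    always produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    surfaces = _pairable_surfaces(lexicon)
    if len(surfaces) < 2:
        raise ValueError("lexicon must provide at least two plantable names")
    exact_terms = sorted(
        t for t in lexicon.interaction_terms.values() if " " not in normalize_key(t)
    )
    if (spec.k1 or spec.k2) and not exact_terms:
        raise ValueError("no exact trigger term available for type-1/2 templates")
    variant = permissive_only_variant(lexicon)
    if spec.k3 and variant is None:
        raise ValueError("no permissive-only trigger surface derivable for type-3 templates")
    starters = _safe_words(_STARTERS, lexicon)
    fillers = _safe_words(_FILLERS, lexicon)
    unsafe_glue = [w for w in _GLUE if not _is_safe_word(w, lexicon)]
    if unsafe_glue:
        raise ValueError(f"lexicon collides with template words: {unsafe_glue}")

    types = [1] * spec.k1 + [2] * spec.k2 + [3] * spec.k3 + [4] * spec.k4
    types += [0] * (spec.n_abstracts - len(types))  # 0 = filler-only abstract
    rng.shuffle(types)

    taxon_assignment: Dict[int, List[int]] = {i: [] for i in range(spec.n_abstracts)}
    for tax_id in sorted(spec.taxon_plan):
        k = round(spec.taxon_plan[tax_id] * spec.n_abstracts)
        for i in sorted(rng.sample(range(spec.n_abstracts), k)):
            taxon_assignment[i].append(tax_id)

    truth = GroundTruth()
    records: List[Tuple[str, str, str]] = []  # (pmid, title, abstract)
    for i, type_ in enumerate(types):
        pmid = str(1000 + i)
        builder = _AbstractBuilder(rng, starters, fillers)
        if type_ > 0:
            (sa, na), (sb, nb) = rng.sample(surfaces, 2)
            _plant(builder, type_, (sa, sb), exact_terms, variant)
            a, b = canonical_pair(na, nb)
            truth.interactions.append((pmid, a, b, type_))
        else:
            builder.add(
                f"{builder.starter()} the {builder.filler()} stayed near the {builder.filler()}."
            )
        for tax_id in taxon_assignment[i]:
            name = rng.choice(lexicon.taxon_names[tax_id])
            builder.add(f"{builder.starter()} surveys covered {name} populations.")
        if rng.random() < spec.decoy_rate:
            builder.add(
                f"{builder.starter()} {_decoy(rng, lexicon)} {_decoy(rng, lexicon)} occurred."
            )
        truth.tax_ids_by_pmid[pmid] = tuple(taxon_assignment[i])
        records.append((pmid, f"Synthetic record {pmid}.", builder.text()))

    paths = _write_xml_files(records, out_dir, n_files)
    truth.write_tsv(out_dir / "ground_truth.tsv")
    return paths, truth


def _write_xml_files(
    records: Sequence[Tuple[str, str, str]], out_dir: Path, n_files: int
) -> List[Path]:
    if n_files < 1:
        raise ValueError("n_files must be >= 1")
    n_files = min(n_files, max(1, len(records)))
    chunk = -(-len(records) // n_files) if records else 1
    paths: List[Path] = []
    for fi in range(n_files):
        part = records[fi * chunk : (fi + 1) * chunk]
        root = ET.Element("PubmedArticleSet")
        for pmid, title, abstract in part:
            article = ET.SubElement(root, "PubmedArticle")
            citation = ET.SubElement(article, "MedlineCitation")
            ET.SubElement(citation, "PMID").text = pmid
            art = ET.SubElement(citation, "Article")
            ET.SubElement(art, "ArticleTitle").text = title
            abstract_el = ET.SubElement(art, "Abstract")
            ET.SubElement(abstract_el, "AbstractText").text = abstract
        path = out_dir / f"corpus_{fi:03d}.xml"
        ET.indent(root)
        path.write_bytes(ET.tostring(root, encoding="utf-8", xml_declaration=True) + b"\n")
        paths.append(path)
    return paths


def generate_hard_records(
    n_abstracts: int, lexicon: Lexicon, seed: int = 0
) -> List[AbstractRecord]:
    """Messy in-memory abstracts for stress/oracle testing.

    Sentences mix several planted names, exact terms, permissive stem
    variants, fillers and decoys at random positions, so minimal-type
    reasoning is exercised on arbitrary configurations (no ground truth;
    compare against a brute-force oracle instead).
    """
    rng = random.Random(seed)
    surfaces = _pairable_surfaces(lexicon)
    exact_terms = sorted(
        t for t in lexicon.interaction_terms.values() if " " not in normalize_key(t)
    )
    variant = permissive_only_variant(lexicon)
    starters = _safe_words(_STARTERS, lexicon)
    fillers = _safe_words(_FILLERS, lexicon)

    records = []
    for i in range(n_abstracts):
        pmid = str(5000 + i)
        sentences = []
        for _ in range(rng.randint(1, 6)):
            words: List[str] = []
            for surface, _ in rng.sample(surfaces, rng.randint(0, min(4, len(surfaces)))):
                words.append(surface)
            for _ in range(rng.randint(0, 2)):
                words.append(rng.choice(exact_terms))
            if variant is not None and rng.random() < 0.35:
                words.append(variant[1])
            words.extend(rng.choice(fillers) for _ in range(rng.randint(1, 3)))
            if rng.random() < 0.2:
                words.append(_decoy(rng, lexicon))
            rng.shuffle(words)
            sentences.append(f"{rng.choice(starters)} {' '.join(words)}.")
        records.append(
            AbstractRecord.build(
                pmid=pmid,
                title=f"Synthetic record {pmid}.",
                abstract=" ".join(sentences),
            )
        )
    return records
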
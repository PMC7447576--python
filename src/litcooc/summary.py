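"""Summary reports over miner output tables.

Basic mode writes one ``<name>.summary`` per co-occurrence TSV in a
folder (each with the terms "extra section") plus a join file named
``A.join.dataset.summary`` computed over the concatenation of all inputs
and written *without* the extra section.  Spread mode joins several
folders into a single report stratified by folder.

Counting unit: one co-occurrence event per (pmid, pair) row, as emitted
by the miner.  "Absolute" counts tally events; "non-redundant" counts
tally distinct names/pairs/terms.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from litcooc.miner import read_cooccurrence_tsv
from litcooc.model import Cooccurrence

logger = logging.getLogger(__name__)

JOIN_FILENAME = "A.join.dataset.summary"
COOC_GLOB = "*.cooc.tsv"

#: Items seen at most this many times count as poorly described.
POORLY_DESCRIBED_THRESHOLD = 2

TOP_K = 10


@dataclass
class SummaryReport:
    """Deterministic tallies over a set of co-occurrence rows."""

    #: name -> (occurrence count across rows, distinct-pair participation)
    protein_stats: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    #: canonical pair -> (count, per-type counts)
    cooccurrence_stats: Dict[Tuple[str, str], Tuple[int, Dict[int, int]]] = field(
        default_factory=dict
    )
    term_stats: Dict[str, int] = field(default_factory=dict)
    #: term -> pair -> number of co-occurrence records relating them
    extra_section: Dict[str, Dict[Tuple[str, str], int]] = field(default_factory=dict)
    totals: Dict[str, int] = field(default_factory=dict)
    poorly_described: Dict[str, List[str]] = field(default_factory=dict)
    n_malformed: int = 0


def compute_stats(
    source: Union[str, Path, Sequence[Cooccurrence]],
    threshold: int = POORLY_DESCRIBED_THRESHOLD,
) -> SummaryReport:
    """Tally a co-occurrence TSV (or row sequence) into a report."""
    if isinstance(source, (str, Path)):
        rows = read_cooccurrence_tsv(source)
    else:
        rows = list(source)

    protein_occ: Counter = Counter()
    protein_pairs: Dict[str, set] = defaultdict(set)
    pair_count: Counter = Counter()
    pair_types: Dict[Tuple[str, str], Counter] = defaultdict(Counter)
    term_count: Counter = Counter()
    extra: Dict[str, Counter] = defaultdict(Counter)
    type_totals: Counter = Counter({1: 0, 2: 0, 3: 0, 4: 0})
    abs_terms = 0

    for row in rows:
        pair = row.pair
        for name in pair:
            protein_occ[name] += 1
            protein_pairs[name].add(pair)
        pair_count[pair] += 1
        pair_types[pair][row.type] += 1
        type_totals[row.type] += 1
        for term in row.terms:
            term_count[term] += 1
            extra[term][pair] += 1
            abs_terms += 1

    report = SummaryReport(
        protein_stats={
            name: (protein_occ[name], len(protein_pairs[name])) for name in protein_occ
        },
        cooccurrence_stats={
            pair: (pair_count[pair], dict(pair_types[pair])) for pair in pair_count
        },
        term_stats=dict(term_count),
        extra_section={term: dict(pairs) for term, pairs in extra.items()},
        totals={
            "absolute_proteins": sum(protein_occ.values()),
            "nonredundant_proteins": len(protein_occ),
            "absolute_cooccurrences": len(rows),
            "nonredundant_cooccurrences": len(pair_count),
            "absolute_terms": abs_terms,
            "nonredundant_terms": len(term_count),
            "type_1": type_totals[1],
            "type_2": type_totals[2],
            "type_3": type_totals[3],
            "type_4": type_totals[4],
        },
        poorly_described={
            "proteins": sorted(n for n, c in protein_occ.items() if c <= threshold),
            "cooccurrences": sorted(
                f"{a} -- {b}" for (a, b), c in pair_count.items() if c <= threshold
            ),
            "terms": sorted(t for t, c in term_count.items() if c <= threshold),
        },
    )
    return report


def _ranked(counter_items: Iterable[Tuple[str, int]]) -> List[Tuple[str, int]]:
    return sorted(counter_items, key=lambda kv: (-kv[1], kv[0]))


def render_summary(report: SummaryReport, with_extra: bool, top_k: int = TOP_K) -> str:
    """Human-readable summary text with fixed section headers."""
    lines: List[str] = []
    lines.append("# co-occurrence summary")
    lines.append("# counting unit: one co-occurrence per (pmid, entity pair) at minimal type")
    t = report.totals
    lines.append("== TOTALS ==")
    lines.append(f"proteins\tabsolute={t['absolute_proteins']}\tnonredundant={t['nonredundant_proteins']}")
    lines.append(
        f"cooccurrences\tabsolute={t['absolute_cooccurrences']}\tnonredundant={t['nonredundant_cooccurrences']}"
    )
    lines.append(f"terms\tabsolute={t['absolute_terms']}\tnonredundant={t['nonredundant_terms']}")
    for k in (1, 2, 3, 4):
        lines.append(f"type_{k}\t{t[f'type_{k}']}")
    lines.append(f"== PROTEINS (top {top_k}) ==")
    for name, count in _ranked((n, c) for n, (c, _) in report.protein_stats.items())[:top_k]:
        lines.append(f"{name}\t{count}\tpairs={report.protein_stats[name][1]}")
    lines.append(f"== COOCCURRENCES (top {top_k}) ==")
    pair_items = [(f"{a} -- {b}", c) for (a, b), (c, _) in report.cooccurrence_stats.items()]
    for label, count in _ranked(pair_items)[:top_k]:
        lines.append(f"{label}\t{count}")
    lines.append(f"== TERMS (top {top_k}) ==")
    for term, count in _ranked(report.term_stats.items())[:top_k]:
        lines.append(f"{term}\t{count}")
    lines.append("== POORLY DESCRIBED ==")
    for kind in ("proteins", "cooccurrences", "terms"):
        items = report.poorly_described.get(kind, [])
        lines.append(f"{kind}\t{len(items)}\t{'; '.join(items)}")
    if with_extra:
        lines.append("== EXTRA SECTION ==")
        for term in sorted(report.extra_section):
            for (a, b), count in sorted(report.extra_section[term].items()):
                lines.append(f"{term}\t{a} -- {b}\t{count}")
    return "\n".join(lines) + "\n"


def render_summary_tsv(report: SummaryReport) -> str:
    """Machine-readable sibling: ``section<TAB>key<TAB>value`` rows."""
    lines = ["section\tkey\tvalue"]
    for key in sorted(report.totals):
        lines.append(f"totals\t{key}\t{report.totals[key]}")
    for name in sorted(report.protein_stats):
        count, pairs = report.protein_stats[name]
        lines.append(f"proteins\t{name}\t{count}")
        lines.append(f"protein_pairs\t{name}\t{pairs}")
    for (a, b) in sorted(report.cooccurrence_stats):
        count, _ = report.cooccurrence_stats[(a, b)]
        lines.append(f"cooccurrences\t{a} -- {b}\t{count}")
    for term in sorted(report.term_stats):
        lines.append(f"terms\t{term}\t{report.term_stats[term]}")
    for term in sorted(report.extra_section):
        for (a, b), count in sorted(report.extra_section[term].items()):
            lines.append(f"extra\t{term} :: {a} -- {b}\t{count}")
    return "\n".join(lines) + "\n"


def summarize_basic(
    result_folder: Union[str, Path],
    threshold: int = POORLY_DESCRIBED_THRESHOLD,
    top_k: int = TOP_K,
) -> List[Path]:
    """Write N per-file summaries plus the concatenated join summary.

    For N input TSVs this writes N ``<name>.summary`` files (with the
    extra section), N ``<name>.summary.tsv`` siblings, and one
    ``A.join.dataset.summary`` without the extra section, computed over
    the concatenation of all rows.  Returns the written ``.summary``
    paths (join last).
    """
    folder = Path(result_folder)
    inputs = sorted(folder.glob(COOC_GLOB))
    if not inputs:
        raise FileNotFoundError(f"no co-occurrence TSV ({COOC_GLOB}) found in {folder}")
    written: List[Path] = []
    all_rows: List[Cooccurrence] = []
    for tsv in inputs:
        rows = read_cooccurrence_tsv(tsv)
        all_rows.extend(rows)
        report = compute_stats(rows, threshold=threshold)
        out = tsv.with_suffix("").with_suffix("")  # strip .cooc.tsv
        summary_path = folder / (out.name + ".summary")
        summary_path.write_text(render_summary(report, with_extra=True, top_k=top_k), encoding="utf-8")
        (folder / (out.name + ".summary.tsv")).write_text(
            render_summary_tsv(report), encoding="utf-8"
        )
        written.append(summary_path)
    join_report = compute_stats(all_rows, threshold=threshold)
    join_path = folder / JOIN_FILENAME
    join_path.write_text(render_summary(join_report, with_extra=False, top_k=top_k), encoding="utf-8")
    written.append(join_path)
    return written


def summarize_spread(
    folder_list: Sequence[Union[str, Path]],
    out_path: Union[str, Path],
    threshold: int = POORLY_DESCRIBED_THRESHOLD,
    top_k: int = TOP_K,
) -> Path:
    """Join several result folders into one stratified report.

    Each folder contributes a stratum labelled by its basename; a POOLED
    section tallies the union of all rows.  Folders without co-occurrence
    TSVs are skipped with a warning.
    """
    strata: List[Tuple[str, List[Cooccurrence]]] = []
    for folder in folder_list:
        folder = Path(folder)
        inputs = sorted(folder.glob(COOC_GLOB))
        if not inputs:
            logger.warning("folder %s has no co-occurrence TSVs; skipped", folder)
            continue
        rows: List[Cooccurrence] = []
        for tsv in inputs:
            rows.extend(read_cooccurrence_tsv(tsv))
        strata.append((folder.name, rows))

    lines: List[str] = ["# spread summary report"]
    pooled: List[Cooccurrence] = []
    for label, rows in strata:
        pooled.extend(rows)
        lines.append(f"==== FOLDER {label} ====")
        lines.append(render_summary(compute_stats(rows, threshold=threshold), with_extra=False, top_k=top_k).rstrip("\n"))
    lines.append("==== POOLED ====")
    lines.append(render_summary(compute_stats(pooled, threshold=threshold), with_extra=False, top_k=top_k).rstrip("\n"))
    out = Path(out_path)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out
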
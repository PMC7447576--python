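"""Shard-parallel pipeline execution.

The parallel unit is the input XML *file*: files are assigned to workers
by deterministic round-robin, every worker loads its own read-only
lexicon copy, and per-file outputs depend only on the file and the
lexicon — so, after canonical sorting, the concatenated output is
byte-identical for any worker count.
"""

from __future__ import annotations

import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from litcooc import corpus_io
from litcooc.lexicon import load_lexicon
from litcooc.miner import (
    filter_by_taxon,
    mine_record,
    select_type,
    write_cooccurrence_tsv,
)
from litcooc.tagger import import_external_tags

logger = logging.getLogger(__name__)

COOC_SUFFIX = ".cooc.tsv"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_paths: List[Path]
    output_dir: Path
    lexicon_path: Path
    jobs: int = 1
    tax_id: Optional[int] = None
    max_type: int = 4
    tags_path: Optional[Path] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.input_paths = [Path(p) for p in self.input_paths]
        self.output_dir = Path(self.output_dir)
        self.lexicon_path = Path(self.lexicon_path)
        if self.jobs < 1:
            raise ValueError("jobs must be >= 1")
        if not self.input_paths:
            raise ValueError("input_paths must be non-empty")
        if self.max_type not in (1, 2, 3, 4):
            raise ValueError("max_type must be in {1, 2, 3, 4}")


def shard_inputs(paths: Sequence[Union[str, Path]], jobs: int) -> List[List[Path]]:
    """Deterministic round-robin assignment of paths to ``jobs`` shards.

    Every path lands in exactly one shard; shard sizes differ by at most
    one; the assignment is a pure function of (path order, jobs).
    """
    if jobs < 1:
        raise ValueError("jobs must be >= 1")
    shards: List[List[Path]] = [[] for _ in range(jobs)]
    for i, p in enumerate(paths):
        shards[i % jobs].append(Path(p))
    return shards


def _process_file(
    xml_path: Path,
    lexicon,
    output_dir: Path,
    tax_id: Optional[int],
    max_type: int,
    tags_path: Optional[Path],
) -> Dict[str, object]:
    entry: Dict[str, object] = {"input": str(xml_path), "status": "ok"}
    t0 = time.monotonic()
    try:
        records = corpus_io.parse_medline_xml(xml_path)
    except Exception as exc:  # malformed XML etc.: skip the file, keep going
        logger.warning("skipping unreadable input %s: %s", xml_path, exc)
        return {"input": str(xml_path), "status": "error", "error": str(exc)}

    external = None
    if tags_path is not None:
        external = import_external_tags(corpus_io.read_tag_interchange(tags_path), records)

    cooccurrences = []
    for record in records:
        mentions = external.get(record.pmid) if external is not None else None
        cooccurrences.extend(mine_record(record, lexicon, entity_mentions=mentions))
    if tax_id is not None:
        cooccurrences = filter_by_taxon(cooccurrences, records, tax_id, lexicon)
    cooccurrences = select_type(cooccurrences, max_type)

    out_path = output_dir / (xml_path.stem + COOC_SUFFIX)
    write_cooccurrence_tsv(cooccurrences, out_path)
    entry.update(
        {
            "output": str(out_path),
            "n_records": len(records),
            "n_without_abstract": sum(1 for r in records if not r.abstract),
            "n_cooccurrences": len(cooccurrences),
            "seconds": round(time.monotonic() - t0, 4),
        }
    )
    return entry


def _process_shard(
    paths: List[Path],
    lexicon_path: Path,
    output_dir: Path,
    tax_id: Optional[int],
    max_type: int,
    tags_path: Optional[Path],
) -> List[Dict[str, object]]:
    # each worker loads its own read-only in-memory lexicon copy
    lexicon = load_lexicon(lexicon_path)
    return [
        _process_file(p, lexicon, output_dir, tax_id, max_type, tags_path)
        for p in paths
    ]


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run parse -> tag -> mine for every input file; returns the manifest.

    A missing lexicon is fatal before any worker starts; unreadable input
    files are skipped and logged.  The manifest is also written to
    ``<output_dir>/run_manifest.json``.
    """
    if not config.lexicon_path.is_file():
        raise FileNotFoundError(f"lexicon file not found: {config.lexicon_path}")
    config.output_dir.mkdir(parents=True, exist_ok=True)

    shards = [s for s in shard_inputs(config.input_paths, config.jobs) if s]
    results: List[Dict[str, object]] = []
    args = (
        config.lexicon_path,
        config.output_dir,
        config.tax_id,
        config.max_type,
        config.tags_path,
    )
    if len(shards) <= 1 or config.jobs == 1:
        for shard in shards:
            results.extend(_process_shard(shard, *args))
    else:
        with ProcessPoolExecutor(max_workers=len(shards)) as pool:
            futures = [pool.submit(_process_shard, shard, *args) for shard in shards]
            for fut in futures:
                results.extend(fut.result())

    results.sort(key=lambda e: e["input"])
    manifest: Dict[str, object] = {
        "jobs": config.jobs,
        "lexicon": str(config.lexicon_path),
        "tax_id": config.tax_id,
        "max_type": config.max_type,
        "mined_text": "title + ' ' + abstract",
        "event_unit": "one co-occurrence per (pmid, pair) at minimal type",
        "n_inputs": len(config.input_paths),
        "n_errors": sum(1 for e in results if e["status"] != "ok"),
        "files": results,
    }
    manifest_path = config.output_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
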
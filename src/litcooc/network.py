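"""Aggregate typed co-occurrences into a weighted network.

Edge weight counts supporting abstracts (one per (pmid, pair) record),
consistent with the miner's event unit.  Exports: SIF, TSV, GraphML.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Tuple, Union

import networkx as nx

from litcooc.model import Cooccurrence

EXPORT_FORMATS = ("sif", "tsv", "graphml")


@dataclass(frozen=True)
class NetworkEdge:
    pair: Tuple[str, str]
    weight: int
    per_type_weight: Dict[int, int]
    best_type: int
    supporting_pmids: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.weight != sum(self.per_type_weight.values()):
            raise ValueError("weight must equal the sum of per-type weights")
        if self.weight != len(self.supporting_pmids):
            raise ValueError("one supporting abstract per unit of weight")


def build_edges(cooccurrences: Iterable[Cooccurrence]) -> List[NetworkEdge]:
    """One edge per canonical pair, ordered by (weight desc, pair asc)."""
    per_pair_types: Dict[Tuple[str, str], Dict[int, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    per_pair_pmids: Dict[Tuple[str, str], set] = defaultdict(set)
    for c in cooccurrences:
        per_pair_types[c.pair][c.type] += 1
        per_pair_pmids[c.pair].add(c.pmid)
    edges = []
    for pair, type_counts in per_pair_types.items():
        weight = sum(type_counts.values())
        edges.append(
            NetworkEdge(
                pair=pair,
                weight=weight,
                per_type_weight=dict(type_counts),
                best_type=min(type_counts),
                supporting_pmids=frozenset(per_pair_pmids[pair]),
            )
        )
    edges.sort(key=lambda e: (-e.weight, e.pair))
    return edges


def to_graph(edges: Iterable[NetworkEdge]) -> "nx.Graph":
    """Undirected graph with weight/type attributes on every edge."""
    graph = nx.Graph()
    for e in edges:
        a, b = e.pair
        graph.add_edge(
            a,
            b,
            weight=e.weight,
            best_type=e.best_type,
            **{f"type{k}": e.per_type_weight.get(k, 0) for k in (1, 2, 3, 4)},
            pmids=";".join(sorted(e.supporting_pmids)),
        )
    return graph


def export_network(
    edges: Iterable[NetworkEdge], destination: Union[str, Path], format: str
) -> Path:
    """Write the edge list in the requested format.

    SIF rows read ``<a> cooccur_t<best_type> <b>``; the TSV mirrors the
    edge fields; GraphML carries weight and per-type counts as edge
    attributes and round-trips through standard readers.
    """
    if format not in EXPORT_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(EXPORT_FORMATS)}"
        )
    edges = list(edges)
    path = Path(destination)
    if format == "sif":
        lines = [f"{e.pair[0]}\tcooccur_t{e.best_type}\t{e.pair[1]}" for e in edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "tsv":
        lines = [
            "entity_a\tentity_b\tweight\tbest_type\ttype1\ttype2\ttype3\ttype4\tpmids"
        ]
        for e in edges:
            counts = [str(e.per_type_weight.get(k, 0)) for k in (1, 2, 3, 4)]
            lines.append(
                "\t".join(
                    [
                        e.pair[0],
                        e.pair[1],
                        str(e.weight),
                        str(e.best_type),
                        *counts,
                        ";".join(sorted(e.supporting_pmids)),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        nx.write_graphml(to_graph(edges), path)
    return path


def read_network_tsv(source: Union[str, Path]) -> List[NetworkEdge]:
    """Read back a TSV export (round-trip counterpart of export_network)."""
    lines = Path(source).read_text(encoding="utf-8").splitlines()
    edges: List[NetworkEdge] = []
    for line in lines[1:]:
        a, b, weight, best_type, t1, t2, t3, t4, pmids = line.split("\t")
        per_type = {
            k: int(v) for k, v in zip((1, 2, 3, 4), (t1, t2, t3, t4)) if int(v) > 0
        }
        edges.append(
            NetworkEdge(
                pair=(a, b),
                weight=int(weight),
                per_type_weight=per_type,
                best_type=int(best_type),
                supporting_pmids=frozenset(p for p in pmids.split(";") if p),
            )
        )
    return edges
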
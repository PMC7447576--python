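# litcooc

Mine typed protein/gene co-occurrences from PubMed/MEDLINE abstracts.

The pipeline parses PubMed XML into (PMID, title, abstract) records,
tags bioentities, interaction trigger terms and concept terms against a
fully in-memory lexicon, and classifies every co-mentioned protein/gene
pair in an abstract into a reliability type:

1. both names in one sentence, exact trigger term strictly between them;
2. both names in one sentence, exact trigger term anywhere;
3. both names in one sentence, trigger found only permissively
   (stem-prefix match, minimum stem length 4);
4. both names in the same abstract only.

One co-occurrence is reported per (PMID, pair) at its minimal qualifying
type. Results can be filtered by NCBI taxonomy id, summarized
(basic/spread modes, including the per-term "extra section" and the
`A.join.dataset.summary` join file), and exported as weighted
co-occurrence networks (SIF/TSV/GraphML).

Execution over many XML files is shard-parallel (`-j N`, round-robin,
one file per worker at a time, each worker holding its own read-only
lexicon copy); the sorted concatenated output is byte-identical for any
worker count.

## CLI

Every stage is a subcommand (so external schedulers such as GNU parallel
can drive per-file stages directly):

```sh
# generate a seeded synthetic corpus with planted, ground-truthed pairs
litcooc simulate --n 20 --k1 5 --k2 5 --k3 5 --k4 5 \
    --taxon 3847:0.5 --seed 1 --files 4 --out corpus/

# full pipeline: parse -> tag -> mine, 4 workers, one TSV per input file
litcooc run corpus/*.xml -j 4 --out mined/ [--tax-id 3847] [--max-type 1]

# single-file stages
litcooc parse corpus/corpus_000.xml --out records.tsv
litcooc tag corpus/corpus_000.xml --out tags.tsv        # interchange TSV
litcooc mine corpus/corpus_000.xml --tags tags.tsv --out out.cooc.tsv

# reports and networks
litcooc summarize mined/                  # N per-file summaries + join
litcooc summarize mined_a/ mined_b/ --mode spread --out spread.summary
litcooc network mined/*.cooc.tsv --format graphml --out net.graphml
```

`litcooc run` also accepts a `key=value` config file via `--config`
(keys: `inputs`, `out`, `lexicon`, `jobs`, `tax_id`, `max_type`, `tags`,
`seed`); explicit flags override it.

## Lexicon format

One TSV travels with each run; the first column is the row type:

```
BIOENTITY  <surface>  <normalized>  <protein|gene|taxon|tissue|cell_type>
TERM       <trigger term>
CONCEPT    <concept term>
TAXON      <name>     <ncbi tax id>
```

`litcooc.lexicon.export_sqlite` writes the store to an SQLite file for
interoperability.

## Library

```python
from litcooc import (
    load_lexicon, parse_medline_xml, tag_entities, tag_terms,
    mine_abstract, filter_by_taxon, compute_stats, build_edges,
)
```

See module docstrings for the full API; `litcooc.synthetic` generates
seeded PubMed-XML corpora with planted interactions and a ground-truth
table for testing.

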
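# File formats

All files are UTF-8 text; tables are tab-separated.

## Expression matrix (`*.tsv`)

First row: condition/time-point labels; first column: gene IDs
(case-sensitive, unique). Missing entries are empty cells or the
missing token (default `NA`).

```
gene	t0	t1	t2	t3
G001	0.12	0.87	NA	-0.43
G002	-1.02	0.33	0.85	0.21
```

Floats are written with `%.17g`, so a write/read round trip is exact.

## Partition (`*.tsv`)

Two columns with a header line; one data line per gene; cluster
indices are 0-based.

```
gene	cluster
G001	0
G002	2
```

## Group manifest (`manifest.yaml`)

```yaml
criterion: synchronization method
groups:
  - name: elutriation
    experiments: [elu1.tsv, elu2.tsv, elu3.tsv]
  - name: cdc25
    experiments: [cdc25-1.tsv, cdc25-2.1.tsv, cdc25-2.2.tsv, cdc25-sep1.tsv]
  - name: combined
    experiments: [elu-cdc10.tsv, elu-cdc25.tsv]
```

Group names must be unique, every group non-empty; experiment paths are
resolved relative to the manifest's directory.

## Formal context (`context.tsv`)

Genes x clusters 0/1 table; column headers are `group:local_index`.

## Concept lattice (`lattice.jsonl`, `lattice.dot`)

`lattice.jsonl` holds one concept per line:

```json
{"extent": ["G001", "G007"], "intent": [1, 5, 12], "own_extent": ["G007"], "support": 0.0027}
```

`lattice.dot` is the Hasse diagram in Graphviz DOT format (edges point
from subconcepts to superconcepts).

## Run report (`report.json`)

Counts and scores of one pipeline run: seed, engine, `r`, `K`, genes
per group, chosen k per group, tie counts, concept/zero-support/block
counts, per-experiment Silhouette and Connectivity, stage timings.
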
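# tjkit

Stream-composable genomic annotation from indexed flat-file catalogs.

Interpreting sequencing results means joining each variant against many
annotation sources — dbSNP identifiers, population allele frequencies, gene
models, clinical and pharmacogenomic tables. At production scale that is
hundreds of millions of small queries, and loading every source into a
database is both slow to maintain and hard to compose with ordinary
command-line workflows. `tjkit` takes the opposite approach: every
annotation source becomes a sorted, compressed, indexed *flat file*
(a **catalog**), and every annotation step is a small UNIX command that
reads a text stream on stdin and writes one on stdout, so complete
pipelines are just shell pipes.

## The format and the model

The universal stream representation is a hybrid of TSV and JSON: a line of
tab-separated cells, any of which may be an embedded JSON object.

```
1024	145.6	{"_type":"gene","_strand":"+","_minBP":10954,"_maxBP":11507,"note":"similarity to: 1 Protein","GeneID":"100506145"}	12.334
```

A **catalog** stores one source as four such columns — `landmark`
(chromosome), `minBP`, `maxBP` (1-based, both inclusive), and a JSON
payload carrying all source data — BGZF-compressed and Tabix-indexed for
region queries. Entries with `minBP = maxBP = 0` are position-independent
(drugs, diseases) and are reachable only by identifier. Inside every
payload a reserved set of **golden keys** (`_landmark`, `_minBP`, `_maxBP`,
`_refAllele`, `_altAlleles`, `_id`, `_strand`, `_type`) gives cross-catalog
semantic consistency; matching commands consume them implicitly.

Three retrieval modes annotate a stream, each appending one matched payload
per output line (`{}` on a miss, so no input line is ever dropped):

* `lookup` — equality on a drilled identifier, e.g. rsID, via a sidecar
  binary-searchable index of `value → file offsets`;
* `overlap` — interval intersection `max(minBPs) ≤ min(maxBPs)` on the same
  landmark, via Tabix;
* `same_variant` — same landmark **and** equal start position **and** equal
  reference allele **and** a non-empty intersection of alternate-allele
  sets (alleles compared case-insensitively as literal strings).

`drill` flattens nested JSON values out of the stream by dotted key paths
(`INFO.EUR_AF`), and converters bring VCF and BED into the format (BED's
0-based half-open intervals become 1-based inclusive at ingest).

## Worked example

Generate a deterministic toy annotation universe — a dbSNP-like catalog, a
1000-Genomes-like frequency catalog sharing 60 % of its variants, a gene
catalog, and an rsID list — then annotate the rsIDs with European allele
frequencies:

```sh
tj_make_fixture --seed 7 --variants 50 --overlap 0.6 --outdir fx

cat fx/rsIDs.txt \
  | tj_lookup -p ID -d fx/dbSNP.tsv.bgz \
  | tj_same_variant -d fx/KGenomes.tsv.bgz \
  | tj_drill -c -1 -p INFO.EUR_AF \
  | cut -f 1,3
```

```
#c1	INFO.EUR_AF
rs1000	.
rs1001	0.8728
rs1002	.
rs1003	0.6086
rs1004	0.7760
...
```

`tj_lookup` matches each rsID against the dbSNP-like catalog's `ID` field
and appends the variant's JSON record; `tj_same_variant` uses the golden
keys of that record to find the *same variant* (position, ref, shared alt)
in the frequency catalog; `tj_drill` pulls `INFO.EUR_AF` out into a flat
column, and standard `cut` keeps the (rsID, frequency) pairs. A `.` marks
an rsID with no same-variant entry — here 30 of the 50 variants have one,
exactly the fixture's 60 % overlap. Each stage is an ordinary process, so
third-party tools (`grep`, `awk`) can be interleaved anywhere and the whole
pipeline runs in constant memory per stage.

The same composition is available in-process:

```python
from tjkit import Catalog, annotate_pipeline, lookup, same_variant
from tjkit.formats import drill_columns

db, kg = Catalog("fx/dbSNP.tsv.bgz"), Catalog("fx/KGenomes.tsv.bgz")
pipe = annotate_pipeline([
    lambda s: lookup(s, db, "ID"),
    lambda s: same_variant(s, kg),
    lambda s: drill_columns(s, -1, ["INFO.EUR_AF"]),
])
for line in pipe(open("fx/rsIDs.txt")):
    print(line)
```

Catalogs are built from any tab-delimited source with a small column
configuration file (`tj_create_catalog --config cols.cfg`), and identifier
indices with `tj_build_index -d CATALOG -p PATH`; see `docs/methods.md` for
the configuration dialect and all matching semantics.

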
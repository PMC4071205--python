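# Methods

## Data model

The stream format is tab-separated text in which any cell may be a JSON
*object* string. A cell is classified as JSON iff it begins with `{` and
parses as an object — deterministic, schema-free, and cheap to test. Tabs
and newlines never occur inside a cell, so `parse` (split on tab) and
`serialize` (join on tab) are exact mutual inverses. One degenerate case is
excluded by construction: a record consisting of a single empty cell would
serialize to the empty string, which the parser rejects as an empty record,
so that record is itself illegal. Header lines begin with `#`, precede all
data, and every operation reproduces them byte-identically and in order —
this is what lets VCF/GFF-style metadata survive an arbitrary pipeline.

JSON numbers are kept in their source text from parse to output (a
`str` subclass tags them), so a frequency printed as `0.12` drills out as
`0.12`, never a shortest-round-trip artifact like `0.12000000000000001`.
Objects and arrays render as compact JSON; booleans as `true`/`false`;
an explicit `null`, like a missing key, renders as the missing-value token
`.` (chosen for consonance with VCF's missing marker).

Drill paths are dot-joined key sequences (`INFO.EUR_AF`). Dot is the only
separator, so keys containing a literal dot are unreachable by textual
path, and array elements are not individually addressable — arrays come
back as compact JSON. Both are accepted limitations of a format whose
practical paths are short and flat.

## Golden keys

Eight reserved payload keys carry cross-catalog semantics: `_landmark`,
`_minBP`, `_maxBP`, `_refAllele`, `_altAlleles`, `_id`, `_strand`, `_type`.
This eight-key set is this package's defined contract; other
underscore-prefixed keys pass through untouched and are never interpreted.
All fields are optional per entry; alleles are uppercased on extraction;
`_minBP = _maxBP = 0` is the sentinel for position-independent entries.
Extraction ignores non-reserved keys entirely and is idempotent.

## Catalogs

A catalog line is `landmark \t minBP \t maxBP \t payload`. Coordinates are
1-based with both ends inclusive (the Tabix dialect); BED's 0-based
half-open intervals are converted at ingest (`_minBP = chromStart + 1`,
`_maxBP = chromEnd`), and a VCF record spans `[POS, POS + len(REF) - 1]`.
Landmark names match exactly — no `chr1`/`1` aliasing (an alias map would
be a compatible extension).

Files are sorted by (landmark lexicographic, minBP, maxBP numeric; ties
keep input order), BGZF-compressed and Tabix-indexed via pysam/htslib
(sequence column 1, begin 2, end 3, comment `#`). htslib itself skips
`(0,0)` lines at index build — which is exactly the intended semantics:
position-independent entries are never returned by coordinate queries; the
per-line warning it logs is suppressed. Duplicate coordinates are legal
and query results preserve file order.

Identifier indices are sidecar files `<catalog>.<path>.idx.bgz`: a
BGZF-compressed, lexicographically sorted two-column table
`key \t offset,offset,...` (offsets are BGZF virtual offsets into the data
file), preceded by a `#key=<path>` header. The format is deliberately
human-inspectable (`bgzip -d`) and needs no database. At query time the
index is loaded into memory and searched with stdlib bisection; this fits
desk- to dbSNP-scale key sets, and a memory-mapped variant would be the
escalation path for larger ones. Indices are built on demand when a lookup
first needs one.

### Building from tab-delimited sources

`create_catalog` converts one source row to one catalog line using a flat
column-configuration dialect, one line per column:

```
position <TAB> name <TAB> kind [<TAB> type [<TAB> delimiter]]
```

with kinds `landmark | start | end | id | ref_allele | alt_alleles |
strand | type | data | skip` and value types `integer | float | text |
list` (list columns split on the declared delimiter, default `,`).
`start`/`end` columns default to integer, `alt_alleles` to list. A
directive `@landmark=<value>` supplies a constant landmark for sources
without a sequence column; exactly one landmark source is required, and
start/end at most once each. Every non-skipped column becomes a JSON key
under its own name; kind-tagged columns additionally emit the
corresponding golden key (alleles uppercased). Rows with empty
coordinates get `0 0` and no golden coordinate keys; a source configured
with only a `start` column yields point features (`_maxBP = _minBP`).
Conversion is strictly per-row, so it streams.

## Retrieval semantics

All three annotators are pure stream transforms with identical framing:
headers pass through first, then each input line yields one output line
per match with the matched payload appended as a new last column
(*fan-out*), or a single line with the sentinel `{}` when nothing matches.
Output line count is therefore Σ max(1, matches) — no line is dropped, and
column arity stays rectangular within each match class.

* **lookup** takes its key value from a selectable input column (default
  the last): drilled from the cell when the cell is JSON, otherwise the
  cell text itself.
* **overlap** reads `_landmark`/`_minBP`/`_maxBP` from the last JSON
  column and returns entries with `max(starts) ≤ min(ends)` on the same
  landmark. Adjacent-but-not-overlapping intervals under the inclusive
  convention do not match.
* **same_variant** requires the full variant key (`_landmark`, `_minBP`,
  `_refAllele`, `_altAlleles`) in the last JSON column and matches on
  exact start-position equality (not interval overlap), exact reference
  equality and non-empty alternate intersection, alleles uppercased and
  compared as literal strings. Indels are therefore matched by their
  literal representation — no left-normalization or multi-allelic
  decomposition — which makes the contract exact, testable, and
  representation-sensitive in the same way as the catalogs it queries.
  Its match set is by construction a subset of `overlap`'s at the same
  position. Candidates come from the coordinate index at the position;
  allele filtering follows.

One deliberate relaxation: a line whose key JSON column is exactly the
sentinel `{}` (an upstream miss) propagates a miss instead of raising the
incomplete-input error. Without this, any pipeline stage downstream of a
miss would abort the whole stream; with it, miss rows flow to the end and
drill renders them as `.`. A *partially* specified variant key is still a
hard error naming the line, since it indicates malformed data rather than
an upstream miss.

## Command-line surface

Every operation is exposed both as `tjkit <command>` and as a `tj_<command>`
alias, with consistent flags (`-d` catalog, `-p` drill path, `-c` signed
column selector, negative counting from the right). stdout carries only
payload; diagnostics and optional per-stage match summaries
(`--log-level INFO`) go to stderr; exit codes are 0 (success), 1 (data or
environment error), 2 (usage). SIGPIPE is restored to default disposition
so early termination of a downstream consumer (e.g. `head`) ends the
command cleanly. Multi-core use falls out of process-level composition —
each stage is its own process — and needs no engineering in the toolkit.

## Fixture generator

The generator builds a closed annotation universe with a known answer key:
`n_variants` variants at globally unique positions across the configured
landmarks (default 2 chromosomes, 50 variants), each with an rsID,
reference and 1–2 alternate alleles (20 % multi-allelic, 10 % literal
indels by default). An exact `round(overlap_fraction · n)` of them (60 %
by default) are mirrored in the frequency catalog with identical
position/ref/alt and a frequency drawn uniform(0,1), rounded to 4 decimals
and stored as VCF INFO text. Half of the unmatched variants receive a
near-miss decoy at the same position — wrong reference or disjoint
alternates — so the matching rule's negative paths are exercised with
known outcomes. The dbSNP-like catalog is built through the column-config
path, the frequency catalog through the VCF converter, and the gene
catalog through the BED converter, so fixture generation itself exercises
catalog construction end to end. Same seed ⇒ byte-identical decompressed
files.

What the fixture does *not* emulate: real dbSNP/1000G schema richness,
clustered or overlapping variant positions, realistic allele-frequency
spectra, structural variants, or chromosome-scale coordinate ranges.
Passing tests demonstrate the correctness of storage, indexing and
matching semantics on faithful miniatures — not robustness to the full
messiness of production annotation sources.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale inputs chosen to
exercise every code path while keeping runs fast: 50-variant fixtures for
pipeline reproduction, 120–300-entry catalogs with ~500 random probes per
mode for index-versus-scan equivalence, 100–500-case round-trip sweeps,
and a 10^5-line synthetic stream (against a 10^2-line baseline) for the
constant-memory check, measured with `tracemalloc` after a warm-up pass so
one-time caches (identifier index, Tabix handles) are excluded from the
comparison. All randomness is seeded; reruns are byte-identical.

## Known limitations

* Keys containing dots and individual array elements are unreachable by
  drill paths.
* No JSON-schema validation of payloads; a malformed payload surfaces at
  first parse with its line number.
* No landmark aliasing, no indel normalization, no fuzzy variant matching,
  no relational-source adapters, and no dedicated catalog-merge command
  (concatenate + sort + recompress achieves it).
* The in-memory identifier index bounds practical key-set size by
  available RAM.
* `tjson_to_tsv` without declared paths must buffer the stream to discover
  keys; with `-p` it is single-pass and pipe-safe.
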
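"""Streaming annotators: identifier lookup, coordinate overlap, same-variant.

Each operation is a pure stream transform over TJSON lines: it reads one
line at a time and appends one matched catalog payload per output line
(*fan-out*: k matches produce k output lines), or the no-match sentinel
``{}`` so that no input line is ever dropped.  ``#`` header lines pass
through unchanged ahead of data.  Memory use is independent of stream
length, which is what lets these transforms run as UNIX pipeline stages
over arbitrarily large inputs.

Matching semantics:

* ``lookup`` — equality on a drilled identifier (e.g. ``ID`` = rsID),
  served by the catalog's sidecar identifier index.  Position-independent
  (0,0) entries are reachable here and only here.
* ``overlap`` — 1-based inclusive interval intersection
  (max(starts) <= min(ends)) on the same landmark, served by Tabix.
* ``same_variant`` — exact position (equality of start coordinates), exact
  reference allele, and a non-empty intersection of alternate allele sets,
  alleles compared case-insensitively as literal strings (no indel
  left-normalization).  Strictly a subset of ``overlap`` at the position.

A line whose key column is exactly the sentinel ``{}`` (an upstream miss)
propagates the miss instead of raising, so stages can be chained even when
earlier stages found nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional

from .catalog import Catalog, CatalogEntry
from .tjson import (
    JsonPath,
    TjsonError,
    TjsonRecord,
    drill,
    extract_golden,
    is_header,
    is_json_cell,
)

#: Appended when an input line matches nothing in the catalog.
NO_MATCH = "{}"

StreamOp = Callable[[Iterable[str]], Iterator[str]]


@dataclass(frozen=True)
class VariantKey:
    """The golden-key tuple same_variant joins on."""

    landmark: str
    position: int  # 1-based start coordinate
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise TjsonError("variant key needs at least one alternate allele")


def _last_json_column(record: TjsonRecord) -> Optional[str]:
    for cell in reversed(record.columns):
        if is_json_cell(cell):
            return cell
    return None


def _emit(line: str, entries: list[CatalogEntry]) -> Iterator[str]:
    if not entries:
        yield f"{line}\t{NO_MATCH}"
    else:
        for entry in entries:
            yield f"{line}\t{entry.json_text}"


def lookup(
    stream: Iterable[str],
    catalog: Catalog,
    key: "JsonPath | str",
    input_column: int = -1,
) -> Iterator[str]:
    """Annotate each line with catalog entries whose drilled *key* matches.

    The lookup value comes from *input_column* (signed 1-based selector,
    default last): if that cell is JSON the key is drilled out of it,
    otherwise the cell text itself is the value.  Matches append in catalog
    order; misses append ``{}``.
    """
    if isinstance(key, str):
        key = JsonPath.parse(key)
    for line_no, line in enumerate(stream, start=1):
        if is_header(line):
            yield line
            continue
        try:
            record = TjsonRecord.parse(line)
            cell = record.cell(input_column)
        except TjsonError as exc:
            raise TjsonError(f"line {line_no}: {exc}") from exc
        value = drill(cell, key) if is_json_cell(cell) else cell
        entries = [] if value == "." else list(catalog.lookup_id(key, value))
        yield from _emit(line, entries)


def overlap(stream: Iterable[str], catalog: Catalog) -> Iterator[str]:
    """Annotate each line with catalog entries overlapping its interval.

    The interval is read from the golden ``_landmark``/``_minBP``/``_maxBP``
    keys of the line's last JSON column.  Intersection is 1-based inclusive:
    max(starts) <= min(ends) on the same landmark.
    """
    for line_no, line in enumerate(stream, start=1):
        if is_header(line):
            yield line
            continue
        record = TjsonRecord.parse(line)
        cell = _last_json_column(record)
        if cell == NO_MATCH:
            yield from _emit(line, [])
            continue
        if cell is None:
            raise TjsonError(f"no coordinates on line {line_no}")
        golden = extract_golden(cell)
        if not golden.has_interval():
            raise TjsonError(f"no coordinates on line {line_no}")
        entries = list(catalog.query(golden.landmark, golden.min_bp, golden.max_bp))
        yield from _emit(line, entries)


def _variant_key_of(cell: str, line_no: int) -> VariantKey:
    golden = extract_golden(cell)
    missing = [
        name
        for name, val in (
            ("_landmark", golden.landmark),
            ("_minBP", golden.min_bp),
            ("_refAllele", golden.ref_allele),
            ("_altAlleles", golden.alt_alleles),
        )
        if val in (None, [])
    ]
    if missing:
        raise TjsonError(
            f"incomplete variant on line {line_no}: missing {','.join(missing)}"
        )
    return VariantKey(
        landmark=golden.landmark,
        position=golden.min_bp,
        ref_allele=golden.ref_allele,
        alt_alleles=tuple(golden.alt_alleles),
    )


def same_variant(stream: Iterable[str], catalog: Catalog) -> Iterator[str]:
    """Annotate each line with catalog entries describing the same variant.

    A catalog entry matches when its landmark and start position equal the
    input's, its reference allele equals the input's, and the alternate
    allele sets intersect (alleles uppercased, compared as literal
    strings).  Candidates are retrieved through the coordinate index at the
    input position, then allele-filtered.
    """
    for line_no, line in enumerate(stream, start=1):
        if is_header(line):
            yield line
            continue
        record = TjsonRecord.parse(line)
        cell = _last_json_column(record)
        if cell == NO_MATCH:
            yield from _emit(line, [])
            continue
        if cell is None:
            raise TjsonError(f"incomplete variant on line {line_no}: no JSON column")
        key = _variant_key_of(cell, line_no)
        alts = set(key.alt_alleles)
        entries = []
        for entry in catalog.query(key.landmark, key.position, key.position):
            g = extract_golden(entry.json_text)
            pos = g.min_bp if g.min_bp is not None else entry.min_bp
            if pos != key.position:
                continue
            if g.ref_allele is None or g.ref_allele != key.ref_allele:
                continue
            if not g.alt_alleles or alts.isdisjoint(g.alt_alleles):
                continue
            entries.append(entry)
        yield from _emit(line, entries)


class Pipeline:
    """In-process composition of stream operations.

    Equivalent to connecting the stages with OS pipes: each stage consumes
    the previous stage's line iterator lazily, so the composition keeps the
    one-line-in/k-lines-out locality and constant memory of the shell form.
    """

    def __init__(self, stages: "list[StreamOp] | None" = None) -> None:
        self.stages: list[StreamOp] = list(stages or [])

    def append(self, stage: StreamOp) -> "Pipeline":
        self.stages.append(stage)
        return self

    def __call__(self, stream: Iterable[str]) -> Iterator[str]:
        out: Iterable[str] = stream
        for stage in self.stages:
            out = stage(out)
        return iter(out)


def annotate_pipeline(stages: Iterable[StreamOp]) -> Pipeline:
    """Compose *stages* into a single stream transform."""
    return Pipeline(list(stages))
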
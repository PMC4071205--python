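"""Format converters: VCF/BED -> TJSON, drill-based flattening, TJSON -> TSV.

Converters append a JSON column carrying the parsed record plus the golden
keys; the original columns are preserved byte-identically, and ``#`` header
lines pass through unaltered and in order.  All catalog-facing coordinates
are 1-based inclusive: BED's 0-based half-open intervals are shifted at
ingest (``_minBP = chromStart + 1``, ``_maxBP = chromEnd``), a VCF record
spans ``[POS, POS + len(REF) - 1]``.

VCF INFO values keep their printed textual form unless the header declares
them Integer or Float, in which case they are parsed (numbers still render
back exactly as printed).  Multi-sample genotype columns are carried as
opaque cells, not parsed into JSON.
"""

from __future__ import annotations

import re
from typing import Any, Iterable, Iterator, Optional, Sequence

from .tjson import (
    JsonPath,
    MISSING,
    RawNumber,
    TjsonError,
    TjsonRecord,
    drill,
    dumps_compact,
    is_header,
    is_json_cell,
    loads_object,
    render_value,
    resolve_column,
)

_INFO_DECL = re.compile(r"##INFO=<ID=([^,>]+),[^>]*Type=([^,>]+)")


def _parse_info(text: str, types: dict[str, str]) -> dict[str, Any]:
    info: dict[str, Any] = {}
    if text in (".", ""):
        return info
    for item in text.split(";"):
        if not item:
            continue
        if "=" not in item:
            info[item] = True  # Flag
            continue
        key, value = item.split("=", 1)
        declared = types.get(key)
        if "," not in value:
            if declared == "Integer":
                try:
                    info[key] = int(value)
                    continue
                except ValueError:
                    pass
            elif declared == "Float":
                try:
                    float(value)
                    info[key] = RawNumber(value)
                    continue
                except ValueError:
                    pass
        info[key] = value
    return info


def vcf_to_tjson(stream: Iterable[str]) -> Iterator[str]:
    """Convert a VCF 4.x text stream to TJSON.

    Each data line is re-emitted with an appended JSON column holding
    CHROM/POS/ID/REF/ALT/QUAL/FILTER, the parsed INFO object, and the
    golden variant keys.  ``##``/``#CHROM`` headers pass through first.
    """
    info_types: dict[str, str] = {}
    for line_no, line in enumerate(stream, start=1):
        if is_header(line):
            m = _INFO_DECL.match(line)
            if m:
                info_types[m.group(1)] = m.group(2)
            yield line
            continue
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) < 8:
            raise TjsonError(f"line {line_no}: VCF record has {len(cells)} fields, expected >= 8")
        chrom, pos_text, vid, ref, alt, qual, filt, info_text = cells[:8]
        try:
            pos = int(pos_text)
        except ValueError as exc:
            raise TjsonError(f"line {line_no}: non-integer POS {pos_text!r}") from exc
        obj: dict[str, Any] = {
            "CHROM": chrom,
            "POS": pos,
            "ID": vid,
            "REF": ref,
            "ALT": alt,
            "QUAL": qual,
            "FILTER": filt,
            "INFO": _parse_info(info_text, info_types),
        }
        obj["_landmark"] = chrom
        obj["_minBP"] = pos
        obj["_maxBP"] = pos + len(ref) - 1
        if vid != ".":
            obj["_id"] = vid
        obj["_refAllele"] = ref.upper()
        if alt != ".":
            obj["_altAlleles"] = [a.upper() for a in alt.split(",")]
        yield f"{line}\t{dumps_compact(obj)}"


def bed_to_tjson(stream: Iterable[str]) -> Iterator[str]:
    """Convert a BED3+ text stream to TJSON.

    BED's 0-based half-open interval becomes the catalog's 1-based
    inclusive one; name and strand populate ``_id`` and ``_strand`` when
    present.
    """
    for line_no, line in enumerate(stream, start=1):
        if is_header(line) or line.startswith(("track", "browser")):
            yield line
            continue
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            raise TjsonError(f"line {line_no}: BED record has {len(cells)} fields, expected >= 3")
        chrom = cells[0]
        try:
            start, end = int(cells[1]), int(cells[2])
        except ValueError as exc:
            raise TjsonError(f"line {line_no}: non-integer BED coordinate") from exc
        if start >= end:
            raise TjsonError(f"line {line_no}: empty interval {start}-{end}")
        obj: dict[str, Any] = {
            "_landmark": chrom,
            "_minBP": start + 1,
            "_maxBP": end,
        }
        if len(cells) > 3 and cells[3] not in (".", ""):
            obj["_id"] = cells[3]
        if len(cells) > 4 and cells[4] not in (".", ""):
            obj["score"] = cells[4]
        if len(cells) > 5 and cells[5] in ("+", "-"):
            obj["_strand"] = cells[5]
        yield f"{line}\t{dumps_compact(obj)}"


def drill_columns(
    stream: Iterable[str],
    target: int,
    paths: "Sequence[JsonPath | str]",
    keep: bool = False,
    emit_header: bool = True,
) -> Iterator[str]:
    """Replace a JSON column by one flat column per drill path.

    *target* is a signed 1-based column selector (-1 = last).  With *keep*
    the JSON column is retained ahead of the drilled columns.  A comment
    line naming the output columns is emitted after any passed-through
    headers (suppress with ``emit_header=False``).  Missing paths yield the
    ``"."`` token; non-target columns are never perturbed.
    """
    parsed = [JsonPath.parse(p) if isinstance(p, str) else p for p in paths]
    if not parsed:
        raise TjsonError("drill requires at least one path")
    announced = not emit_header
    for line_no, line in enumerate(stream, start=1):
        if is_header(line):
            yield line
            continue
        record = TjsonRecord.parse(line)
        idx = resolve_column(target, len(record.columns))
        cell = record.columns[idx]
        if not is_json_cell(cell):
            raise TjsonError(f"line {line_no}: target column {target} is not JSON")
        if not announced:
            names = [f"c{i + 1}" for i in range(len(record.columns))]
            out_names = names[:idx]
            if keep:
                out_names.append(names[idx])
            out_names += [str(p) for p in parsed]
            out_names += names[idx + 1:]
            yield "#" + "\t".join(out_names)
            announced = True
        drilled = [drill(cell, p) for p in parsed]
        out = record.columns[:idx]
        if keep:
            out.append(cell)
        out += drilled
        out += record.columns[idx + 1:]
        yield "\t".join(out)


def _flatten_paths(obj: Any, prefix: str = "") -> Iterator[tuple[str, Any]]:
    if isinstance(obj, dict):
        for key, value in obj.items():
            name = f"{prefix}.{key}" if prefix else str(key)
            if isinstance(value, dict):
                yield from _flatten_paths(value, name)
            else:
                yield name, value
    else:
        yield prefix, obj


def tjson_to_tsv(
    stream: Iterable[str], paths: "Optional[Sequence[str]]" = None
) -> Iterator[str]:
    """Flatten a TJSON stream into plain TSV.

    JSON columns are expanded into one column per dotted key path.  With
    *paths* given, those columns are emitted in a single pass (suitable for
    pipes); otherwise the stream is buffered and the paths are discovered
    in first-seen order.  A ``#`` header line names the output columns;
    values missing from a record render as ``"."``.  All data lines must
    share the same arity.
    """
    if paths is not None:
        yield from _tsv_single_pass(stream, list(paths))
        return
    headers: list[str] = []
    records: list[TjsonRecord] = []
    arity: Optional[int] = None
    for line_no, line in enumerate(stream, start=1):
        if is_header(line):
            headers.append(line)
            continue
        record = TjsonRecord.parse(line)
        if arity is None:
            arity = len(record.columns)
        elif len(record.columns) != arity:
            raise TjsonError(
                f"ragged arity at line {line_no}: {len(record.columns)} != {arity}"
            )
        records.append(record)
    yield from headers
    if arity is None:
        return
    # per-column schema: either opaque (None) or ordered drill paths
    json_cols: dict[int, list[str]] = {}
    parsed_cells: list[list[Any]] = []
    for record in records:
        row = []
        for i, cell in enumerate(record.columns):
            if is_json_cell(cell):
                obj = loads_object(cell)
                row.append(obj)
                seen = json_cols.setdefault(i, [])
                for path, _ in _flatten_paths(obj):
                    if path not in seen:
                        seen.append(path)
            else:
                row.append(None)
        parsed_cells.append(row)
    names: list[str] = []
    for i in range(arity):
        if i in json_cols:
            names.extend(json_cols[i])
        else:
            names.append(f"c{i + 1}")
    yield "#" + "\t".join(names)
    for record, row in zip(records, parsed_cells):
        out: list[str] = []
        for i in range(arity):
            if i in json_cols:
                obj = row[i]
                for path in json_cols[i]:
                    value = JsonPath.parse(path).resolve(obj) if obj else None
                    out.append(MISSING if value is None else render_value(value))
            else:
                out.append(record.columns[i])
        yield "\t".join(out)


def _tsv_single_pass(stream: Iterable[str], paths: list[str]) -> Iterator[str]:
    parsed = [JsonPath.parse(p) for p in paths]
    announced = False
    for line in stream:
        if is_header(line):
            yield line
            continue
        record = TjsonRecord.parse(line)
        if not announced:
            yield "#" + "\t".join(paths)
            announced = True
        obj = None
        for cell in reversed(record.columns):
            if is_json_cell(cell):
                obj = loads_object(cell)
                break
        out = []
        for p in parsed:
            value = p.resolve(obj) if obj is not None else None
            out.append(MISSING if value is None else render_value(value))
        yield "\t".join(out)
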
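"""Annotation catalogs: sorted, BGZF-compressed, Tabix-indexed flat files.

A catalog stores one annotation source as a 4-column TJSON file:

    landmark <TAB> minBP <TAB> maxBP <TAB> JSON payload

The first three columns give the 1-based inclusive genomic interval of the
entry (``0 0`` marks a position-independent entry, e.g. a drug or disease
record); the payload carries all data from the original source plus the
golden keys.  The file is compressed with BGZF and coordinate-indexed with
Tabix, giving random access by region.  Identifier lookups go through
sidecar indices mapping a drilled JSON value to BGZF virtual offsets.

Coordinates use the Tabix "1-based, both ends inclusive" dialect
throughout; BED input is converted at ingest.  Landmark names are matched
exactly (no ``chr1``/``1`` aliasing).
"""

from __future__ import annotations

import bisect
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional

import pysam

from .tjson import (
    GOLDEN_KEYS,
    JsonPath,
    RawNumber,
    TjsonError,
    drill,
    dumps_compact,
    is_header,
)

CATALOG_SUFFIX = ".tsv.bgz"

COLUMN_KINDS = (
    "landmark",
    "start",
    "end",
    "id",
    "ref_allele",
    "alt_alleles",
    "strand",
    "type",
    "data",
    "skip",
)

VALUE_TYPES = ("integer", "float", "text", "list")

_KIND_TO_GOLDEN = {
    "landmark": "_landmark",
    "start": "_minBP",
    "end": "_maxBP",
    "id": "_id",
    "ref_allele": "_refAllele",
    "alt_alleles": "_altAlleles",
    "strand": "_strand",
    "type": "_type",
}


class CatalogError(ValueError):
    """Malformed catalog input or configuration."""


@dataclass(frozen=True)
class CatalogEntry:
    """One catalog line: landmark, 1-based inclusive interval, JSON payload."""

    landmark: str
    min_bp: int
    max_bp: int
    json_text: str

    @classmethod
    def parse(cls, line: str) -> "CatalogEntry":
        parts = line.split("\t")
        if len(parts) != 4:
            raise CatalogError(
                f"catalog line has {len(parts)} fields, expected 4: {line[:80]!r}"
            )
        try:
            min_bp, max_bp = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise CatalogError(f"bad coordinate in catalog line: {line[:80]!r}") from exc
        return cls(parts[0], min_bp, max_bp, parts[3])

    def serialize(self) -> str:
        return f"{self.landmark}\t{self.min_bp}\t{self.max_bp}\t{self.json_text}"

    def is_position_independent(self) -> bool:
        return self.min_bp == 0 and self.max_bp == 0


# ---------------------------------------------------------------------------
# column configuration

@dataclass
class ColumnSpec:
    position: int  # 1-based source column
    name: str  # becomes the JSON key
    kind: str = "data"
    value_type: str = "text"
    delimiter: str = ","


@dataclass
class ColumnConfig:
    """Declarative description of a tab-delimited source's columns.

    The on-disk form is a flat text file, one line per column::

        # position <TAB> name <TAB> kind [<TAB> type [<TAB> delimiter]]
        1   CHROM   landmark
        2   POS     start   integer
        6   ALT     alt_alleles list   ,

    Kinds tag the columns that populate catalog fields and golden keys
    (``landmark``, ``start``, ``end``, ``id``, ``ref_allele``,
    ``alt_alleles``, ``strand``, ``type``); ``data`` columns only become
    JSON keys, ``skip`` columns are dropped.  A directive line
    ``@landmark=<value>`` supplies a constant landmark for sources without
    a sequence column.
    """

    columns: list[ColumnSpec] = field(default_factory=list)
    constant_landmark: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [c.name for c in self.columns if c.kind != "skip"]
        if len(names) != len(set(names)):
            raise CatalogError("duplicate column names in config")
        for c in self.columns:
            if c.kind not in COLUMN_KINDS:
                raise CatalogError(f"unknown column kind: {c.kind!r}")
            if c.value_type not in VALUE_TYPES:
                raise CatalogError(f"unknown value type: {c.value_type!r}")
        n_landmark = sum(c.kind == "landmark" for c in self.columns)
        if n_landmark + (self.constant_landmark is not None) != 1:
            raise CatalogError(
                "config must supply exactly one landmark (column or @landmark=)"
            )
        for kind in ("start", "end"):
            if sum(c.kind == kind for c in self.columns) > 1:
                raise CatalogError(f"more than one {kind} column")

    @classmethod
    def parse(cls, text: str) -> "ColumnConfig":
        columns: list[ColumnSpec] = []
        constant = None
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@landmark="):
                constant = line.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise CatalogError(f"bad config line: {raw!r}")
            try:
                position = int(parts[0])
            except ValueError as exc:
                raise CatalogError(f"bad column position: {parts[0]!r}") from exc
            spec = ColumnSpec(position=position, name=parts[1])
            if len(parts) > 2:
                spec.kind = parts[2]
            if len(parts) > 3:
                spec.value_type = parts[3]
            elif spec.kind in ("start", "end"):
                spec.value_type = "integer"
            elif spec.kind == "alt_alleles":
                spec.value_type = "list"
            if len(parts) > 4:
                spec.delimiter = parts[4]
            columns.append(spec)
        return cls(columns=columns, constant_landmark=constant)

    @classmethod
    def load(cls, path: "str | os.PathLike") -> "ColumnConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.parse(fh.read())


def _typed_value(text: str, spec: ColumnSpec) -> Any:
    if spec.value_type == "integer":
        try:
            return int(text)
        except ValueError as exc:
            if spec.kind in ("start", "end"):
                raise CatalogError(f"bad coordinate: {text!r}") from exc
            raise CatalogError(
                f"bad integer in column {spec.name!r}: {text!r}"
            ) from exc
    if spec.value_type == "float":
        try:
            float(text)
        except ValueError as exc:
            raise CatalogError(
                f"bad float in column {spec.name!r}: {text!r}"
            ) from exc
        return RawNumber(text)
    if spec.value_type == "list":
        return text.split(spec.delimiter)
    return text


def create_catalog(
    source: Iterable[str], config: ColumnConfig
) -> Iterator[str]:
    """Convert tab-delimited source rows into (unsorted) catalog lines.

    Each data row yields one catalog line; ``#``-prefixed source lines are
    skipped.  Output depends only on the row and the config, so the
    conversion streams.
    """
    max_pos = max((c.position for c in config.columns), default=0)
    for row_no, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or is_header(line):
            continue
        cells = line.split("\t")
        if len(cells) < max_pos:
            raise CatalogError(
                f"row {row_no} has {len(cells)} columns, config requires {max_pos}"
            )
        payload: dict[str, Any] = {}
        golden: dict[str, Any] = {}
        landmark = config.constant_landmark or ""
        min_bp = max_bp = 0
        for spec in config.columns:
            text = cells[spec.position - 1]
            if spec.kind == "skip":
                continue
            if text == "":
                continue  # absent value: no JSON key, coordinates default to 0
            value = _typed_value(text, spec)
            payload[spec.name] = value
            gkey = _KIND_TO_GOLDEN.get(spec.kind)
            if gkey == "_landmark":
                landmark = str(value)
                golden[gkey] = landmark
            elif gkey == "_minBP":
                min_bp = int(value)
                golden[gkey] = min_bp
            elif gkey == "_maxBP":
                max_bp = int(value)
                golden[gkey] = max_bp
            elif gkey == "_refAllele":
                golden[gkey] = str(value).upper()
            elif gkey == "_altAlleles":
                alts = value if isinstance(value, list) else [str(value)]
                golden[gkey] = [str(a).upper() for a in alts]
            elif gkey is not None:
                golden[gkey] = value
        if config.constant_landmark is not None:
            golden["_landmark"] = landmark
        if ("_minBP" in golden) != ("_maxBP" in golden):
            # point features configured with only a start column
            pos = golden.get("_minBP", golden.get("_maxBP"))
            golden["_minBP"] = golden["_maxBP"] = pos
            min_bp = max_bp = pos
        ordered = {k: golden[k] for k in GOLDEN_KEYS if k in golden}
        for key, value in payload.items():
            ordered.setdefault(key, value)
        yield f"{landmark}\t{min_bp}\t{max_bp}\t{dumps_compact(ordered)}"


def sort_catalog(lines: Iterable[str]) -> list[str]:
    """Sort catalog lines by (landmark, minBP, maxBP); stable for ties.

    Landmarks sort lexicographically, coordinates numerically, so
    position-independent (0,0) entries group first within each landmark.
    Header lines are kept in order at the front.
    """
    headers: list[str] = []
    data: list[str] = []
    for line in lines:
        (headers if is_header(line) else data).append(line)

    def key(line: str) -> tuple[str, int, int]:
        e = CatalogEntry.parse(line)
        return (e.landmark, e.min_bp, e.max_bp)

    return headers + sorted(data, key=key)


def _check_sorted(lines: list[str]) -> None:
    prev: Optional[tuple[str, int, int]] = None
    for i, line in enumerate(lines, start=1):
        if is_header(line):
            if prev is not None:
                raise CatalogError(f"catalog not sorted: header after data at line {i}")
            continue
        e = CatalogEntry.parse(line)
        cur = (e.landmark, e.min_bp, e.max_bp)
        if prev is not None and cur < prev:
            raise CatalogError(f"catalog not sorted: line {i}")
        prev = cur


def compress_and_index(
    lines: Iterable[str], out_prefix: "str | os.PathLike"
) -> "Catalog":
    """Write sorted catalog lines as BGZF + Tabix index.

    ``out_prefix`` may or may not carry the ``.tsv.bgz`` suffix; the data
    file is ``<prefix>.tsv.bgz`` and the index ``<prefix>.tsv.bgz.tbi``.
    Raises ``catalog not sorted`` on out-of-order input.
    """
    lines = list(lines)
    _check_sorted(lines)
    prefix = str(out_prefix)
    if prefix.endswith(CATALOG_SUFFIX):
        prefix = prefix[: -len(CATALOG_SUFFIX)]
    plain = prefix + ".tsv"
    data = plain + ".bgz"
    with open(plain, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")
    pysam.tabix_compress(plain, data, force=True)
    os.unlink(plain)
    # htslib logs a warning per (0,0) line at index build; these entries are
    # intentionally unindexed (position-independent), so silence it.
    verbosity = pysam.set_verbosity(0)
    try:
        pysam.tabix_index(
            data,
            seq_col=0,
            start_col=1,
            end_col=2,
            meta_char="#",
            zerobased=False,
            force=True,
        )
    finally:
        pysam.set_verbosity(verbosity)
    return Catalog(data)


def build_catalog(
    source: Iterable[str],
    config: ColumnConfig,
    out_prefix: "str | os.PathLike",
) -> "Catalog":
    """create → sort → compress+index in one call."""
    return compress_and_index(sort_catalog(create_catalog(source, config)), out_prefix)


# ---------------------------------------------------------------------------
# random access

class Catalog:
    """Random-access view of a built catalog (data file + Tabix index)."""

    def __init__(self, path: "str | os.PathLike") -> None:
        self.path = str(path)
        if not os.path.exists(self.path):
            raise FileNotFoundError(f"missing catalog file: {self.path}")
        self._tabix: Optional[pysam.TabixFile] = None
        self._contigs: Optional[set] = None
        self._id_indices: dict[str, IdIndex] = {}
        self._bgzf: Optional[pysam.BGZFile] = None

    def _bgzf_file(self) -> pysam.BGZFile:
        # persistent handle for offset fetches; one seek per access
        if self._bgzf is None:
            self._bgzf = pysam.BGZFile(self.path)
        return self._bgzf

    # -- coordinate access ------------------------------------------------

    def _tabix_file(self) -> pysam.TabixFile:
        if self._tabix is None:
            self._tabix = pysam.TabixFile(self.path)
            self._contigs = set(self._tabix.contigs)
        return self._tabix

    def query(self, landmark: str, min_bp: int, max_bp: int) -> Iterator[CatalogEntry]:
        """Entries whose 1-based inclusive interval intersects the query.

        Position-independent (0,0) entries are never returned.  An unknown
        landmark yields no hits (exact name match, no aliasing).
        """
        if max_bp < min_bp:
            raise CatalogError(f"empty query interval {min_bp}-{max_bp}")
        tbx = self._tabix_file()
        if landmark not in (self._contigs or ()):
            return
        for line in tbx.fetch(landmark, max(min_bp - 1, 0), max_bp):
            entry = CatalogEntry.parse(line)
            if not entry.is_position_independent():
                yield entry

    # -- sequential access -------------------------------------------------

    def iter_lines(self) -> Iterator[str]:
        with pysam.BGZFile(self.path) as bf:
            for raw in bf:
                yield raw.decode("utf-8").rstrip("\n")

    def iter_entries(self) -> Iterator[CatalogEntry]:
        for line in self.iter_lines():
            if not is_header(line):
                yield CatalogEntry.parse(line)

    def entry_at(self, virtual_offset: int) -> CatalogEntry:
        """Read the entry starting at a BGZF virtual offset."""
        bf = self._bgzf_file()
        bf.seek(virtual_offset)
        line = bf.readline().decode("utf-8").rstrip("\n")
        return CatalogEntry.parse(line)

    # -- identifier access -------------------------------------------------

    def id_index_path(self, key: "JsonPath | str") -> str:
        return f"{self.path}.{key}.idx.bgz"

    def id_index(self, key: "JsonPath | str") -> "IdIndex":
        """Load (building on demand) the identifier index for *key*."""
        name = str(key)
        if name not in self._id_indices:
            path = self.id_index_path(name)
            if not os.path.exists(path):
                build_id_index(self, JsonPath.parse(name))
            self._id_indices[name] = IdIndex.load(path)
        return self._id_indices[name]

    def lookup_id(self, key: "JsonPath | str", value: str) -> Iterator[CatalogEntry]:
        """Entries whose drilled *key* equals *value*, in catalog order.

        Reachable for every entry carrying the key, including
        position-independent ones.
        """
        index = self.id_index(key)
        for off in index.get(value):
            yield self.entry_at(off)

    def close(self) -> None:
        if self._tabix is not None:
            self._tabix.close()
            self._tabix = None
        if self._bgzf is not None:
            self._bgzf.close()
            self._bgzf = None

    def __enter__(self) -> "Catalog":
        return self

    def __exit__(self, *exc: Any) -> None:
        self.close()


class IdIndex:
    """Sidecar index: drilled JSON value -> BGZF virtual offsets.

    Persisted as a BGZF-compressed, lexicographically sorted two-column
    text file (``key<TAB>off1,off2,...``) beside the catalog; loaded fully
    and searched by binary bisection.  Human-inspectable with ``bgzip -d``.
    """

    def __init__(self, key: JsonPath, keys: list[str], offsets: list[list[int]]):
        self.key = key
        self._keys = keys
        self._offsets = offsets

    def __len__(self) -> int:
        return len(self._keys)

    def get(self, value: str) -> list[int]:
        i = bisect.bisect_left(self._keys, value)
        if i < len(self._keys) and self._keys[i] == value:
            return self._offsets[i]
        return []

    def keys(self) -> list[str]:
        return list(self._keys)

    @classmethod
    def load(cls, path: "str | os.PathLike") -> "IdIndex":
        key_text = None
        keys: list[str] = []
        offsets: list[list[int]] = []
        with pysam.BGZFile(str(path)) as bf:
            for raw in bf:
                line = raw.decode("utf-8").rstrip("\n")
                if is_header(line):
                    if line.startswith("#key="):
                        key_text = line[len("#key="):]
                    continue
                if not line:
                    continue
                key, offs = line.rsplit("\t", 1)
                keys.append(key)
                offsets.append([int(o) for o in offs.split(",")])
        if key_text is None:
            raise CatalogError(f"id index missing #key= header: {path}")
        return cls(JsonPath.parse(key_text), keys, offsets)


def build_id_index(catalog: Catalog, key: "JsonPath | str") -> IdIndex:
    """Build and persist the identifier index for *key* over *catalog*.

    Every entry whose drilled key is present appears once per occurrence;
    entries lacking the key are skipped silently.  Offsets are BGZF virtual
    offsets into the catalog data file.
    """
    if isinstance(key, str):
        key = JsonPath.parse(key)
    mapping: dict[str, list[int]] = {}
    with pysam.BGZFile(catalog.path) as bf:
        while True:
            offset = bf.tell()
            raw = bf.readline()
            if not raw:
                break
            line = raw.decode("utf-8").rstrip("\n")
            if not line or is_header(line):
                continue
            entry = CatalogEntry.parse(line)
            value = drill(entry.json_text, key)
            if value != ".":
                mapping.setdefault(value, []).append(offset)
    out_path = catalog.id_index_path(key)
    with pysam.BGZFile(out_path, "wb") as out:
        out.write(f"#key={key}\n".encode("utf-8"))
        for value in sorted(mapping):
            offs = ",".join(str(o) for o in mapping[value])
            out.write(f"{value}\t{offs}\n".encode("utf-8"))
    return IdIndex.load(out_path)
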
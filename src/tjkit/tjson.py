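"""Core TJSON data model.

TJSON is a hybrid line format: tab-separated columns in which any cell may
be either a plain scalar token or an embedded JSON *object* string.  It is
the universal stream representation of this toolkit — every command reads
TJSON on stdin and writes TJSON on stdout, which is what makes the commands
composable with ordinary UNIX pipes.

A cell is classified as JSON iff it begins with ``{`` and parses as a JSON
object; everything else is an opaque scalar.  Classification is therefore
deterministic and needs no schema.

Nested values are addressed by *drill paths*: dot-joined key sequences such
as ``INFO.EUR_AF``.  Dot is the only separator, so keys containing a
literal dot are unreachable by textual paths, and array elements are not
individually addressable (arrays render as compact JSON).  These are
documented limitations, not bugs.

JSON numbers are kept in their source text form during parsing so that a
value printed as ``0.12`` drills out as ``0.12``, never as
``0.12000000000000001``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Iterable, Iterator, Optional

#: Token emitted when a drill path has no value at a record.
MISSING = "."

#: Reserved JSON keys carrying cross-catalog semantics ("golden" keys).
GOLDEN_KEYS = (
    "_landmark",
    "_minBP",
    "_maxBP",
    "_refAllele",
    "_altAlleles",
    "_id",
    "_strand",
    "_type",
)


class TjsonError(ValueError):
    """Malformed TJSON input."""


class RawNumber(str):
    """A JSON number preserved as its original source text.

    Subclassing :class:`str` keeps comparisons and rendering trivial; the
    numeric value is available via ``float(raw)`` when needed.
    """

    __slots__ = ()


def _loads(text: str) -> Any:
    return json.loads(text, parse_float=RawNumber)


def loads_object(text: str) -> dict:
    """Parse *text* as a JSON object, numbers kept as source text.

    Raises :class:`TjsonError` ("invalid JSON payload") on malformed JSON
    or a non-object top level.
    """
    try:
        obj = _loads(text)
    except json.JSONDecodeError as exc:
        raise TjsonError(f"invalid JSON payload: {exc.msg}") from exc
    if not isinstance(obj, dict):
        raise TjsonError("invalid JSON payload: top level is not an object")
    return obj


def is_json_cell(cell: str) -> bool:
    """True iff *cell* starts with ``{`` and parses as a JSON object."""
    if not cell.startswith("{"):
        return False
    try:
        return isinstance(_loads(cell), dict)
    except json.JSONDecodeError:
        return False


def dumps_compact(value: Any) -> str:
    """Serialize a JSON value compactly, re-emitting RawNumber source text."""
    if isinstance(value, RawNumber):
        return str(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    if value is None:
        return "null"
    if isinstance(value, str):
        return json.dumps(value, ensure_ascii=False)
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, dict):
        inner = ",".join(
            json.dumps(str(k), ensure_ascii=False) + ":" + dumps_compact(v)
            for k, v in value.items()
        )
        return "{" + inner + "}"
    if isinstance(value, (list, tuple)):
        return "[" + ",".join(dumps_compact(v) for v in value) + "]"
    raise TypeError(f"not a JSON value: {type(value)!r}")


def render_value(value: Any) -> str:
    """Render a drilled JSON value as a flat TSV cell.

    Scalars lose their quotes; numbers keep their source text; booleans
    render ``true``/``false``; null renders as the missing token; objects
    and arrays render as compact JSON.
    """
    if value is None:
        return MISSING
    if isinstance(value, RawNumber):
        return str(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return value
    if isinstance(value, (int, float)):
        return repr(value)
    return dumps_compact(value)


@dataclass(frozen=True)
class JsonPath:
    """A dot-joined key path into nested JSON objects, e.g. ``INFO.EUR_AF``."""

    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise TjsonError("empty drill path")
        for seg in self.segments:
            if not seg or "." in seg or "\t" in seg:
                raise TjsonError(f"illegal path segment: {seg!r}")

    @classmethod
    def parse(cls, text: str) -> "JsonPath":
        return cls(tuple(text.split(".")))

    def __str__(self) -> str:
        return ".".join(self.segments)

    def resolve(self, obj: dict) -> Any:
        """Value at this path, or ``None`` when any segment is missing."""
        cur: Any = obj
        for seg in self.segments:
            if not isinstance(cur, dict) or seg not in cur:
                return None
            cur = cur[seg]
        return cur


def drill(json_text: str, path: "JsonPath | str") -> str:
    """Extract the value at *path* from a JSON object string.

    Returns the rendered value, or the missing token ``"."`` when the path
    does not resolve.  Never raises on well-formed JSON input.
    """
    if isinstance(path, str):
        path = JsonPath.parse(path)
    obj = loads_object(json_text)
    value = path.resolve(obj)
    # an explicit JSON null and a missing key both render as the token
    return MISSING if value is None else render_value(value)


@dataclass
class TjsonRecord:
    """One TJSON line: an ordered list of tab-free text cells."""

    columns: list[str]

    def __post_init__(self) -> None:
        # [""] would serialize to the empty string, which parse rejects;
        # forbid it so parse and serialize stay mutually inverse
        if not self.columns or self.columns == [""]:
            raise TjsonError("empty record")
        for cell in self.columns:
            if "\t" in cell or "\n" in cell or "\r" in cell:
                raise TjsonError("illegal cell character")

    @classmethod
    def parse(cls, line: str) -> "TjsonRecord":
        if line == "":
            raise TjsonError("empty record")
        if "\n" in line or "\r" in line:
            raise TjsonError("record contains newline")
        return cls(line.split("\t"))

    def serialize(self) -> str:
        return "\t".join(self.columns)

    def __len__(self) -> int:
        return len(self.columns)

    def cell(self, selector: int) -> str:
        """Cell by signed 1-based selector: +1 = first, -1 = last."""
        return self.columns[resolve_column(selector, len(self.columns))]

    def json_cell(self, selector: int) -> dict:
        """Parse the selected cell as a JSON object."""
        return loads_object(self.cell(selector))


def resolve_column(selector: int, arity: int) -> int:
    """Map a signed 1-based column selector to a 0-based list index.

    Positive counts from the left (1 = first), negative from the right
    (-1 = last); 0 is illegal.
    """
    if selector == 0:
        raise TjsonError("column selector must be nonzero")
    idx = selector - 1 if selector > 0 else arity + selector
    if not 0 <= idx < arity:
        raise TjsonError(
            f"column {selector} out of range for {arity}-column record"
        )
    return idx


def parse_tjson_line(line: str) -> TjsonRecord:
    """Parse one TJSON line into a record (see :meth:`TjsonRecord.parse`)."""
    return TjsonRecord.parse(line)


def serialize_tjson(record: TjsonRecord) -> str:
    """Serialize a record back to its tab-joined line form."""
    return record.serialize()


# ---------------------------------------------------------------------------
# golden attributes

_ALLELE_ALPHABET = set("ACGTN-")


@dataclass
class GoldenAttributes:
    """The reserved, semantically consistent keys of a catalog payload.

    Every field is optional: an annotation entry carries only the golden
    keys that make sense for it.  ``min_bp == max_bp == 0`` is the sentinel
    for position-independent entries.
    """

    landmark: Optional[str] = None
    min_bp: Optional[int] = None
    max_bp: Optional[int] = None
    ref_allele: Optional[str] = None
    alt_alleles: Optional[list[str]] = None
    id: Optional[str] = None
    strand: Optional[str] = None
    type: Optional[str] = None

    def has_interval(self) -> bool:
        return (
            self.landmark is not None
            and self.min_bp is not None
            and self.max_bp is not None
        )

    def is_position_independent(self) -> bool:
        return self.min_bp == 0 and self.max_bp == 0


def _coerce_coord(value: Any, key: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, RawNumber, str)):
        raise TjsonError(f"malformed golden coordinate: {key}={value!r}")
    if isinstance(value, int):
        return value
    try:
        return int(str(value))
    except ValueError as exc:
        raise TjsonError(f"malformed golden coordinate: {key}={value!r}") from exc


def _coerce_alleles(value: Any) -> list[str]:
    if isinstance(value, str):
        value = [value]
    if not isinstance(value, list):
        raise TjsonError(f"malformed allele list: {value!r}")
    return [str(a).upper() for a in value]


def extract_golden(json_text: "str | dict") -> GoldenAttributes:
    """Extract golden attributes from a JSON object (string or parsed).

    Absent reserved keys yield absent fields; non-reserved keys — including
    unknown underscore-prefixed ones — are ignored entirely.  Alleles are
    uppercased.
    """
    obj = loads_object(json_text) if isinstance(json_text, str) else json_text
    g = GoldenAttributes()
    if "_landmark" in obj:
        g.landmark = str(obj["_landmark"])
    if "_minBP" in obj:
        g.min_bp = _coerce_coord(obj["_minBP"], "_minBP")
    if "_maxBP" in obj:
        g.max_bp = _coerce_coord(obj["_maxBP"], "_maxBP")
    if "_refAllele" in obj:
        g.ref_allele = str(obj["_refAllele"]).upper()
    if "_altAlleles" in obj:
        g.alt_alleles = _coerce_alleles(obj["_altAlleles"])
    if "_id" in obj:
        g.id = str(obj["_id"])
    if "_strand" in obj:
        g.strand = str(obj["_strand"])
    if "_type" in obj:
        g.type = str(obj["_type"])
    return g


# ---------------------------------------------------------------------------
# stream plumbing

def is_header(line: str) -> bool:
    return line.startswith("#")


def iter_lines(stream: Iterable[str]) -> Iterator[str]:
    """Strip trailing newlines from an iterable of raw text lines."""
    for raw in stream:
        yield raw.rstrip("\n")
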
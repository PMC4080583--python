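"""Typed Dublin Core technical-metadata records.

The archive describes every stored object with the 15-element Dublin Core
Metadata Element Set (DCMES): contributor, coverage, creator, date,
description, format, identifier, language, publisher, relation, rights,
source, subject, title, type.  Each element has a suitable data type —
``creator`` and ``contributor`` are structured persons (name +
affiliation), ``date`` is an ISO-8601 calendar date, everything else is
UTF-8 text.  Elements that have not been supplied carry an explicit
*unknown* marker rather than being absent, which keeps records
fixed-shape for indexing and for migration to registrar metadata.

File *size* is deliberately **not** a metadata element: it is an
attribute of a stored version and is injected into human-readable
listings at render time only, keeping the element set at exactly 15.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterator, Mapping

from lxml import etree

from .errors import ValidationError

#: The fixed DCMES element names, alphabetically ordered.
ELEMENT_NAMES: tuple[str, ...] = (
    "contributor",
    "coverage",
    "creator",
    "date",
    "description",
    "format",
    "identifier",
    "language",
    "publisher",
    "relation",
    "rights",
    "source",
    "subject",
    "title",
    "type",
)

_PERSON_ELEMENTS = ("contributor", "creator")


class _Unknown:
    """Singleton marker for an element that has not been set."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNKNOWN"

    def __bool__(self) -> bool:
        return False


#: Explicit marker stored in every unset element slot.
UNKNOWN = _Unknown()


def element_names() -> frozenset[str]:
    """The fixed set of the 15 DCMES element names."""
    return frozenset(ELEMENT_NAMES)


@dataclass(frozen=True)
class Person:
    """Structured person value for the creator and contributor elements.

    Rendered and indexed as the display string ``"<name>, <affiliation>"``.
    """

    name: str
    affiliation: str = ""

    def __post_init__(self):
        if not self.name.strip():
            raise ValidationError("person name must be non-empty")

    def display(self) -> str:
        if self.affiliation:
            return f"{self.name}, {self.affiliation}"
        return self.name

    @classmethod
    def parse(cls, text: str) -> "Person":
        """Parse a display string back into a person.

        Names are conventionally written ``"Last, First"``, so the first
        two comma-separated fields form the name and the remainder the
        affiliation; with fewer than three fields the whole string is
        taken as the name.
        """
        parts = [p.strip() for p in text.split(",")]
        if len(parts) >= 3:
            return cls(name=", ".join(parts[:2]), affiliation=", ".join(parts[2:]))
        return cls(name=text.strip())


def _coerce(name: str, value):
    """Validate and type a raw value for element *name*."""
    if value is UNKNOWN or value is None:
        return UNKNOWN
    if name in _PERSON_ELEMENTS:
        if isinstance(value, Person):
            return value
        if isinstance(value, Mapping):
            return Person(**value)
        if isinstance(value, str):
            if not value.strip():
                raise ValidationError(f"{name}: person name must be non-empty")
            return Person.parse(value)
        raise ValidationError(f"{name}: expected a person, got {type(value).__name__}")
    if name == "date":
        if isinstance(value, _dt.datetime):
            return value.date()
        if isinstance(value, _dt.date):
            return value
        if isinstance(value, str):
            try:
                return _dt.date.fromisoformat(value[:10])
            except ValueError as exc:
                raise ValidationError(f"date: not an ISO-8601 date: {value!r}") from exc
        raise ValidationError(f"date: expected a date, got {type(value).__name__}")
    if isinstance(value, str):
        return value
    raise ValidationError(f"{name}: expected text, got {type(value).__name__}")


class MetaData:
    """An immutable, fully-typed DCMES record.

    Construct through :func:`make_metadata`; every one of the 15 element
    slots is always present, holding either a typed value or
    :data:`UNKNOWN`.
    """

    __slots__ = ("_values",)

    def __init__(self, values: dict):
        object.__setattr__(self, "_values", values)

    def __setattr__(self, *a):  # pragma: no cover - guard
        raise AttributeError("MetaData is immutable")

    def get(self, name: str):
        if name not in ELEMENT_NAMES:
            raise ValidationError(f"unknown metadata element: {name!r}")
        return self._values[name]

    def is_set(self, name: str) -> bool:
        return self.get(name) is not UNKNOWN

    def items(self) -> Iterator[tuple[str, object]]:
        """Yield ``(element, value)`` pairs in fixed alphabetical order."""
        for name in ELEMENT_NAMES:
            yield name, self._values[name]

    def replace(self, **changes) -> "MetaData":
        """Return a copy with the given elements re-set (and re-validated)."""
        raw = {n: v for n, v in self.items() if v is not UNKNOWN}
        raw.update(changes)
        return make_metadata(raw)

    def display(self, name: str) -> str:
        """Human-readable string for a set element."""
        value = self.get(name)
        if value is UNKNOWN:
            return ""
        if isinstance(value, Person):
            return value.display()
        if isinstance(value, _dt.date):
            return value.isoformat()
        return str(value)

    def __eq__(self, other) -> bool:
        return isinstance(other, MetaData) and self._values == other._values

    def __hash__(self):
        return hash(tuple(sorted((k, str(v)) for k, v in self._values.items())))

    def __repr__(self) -> str:
        kept = {n: v for n, v in self.items() if v is not UNKNOWN}
        return f"MetaData({kept!r})"

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-safe dict with all 15 keys (unset slots -> None)."""
        out: dict = {}
        for name, value in self.items():
            if value is UNKNOWN:
                out[name] = None
            elif isinstance(value, Person):
                out[name] = {"name": value.name, "affiliation": value.affiliation}
            elif isinstance(value, _dt.date):
                out[name] = value.isoformat()
            else:
                out[name] = value
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "MetaData":
        return make_metadata({k: v for k, v in data.items() if v is not None})


def make_metadata(values: Mapping | None = None) -> MetaData:
    """Build a validated record from a raw ``{element: value}`` mapping.

    Unknown keys and type-invalid values (bad dates, empty person names)
    raise :class:`~edarch.errors.ValidationError`; unspecified elements
    are set to :data:`UNKNOWN`.
    """
    values = dict(values or {})
    bad = set(values) - set(ELEMENT_NAMES)
    if bad:
        raise ValidationError(f"unknown metadata element(s): {sorted(bad)}")
    record = {name: _coerce(name, values.get(name, UNKNOWN)) for name in ELEMENT_NAMES}
    return MetaData(record)


# -- format detection ---------------------------------------------------

_MAGIC: tuple[tuple[bytes, str], ...] = (
    (b"\x1f\x8b", "application/gzip"),
    (b"PK\x03\x04", "application/zip"),
    (b"%PDF", "application/pdf"),
    (b"\x89PNG\r\n\x1a\n", "image/png"),
)

_EXTENSIONS = {
    ".txt": "text/plain",
    ".csv": "text/csv",
    ".tsv": "text/tab-separated-values",
    ".xml": "application/xml",
    ".json": "application/json",
    ".html": "text/html",
    ".fa": "text/plain",
    ".fasta": "text/plain",
    ".fastq": "text/plain",
    ".pdf": "application/pdf",
    ".png": "image/png",
    ".gz": "application/gzip",
    ".zip": "application/zip",
}

#: Fraction of printable bytes above which content counts as plain text.
TEXT_PRINTABLE_THRESHOLD = 0.95


def sniff_format(
    content: bytes,
    filename: str = "",
    *,
    printable_threshold: float = TEXT_PRINTABLE_THRESHOLD,
) -> str:
    """Guess a media type from magic bytes, then a text heuristic, then
    the filename extension; fall back to ``application/octet-stream``."""
    for magic, mtype in _MAGIC:
        if content.startswith(magic):
            return mtype
    head = content[:1024]
    if head:
        printable = sum(1 for b in head if 32 <= b < 127 or b in (9, 10, 13))
        if printable / len(head) >= printable_threshold:
            return "text/plain"
    dot = filename.rfind(".")
    if dot != -1:
        mtype = _EXTENSIONS.get(filename[dot:].lower())
        if mtype:
            return mtype
    return "application/octet-stream"


# -- rendering -----------------------------------------------------------


def format_size(size_bytes: int) -> str:
    """Format a byte count as KB with one decimal (e.g. 101069 -> ``98.7 KB``)."""
    return f"{size_bytes / 1024:.1f} KB"


def render_listing(metadata: MetaData, size_bytes: int) -> list[tuple[str, str]]:
    """Rows ``(label, value)`` for every set element, in fixed alphabetical
    label order, plus a synthetic ``Size`` row for the version's byte count
    (slotted alphabetically between Rights and Source)."""
    rows: list[tuple[str, str]] = []
    for name, value in metadata.items():
        if value is not UNKNOWN:
            rows.append((name.capitalize(), metadata.display(name)))
    size_row = ("Size", format_size(size_bytes))
    for pos, (label, _) in enumerate(rows):
        if label > "Size":
            rows.insert(pos, size_row)
            break
    else:
        rows.append(size_row)
    return rows


# -- flat key=value text form (CLI import/export) ------------------------


def to_text(metadata: MetaData) -> str:
    """One ``element=value`` line per set element, UTF-8, sorted order."""
    lines = [
        f"{name}={metadata.display(name)}"
        for name, value in metadata.items()
        if value is not UNKNOWN
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def from_text(text: str) -> MetaData:
    values: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"line {lineno}: expected element=value")
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    return make_metadata(values)


# -- XML form (per-version metadata documents) ---------------------------


def to_xml(metadata: MetaData) -> bytes:
    """Serialize a record as a deterministic standalone XML document."""
    root = etree.Element("metadata")
    for name, value in metadata.items():
        if value is UNKNOWN:
            continue
        el = etree.SubElement(root, "element", name=name)
        if isinstance(value, Person):
            etree.SubElement(el, "name").text = value.name
            etree.SubElement(el, "affiliation").text = value.affiliation
        else:
            el.text = metadata.display(name)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def from_xml(document: bytes) -> MetaData:
    root = etree.fromstring(document)
    values: dict = {}
    for el in root.findall("element"):
        name = el.get("name")
        if name in _PERSON_ELEMENTS:
            values[name] = Person(
                name=el.findtext("name") or "",
                affiliation=el.findtext("affiliation") or "",
            )
        else:
            values[name] = el.text or ""
    return make_metadata(values)
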
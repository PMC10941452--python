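"""Document and concept-registry ingestion.

Supported document sources: plain text (one document per file, a single
``text`` section), CSV (one document per row, headers become sections),
JSON (one record or a list of records, keys become sections), and
bibliographic identifiers resolved through an injected fetcher emulating
the PubMed / Semantic Scholar / OpenAIRE metadata APIs.

Ingestion is lossless for offsets: section text is the decoded file
content verbatim (UTF-8, BOM stripped, no normalisation) so that stand-off
character offsets computed later always resolve against the same bytes.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

from .model import AnnotationError, Concept, Document, Section

PathLike = Union[str, Path]


class IngestError(AnnotationError):
    """Malformed or undecodable input file."""


@dataclass
class DocumentRecord:
    """Bibliographic metadata for a fetched abstract."""

    external_id: str
    id_kind: str  # "pmid" | "doi"
    title: str = ""
    abstract: str = ""
    authors: list[str] = field(default_factory=list)
    venue: str = ""
    publication_date: str = ""

    def __post_init__(self) -> None:
        if not (self.title or self.abstract):
            raise IngestError(
                "a document record needs a title or an abstract")
        if self.id_kind not in ("pmid", "doi"):
            raise IngestError(f"unknown external id kind {self.id_kind!r}")


def _read_text(path: PathLike) -> str:
    raw = Path(path).read_bytes()
    if raw.startswith(b"\xef\xbb\xbf"):
        raw = raw[3:]
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        # silent replacement would corrupt offsets, so decoding is strict
        raise IngestError(f"{path}: not valid UTF-8 ({exc})") from None


def read_txt(path: PathLike) -> Document:
    """One TXT file -> one document with a single ``text`` section.

    The file content is preserved verbatim (including any trailing
    newline); the document id is the file stem.
    """
    text = _read_text(path)
    if not text:
        raise IngestError(f"{path}: empty file")
    return Document(Path(path).stem, [Section("text", text)])


def read_csv(path: PathLike) -> list[Document]:
    """One CSV row -> one document; each non-id header becomes a section
    in header order.

    A column literally named ``id`` (case-insensitively) holds the
    document id; otherwise the first column does, with a warning.
    Empty cells yield empty sections (present but not annotatable).
    """
    text = _read_text(path)
    reader = csv.reader(io.StringIO(text, newline=""))
    try:
        header = next(reader)
    except StopIteration:
        raise IngestError(f"{path}: missing header row") from None
    if not header:
        raise IngestError(f"{path}: empty header row")
    id_col = next((i for i, h in enumerate(header)
                   if h.strip().lower() == "id"), None)
    if id_col is None:
        id_col = 0
        warnings.warn(
            f"{path}: no 'id' column; using first column "
            f"({header[0]!r}) as the document id", stacklevel=2)
    section_cols = [(i, h) for i, h in enumerate(header) if i != id_col]
    docs: list[Document] = []
    seen: set[str] = set()
    for row_no, row in enumerate(reader, start=2):
        if len(row) != len(header):
            raise IngestError(
                f"{path}: row {row_no} has {len(row)} cells, "
                f"expected {len(header)}")
        doc_id = row[id_col]
        if not doc_id:
            raise IngestError(f"{path}: row {row_no} has an empty id")
        if doc_id in seen:
            raise IngestError(f"{path}: duplicate document id {doc_id!r}")
        seen.add(doc_id)
        docs.append(Document(
            doc_id, [Section(h, row[i]) for i, h in section_cols]))
    return docs


def read_json(path: PathLike) -> list[Document]:
    """JSON record(s) -> documents; keys become sections in key order.

    The top level may be one object or a list of objects of string
    fields.  An ``id`` key becomes the document id; records without one
    get a synthesized ordinal id (``doc-000001``, ...).
    """
    text = _read_text(path)
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise IngestError(f"{path}: invalid JSON ({exc})") from None
    records = data if isinstance(data, list) else [data]
    docs: list[Document] = []
    seen: set[str] = set()
    for i, rec in enumerate(records, start=1):
        if not isinstance(rec, dict):
            raise IngestError(f"{path}: record {i} is not an object")
        doc_id = None
        sections: list[Section] = []
        for key, value in rec.items():
            if key.lower() == "id":
                doc_id = str(value)
                continue
            if not isinstance(value, str):
                raise IngestError(
                    f"{path}: record {i} field {key!r} is not a string "
                    f"(flat records only)")
            sections.append(Section(key, value))
        if not sections:
            raise IngestError(f"{path}: record {i} has no text fields")
        if doc_id is None:
            doc_id = f"doc-{i:06d}"
        if doc_id in seen:
            raise IngestError(f"{path}: duplicate document id {doc_id!r}")
        seen.add(doc_id)
        docs.append(Document(doc_id, sections))
    return docs


# --------------------------------------------------------------------------
# concept templates
# --------------------------------------------------------------------------

_ID_ALIASES = ("identifier", "uri", "id")


def _concept_from_fields(fields: dict, where: str) -> Concept:
    identifier = next((fields[k] for k in _ID_ALIASES
                       if fields.get(k)), None)
    name = fields.get("name", "")
    ctype = fields.get("type", "") or fields.get("concept_type", "")
    if not identifier:
        raise IngestError(f"{where}: identifier (URI/ID) mandatory")
    if not name:
        raise IngestError(f"{where}: name mandatory")
    if not ctype:
        raise IngestError(f"{where}: type mandatory")
    return Concept(identifier, name, ctype,
                   fields.get("description") or None)


def load_concepts(path: PathLike, fmt: Optional[str] = None
                  ) -> list[Concept]:
    """Read a concept template file (CSV or JSON).

    Mandatory fields per record: identifier (``identifier``/``uri``/
    ``id``), ``name``, ``type``; ``description`` is optional.  Identical
    duplicate rows are collapsed; conflicting duplicates are an error,
    both reported with row numbers.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    rows: list[tuple[str, dict]] = []
    if fmt == "csv":
        text = _read_text(path)
        reader = csv.DictReader(io.StringIO(text, newline=""))
        if reader.fieldnames is None:
            raise IngestError(f"{path}: missing header row")
        normalized = [h.strip().lower() for h in reader.fieldnames]
        for row_no, row in enumerate(reader, start=2):
            fields = {n: (v or "").strip()
                      for n, v in zip(normalized, row.values())}
            rows.append((f"{path}: row {row_no}", fields))
    elif fmt == "json":
        data = json.loads(_read_text(path))
        records = data if isinstance(data, list) else [data]
        for i, rec in enumerate(records, start=1):
            if not isinstance(rec, dict):
                raise IngestError(f"{path}: record {i} is not an object")
            rows.append((f"{path}: record {i}",
                         {str(k).lower(): str(v) for k, v in rec.items()
                          if v is not None}))
    else:
        raise IngestError(f"unknown concept template format {fmt!r}")

    out: dict[str, Concept] = {}
    for where, fields in rows:
        concept = _concept_from_fields(fields, where)
        existing = out.get(concept.identifier)
        if existing is None:
            out[concept.identifier] = concept
        elif not existing.same_record(concept):
            raise IngestError(
                f"{where}: conflicting duplicate for concept "
                f"{concept.identifier!r}")
    return list(out.values())


# --------------------------------------------------------------------------
# bibliographic fetchers (injected transport; no live HTTP here)
# --------------------------------------------------------------------------

SOURCES = ("pubmed", "semanticscholar", "openaire")

#: a fetcher maps (identifier, source) -> dict with keys title, abstract,
#: authors, venue, publication_date (all optional but title/abstract)
Fetcher = Callable[[str, str], dict]


def _looks_like_doi(identifier: str) -> bool:
    return identifier.startswith("10.") and "/" in identifier


def fetch_record(identifier: str, source: str, fetcher: Fetcher
                 ) -> DocumentRecord:
    """Resolve a PMID (PubMed) or DOI (Semantic Scholar, OpenAIRE) into a
    DocumentRecord through the injected ``fetcher`` transport."""
    if source not in SOURCES:
        raise IngestError(f"unknown metadata source {source!r}")
    if source == "pubmed":
        if not identifier.isdigit():
            raise IngestError(
                f"PubMed requires a numeric PMID, got {identifier!r}")
        id_kind = "pmid"
    else:
        if not _looks_like_doi(identifier):
            raise IngestError(
                f"{source} requires a DOI, got {identifier!r}")
        id_kind = "doi"
    try:
        payload = fetcher(identifier, source)
    except Exception as exc:
        raise IngestError(f"{source} fetch failed: {exc}") from exc
    return DocumentRecord(
        external_id=identifier,
        id_kind=id_kind,
        title=payload.get("title", "") or "",
        abstract=payload.get("abstract", "") or "",
        authors=list(payload.get("authors", []) or []),
        venue=payload.get("venue", "") or "",
        publication_date=payload.get("publication_date", "") or "",
    )


def record_to_document(record: DocumentRecord) -> Document:
    """Map a fetched record to a document with ``title`` and ``abstract``
    sections (empty sections omitted); the id mirrors the source, e.g.
    ``pubmed_27839516`` for a PMID."""
    prefix = "pubmed" if record.id_kind == "pmid" else "doi"
    doc_id = f"{prefix}_{record.external_id}" if prefix == "pubmed" \
        else f"doi_{record.external_id.replace('/', '_')}"
    sections = []
    if record.title:
        sections.append(Section("title", record.title))
    if record.abstract:
        sections.append(Section("abstract", record.abstract))
    return Document(doc_id, sections, metadata={
        "external_id": record.external_id,
        "id_kind": record.id_kind,
        "title": record.title,
        "authors": record.authors,
        "venue": record.venue,
        "publication_date": record.publication_date,
    })


class PdfParser:
    """Interface stub for PDF full-text extraction.

    Structured PDF parsing requires an external service; this package
    declares the contract only.  Implementations must provide
    ``parse(path) -> Document``.
    """

    def parse(self, path: PathLike) -> Document:  # pragma: no cover
        raise NotImplementedError(
            "PDF parsing requires an external parser implementation")
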
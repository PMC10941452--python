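"""Bit-stable interchange and persistence.

Three export formats — JSON (documented schema, versioned), CSV
(RFC-4180, one file per annotation type, zipped when several types are
requested) and BioC-XML — plus the directory-per-collection file store.

Determinism: exports of the same state are byte-identical (stable key
ordering, annotations ordered by identity key, fixed zip timestamps), and
``export -> import into a fresh store -> export`` is the identity on the
representable content for all three formats.

BioC dialect
------------
* one passage per section, in canonical section order; passage offsets
  are absolute over the concatenation of the sections separated by
  single newlines;
* a mention (with its concept links) maps to a BioC ``annotation`` whose
  infons carry the annotator and the ``|``-joined concept ids, names and
  types (concept ids must therefore not contain ``|``);
* a relationship maps to a ``relation`` whose nodes reference mention
  annotations by id and whose infons carry concept / free-text
  components (free-text predicates are flagged distinctly);
* an assertion maps to a ``relation`` with zero nodes and its three
  concept components in infons (BioC relations normally reference
  annotations; pure-concept triples have none to reference);
* label annotations map to document-level infons.

On import every span is re-validated against the document text
(``surface == text[start:end)`` is enforced, not assumed) and the whole
file is committed all-or-nothing.
"""

from __future__ import annotations

import difflib
import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import csv

from lxml import etree

from .model import (
    ANNOTATION_TYPES,
    AnnotationError,
    AnnotationSet,
    Assertion,
    Collection,
    Concept,
    Document,
    LabelAnnotation,
    Mention,
    NotFoundError,
    RelComponent,
    Relationship,
    Section,
    Span,
    TYPE_ASSERTION,
    TYPE_LABEL,
    TYPE_MENTION,
    TYPE_RELATIONSHIP,
    identity_key,
    relationship_key,
)

SCHEMA_VERSION = "1"

EXPORT_TYPES = (TYPE_MENTION, TYPE_RELATIONSHIP, TYPE_ASSERTION, TYPE_LABEL)


class ImportError_(AnnotationError):
    """Malformed or inconsistent annotation file (nothing committed)."""


@dataclass
class ExportRequest:
    """What to export: scope, annotation types, annotator and format.

    ``annotator_id=None`` exports every annotator in scope (including
    the machine annotator and any materialized consensus set).
    Concept links always travel with their mentions.
    """

    fmt: str                                  # "json" | "csv" | "bioc"
    annotation_types: tuple = EXPORT_TYPES
    annotator_id: Optional[str] = None
    document_id: Optional[str] = None         # None = whole collection
    round_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fmt not in ("json", "csv", "bioc"):
            raise AnnotationError(f"unknown export format {self.fmt!r}")
        if not self.annotation_types:
            raise AnnotationError("at least one annotation type required")
        unknown = set(self.annotation_types) - set(EXPORT_TYPES)
        if unknown:
            raise AnnotationError(
                f"unknown annotation types {sorted(unknown)} "
                f"(concept links travel with mentions)")


@dataclass
class ImportReport:
    added: dict = field(default_factory=lambda: {t: 0 for t in EXPORT_TYPES})
    concept_links_added: int = 0
    skipped_duplicates: int = 0

    @property
    def total_added(self) -> int:
        return sum(self.added.values()) + self.concept_links_added


# --------------------------------------------------------------------------
# record construction (shared by JSON and CSV)
# --------------------------------------------------------------------------

def _scope_sets(collection: Collection, request: ExportRequest
                ) -> list[AnnotationSet]:
    rnd = collection.round(request.round_index)
    out = []
    for (ann, doc), aset in sorted(rnd.sets.items()):
        if request.annotator_id is not None and ann != request.annotator_id:
            continue
        if request.document_id is not None and doc != request.document_id:
            continue
        out.append(aset)
    if request.annotator_id is not None and not out:
        members = {a for (a, _d) in rnd.sets}
        if request.annotator_id not in collection.member_ids \
                and request.annotator_id not in members:
            raise NotFoundError(
                f"unknown annotator {request.annotator_id!r}")
    return out


def _component_record(comp: RelComponent, aset: AnnotationSet) -> dict:
    if comp.kind == "concept":
        return {"kind": "concept", "concept": comp.ref}
    if comp.kind == "text":
        return {"kind": "text", "text": comp.ref}
    m = aset.mentions[comp.ref]
    return {"kind": "mention", "mention_id": comp.ref,
            "section": m.span.section_name,
            "start": m.span.start, "end": m.span.end}


def _records(collection: Collection, request: ExportRequest
             ) -> dict[str, list[dict]]:
    sets = _scope_sets(collection, request)
    recs: dict[str, list[dict]] = {t: [] for t in EXPORT_TYPES}
    for aset in sets:
        if TYPE_MENTION in request.annotation_types:
            for m in aset.mentions.values():
                recs[TYPE_MENTION].append({
                    "id": m.mention_id, "annotator": aset.annotator_id,
                    "document": m.document_id,
                    "section": m.span.section_name,
                    "start": m.span.start, "end": m.span.end,
                    "surface": m.span.surface,
                    "concepts": list(m.linked_concepts),
                    "created": aset.created.get(m.mention_id, ""),
                    "_key": identity_key(m, aset)})
        if TYPE_RELATIONSHIP in request.annotation_types:
            for r in aset.relationships.values():
                recs[TYPE_RELATIONSHIP].append({
                    "id": r.relationship_id,
                    "annotator": aset.annotator_id,
                    "document": r.document_id,
                    "subject": _component_record(r.subject, aset),
                    "predicate": _component_record(r.predicate, aset),
                    "object": _component_record(r.object, aset),
                    "created": aset.created.get(r.relationship_id, ""),
                    "_key": identity_key(r, aset)})
        if TYPE_ASSERTION in request.annotation_types:
            for a in aset.assertions.values():
                recs[TYPE_ASSERTION].append({
                    "id": a.assertion_id, "annotator": aset.annotator_id,
                    "document": a.document_id, "subject": a.subject,
                    "predicate": a.predicate, "object": a.object,
                    "created": aset.created.get(a.assertion_id, ""),
                    "_key": identity_key(a, aset)})
        if TYPE_LABEL in request.annotation_types:
            for la in aset.labels.values():
                recs[TYPE_LABEL].append({
                    "id": la.label_id, "annotator": aset.annotator_id,
                    "document": la.document_id, "label": la.label,
                    "created": aset.created.get(la.label_id, ""),
                    "_key": identity_key(la, aset)})
    for t in recs:
        recs[t].sort(key=lambda r: (r["annotator"], repr(r["_key"]),
                                    r["id"]))
        for r in recs[t]:
            del r["_key"]
    return recs


# --------------------------------------------------------------------------
# JSON
# --------------------------------------------------------------------------

def _export_json(collection: Collection, request: ExportRequest) -> bytes:
    recs = _records(collection, request)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "format": "annodesk-annotations",
        "collection": collection.collection_id,
        "document": request.document_id,
        "annotator": request.annotator_id,
        "annotation_types": sorted(request.annotation_types),
        "mentions": recs[TYPE_MENTION],
        "relationships": recs[TYPE_RELATIONSHIP],
        "assertions": recs[TYPE_ASSERTION],
        "labels": recs[TYPE_LABEL],
    }
    return (json.dumps(payload, sort_keys=True, ensure_ascii=False,
                       indent=1) + "\n").encode("utf-8")


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------

_CSV_COLUMNS = {
    TYPE_MENTION: ["schema_version", "id", "annotator", "document",
                   "section", "start", "end", "surface", "concepts",
                   "created"],
    TYPE_RELATIONSHIP: ["schema_version", "id", "annotator", "document"]
    + [f"{role}_{f}" for role in ("subject", "predicate", "object")
       for f in ("kind", "ref", "section", "start", "end")]
    + ["created"],
    TYPE_ASSERTION: ["schema_version", "id", "annotator", "document",
                     "subject", "predicate", "object", "created"],
    TYPE_LABEL: ["schema_version", "id", "annotator", "document", "label",
                 "created"],
}


def _csv_rows(annotation_type: str, records: list[dict]) -> list[list]:
    rows = []
    for r in records:
        if annotation_type == TYPE_MENTION:
            rows.append([SCHEMA_VERSION, r["id"], r["annotator"],
                         r["document"], r["section"], r["start"], r["end"],
                         r["surface"], "|".join(r["concepts"]),
                         r["created"]])
        elif annotation_type == TYPE_RELATIONSHIP:
            row = [SCHEMA_VERSION, r["id"], r["annotator"], r["document"]]
            for role in ("subject", "predicate", "object"):
                c = r[role]
                if c["kind"] == "mention":
                    row += ["mention", c["mention_id"], c["section"],
                            c["start"], c["end"]]
                elif c["kind"] == "concept":
                    row += ["concept", c["concept"], "", "", ""]
                else:
                    row += ["text", c["text"], "", "", ""]
            row.append(r["created"])
            rows.append(row)
        elif annotation_type == TYPE_ASSERTION:
            rows.append([SCHEMA_VERSION, r["id"], r["annotator"],
                         r["document"], r["subject"], r["predicate"],
                         r["object"], r["created"]])
        else:
            rows.append([SCHEMA_VERSION, r["id"], r["annotator"],
                         r["document"], r["label"], r["created"]])
    return rows


def _export_csv(collection: Collection, request: ExportRequest) -> bytes:
    recs = _records(collection, request)
    files: dict[str, bytes] = {}
    for t in EXPORT_TYPES:
        if t not in request.annotation_types:
            continue
        buf = io.StringIO(newline="")
        writer = csv.writer(buf, lineterminator="\r\n")
        writer.writerow(_CSV_COLUMNS[t])
        writer.writerows(_csv_rows(t, recs[t]))
        files[f"{t}s.csv"] = buf.getvalue().encode("utf-8")
    if len(files) == 1:
        return next(iter(files.values()))
    out = io.BytesIO()
    with zipfile.ZipFile(out, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(files):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, files[name])
    return out.getvalue()


# --------------------------------------------------------------------------
# BioC-XML
# --------------------------------------------------------------------------

def section_offsets(document: Document) -> dict[str, int]:
    """Absolute passage offsets: sections concatenated in canonical
    order, separated by single newlines."""
    offsets: dict[str, int] = {}
    pos = 0
    for section in document.sections:
        offsets[section.name] = pos
        pos += len(section.text) + 1  # "\n" separator
    return offsets


def _infon(parent, key: str, value: str) -> None:
    el = etree.SubElement(parent, "infon", key=key)
    el.text = value


def _export_bioc(collection: Collection, request: ExportRequest) -> bytes:
    recs = _records(collection, request)
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "annodesk"
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = "annodesk.key"
    _infon(root, "schema_version", SCHEMA_VERSION)

    doc_ids = sorted({r["document"] for t in recs for r in recs[t]})
    if request.document_id is not None:
        doc_ids = sorted(set(doc_ids) | {request.document_id})
    for doc_id in doc_ids:
        document = collection.documents[doc_id]
        offsets = section_offsets(document)
        doc_el = etree.SubElement(root, "document")
        etree.SubElement(doc_el, "id").text = doc_id
        for r in [r for r in recs[TYPE_LABEL] if r["document"] == doc_id]:
            _infon(doc_el, f"label:{r['id']}", json.dumps(
                {"annotator": r["annotator"], "label": r["label"],
                 "created": r["created"]}, sort_keys=True))
        mention_recs = [r for r in recs[TYPE_MENTION]
                        if r["document"] == doc_id]
        for section in document.sections:
            passage = etree.SubElement(doc_el, "passage")
            _infon(passage, "section", section.name)
            etree.SubElement(passage, "offset").text = \
                str(offsets[section.name])
            etree.SubElement(passage, "text").text = section.text
            for r in [m for m in mention_recs
                      if m["section"] == section.name]:
                ann = etree.SubElement(passage, "annotation", id=r["id"])
                _infon(ann, "annotator", r["annotator"])
                concepts = [collection.registry[c] for c in r["concepts"]]
                _infon(ann, "concept_ids",
                       "|".join(c.identifier for c in concepts))
                _infon(ann, "concept_names",
                       "|".join(c.name for c in concepts))
                _infon(ann, "concept_types",
                       "|".join(c.concept_type for c in concepts))
                _infon(ann, "created", r["created"])
                etree.SubElement(
                    ann, "location",
                    offset=str(offsets[section.name] + r["start"]),
                    length=str(r["end"] - r["start"]))
                etree.SubElement(ann, "text").text = r["surface"]
        for r in [x for x in recs[TYPE_RELATIONSHIP]
                  if x["document"] == doc_id]:
            rel = etree.SubElement(doc_el, "relation", id=r["id"])
            _infon(rel, "kind", "relationship")
            _infon(rel, "annotator", r["annotator"])
            for role in ("subject", "predicate", "object"):
                c = r[role]
                _infon(rel, f"{role}_kind", c["kind"])
                if c["kind"] == "concept":
                    _infon(rel, f"{role}_concept", c["concept"])
                elif c["kind"] == "text":
                    # free-text predicate, flagged distinctly
                    _infon(rel, f"{role}_text", c["text"])
            _infon(rel, "created", r["created"])
            for role in ("subject", "predicate", "object"):
                c = r[role]
                if c["kind"] == "mention":
                    etree.SubElement(rel, "node", refid=c["mention_id"],
                                     role=role)
        for r in [x for x in recs[TYPE_ASSERTION]
                  if x["document"] == doc_id]:
            rel = etree.SubElement(doc_el, "relation", id=r["id"])
            _infon(rel, "kind", "assertion")
            _infon(rel, "annotator", r["annotator"])
            _infon(rel, "subject_concept", r["subject"])
            _infon(rel, "predicate_concept", r["predicate"])
            _infon(rel, "object_concept", r["object"])
            _infon(rel, "created", r["created"])
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def export_annotations(collection: Collection,
                       request: ExportRequest) -> bytes:
    """Serialize the requested annotations; deterministic (two exports
    of the same state are byte-identical).  An empty scope yields an
    empty-but-valid file."""
    if request.document_id is not None:
        collection._document(request.document_id)
    if request.fmt == "json":
        return _export_json(collection, request)
    if request.fmt == "csv":
        return _export_csv(collection, request)
    return _export_bioc(collection, request)


# --------------------------------------------------------------------------
# import
# --------------------------------------------------------------------------

def _parse_json(data: bytes) -> dict[str, list[dict]]:
    payload = json.loads(data.decode("utf-8"))
    return {t: payload.get(f"{t}s", []) for t in EXPORT_TYPES}


def _parse_csv(data: bytes) -> dict[str, list[dict]]:
    files: dict[str, bytes]
    if data[:4] == b"PK\x03\x04":
        with zipfile.ZipFile(io.BytesIO(data)) as zf:
            files = {n: zf.read(n) for n in zf.namelist()}
    else:
        text = data.decode("utf-8")
        header = text.split("\r\n", 1)[0].split("\n", 1)[0]
        cols = next(csv.reader(io.StringIO(header)))
        for t, expected in _CSV_COLUMNS.items():
            if cols == expected:
                files = {f"{t}s.csv": data}
                break
        else:
            raise ImportError_("unrecognized CSV header")
    out: dict[str, list[dict]] = {t: [] for t in EXPORT_TYPES}
    for name, blob in files.items():
        t = name[:-5]  # strip "s.csv"
        if t not in EXPORT_TYPES:
            raise ImportError_(f"unrecognized CSV member {name!r}")
        reader = csv.DictReader(io.StringIO(blob.decode("utf-8"),
                                            newline=""))
        for row_no, row in enumerate(reader, start=2):
            try:
                out[t].append(_csv_record(t, row))
            except (KeyError, ValueError) as exc:
                raise ImportError_(
                    f"{name}: row {row_no}: malformed ({exc})") from None
    return out


def _csv_record(annotation_type: str, row: dict) -> dict:
    if annotation_type == TYPE_MENTION:
        return {"id": row["id"], "annotator": row["annotator"],
                "document": row["document"], "section": row["section"],
                "start": int(row["start"]), "end": int(row["end"]),
                "surface": row["surface"],
                "concepts": [c for c in row["concepts"].split("|") if c],
                "created": row["created"]}
    if annotation_type == TYPE_RELATIONSHIP:
        rec = {"id": row["id"], "annotator": row["annotator"],
               "document": row["document"], "created": row["created"]}
        for role in ("subject", "predicate", "object"):
            kind = row[f"{role}_kind"]
            if kind == "mention":
                rec[role] = {"kind": "mention",
                             "mention_id": row[f"{role}_ref"],
                             "section": row[f"{role}_section"],
                             "start": int(row[f"{role}_start"]),
                             "end": int(row[f"{role}_end"])}
            elif kind == "concept":
                rec[role] = {"kind": "concept",
                             "concept": row[f"{role}_ref"]}
            elif kind == "text":
                rec[role] = {"kind": "text", "text": row[f"{role}_ref"]}
            else:
                raise ValueError(f"unknown component kind {kind!r}")
        return rec
    if annotation_type == TYPE_ASSERTION:
        return {"id": row["id"], "annotator": row["annotator"],
                "document": row["document"], "subject": row["subject"],
                "predicate": row["predicate"], "object": row["object"],
                "created": row["created"]}
    return {"id": row["id"], "annotator": row["annotator"],
            "document": row["document"], "label": row["label"],
            "created": row["created"]}


def _parse_bioc(data: bytes, collection: Collection
                ) -> dict[str, list[dict]]:
    root = etree.fromstring(data)
    out: dict[str, list[dict]] = {t: [] for t in EXPORT_TYPES}
    for doc_el in root.findall("document"):
        doc_id = doc_el.findtext("id")
        for infon in doc_el.findall("infon"):
            key = infon.get("key", "")
            if key.startswith("label:"):
                rec = json.loads(infon.text or "{}")
                out[TYPE_LABEL].append({
                    "id": key.split(":", 1)[1],
                    "annotator": rec["annotator"],
                    "document": doc_id, "label": rec["label"],
                    "created": rec.get("created", "")})
        for passage in doc_el.findall("passage"):
            infons = {i.get("key"): (i.text or "")
                      for i in passage.findall("infon")}
            section = infons.get("section", "text")
            offset = int(passage.findtext("offset") or "0")
            for ann in passage.findall("annotation"):
                a_infons = {i.get("key"): (i.text or "")
                            for i in ann.findall("infon")}
                loc = ann.find("location")
                start = int(loc.get("offset")) - offset
                length = int(loc.get("length"))
                ids = [c for c in
                       a_infons.get("concept_ids", "").split("|") if c]
                names = a_infons.get("concept_names", "").split("|")
                types = a_infons.get("concept_types", "").split("|")
                for i, cid in enumerate(ids):
                    if cid not in collection.registry and i < len(names) \
                            and i < len(types) and names[i] and types[i]:
                        collection.register_concept(
                            Concept(cid, names[i], types[i]))
                out[TYPE_MENTION].append({
                    "id": ann.get("id"),
                    "annotator": a_infons.get("annotator", ""),
                    "document": doc_id, "section": section,
                    "start": start, "end": start + length,
                    "surface": ann.findtext("text") or "",
                    "concepts": ids,
                    "created": a_infons.get("created", "")})
        mention_spans = {r["id"]: r for r in out[TYPE_MENTION]
                         if r["document"] == doc_id}
        for rel in doc_el.findall("relation"):
            r_infons = {i.get("key"): (i.text or "")
                        for i in rel.findall("infon")}
            kind = r_infons.get("kind")
            if kind == "assertion":
                out[TYPE_ASSERTION].append({
                    "id": rel.get("id"),
                    "annotator": r_infons.get("annotator", ""),
                    "document": doc_id,
                    "subject": r_infons.get("subject_concept", ""),
                    "predicate": r_infons.get("predicate_concept", ""),
                    "object": r_infons.get("object_concept", ""),
                    "created": r_infons.get("created", "")})
                continue
            nodes = {n.get("role"): n.get("refid")
                     for n in rel.findall("node")}
            rec = {"id": rel.get("id"),
                   "annotator": r_infons.get("annotator", ""),
                   "document": doc_id,
                   "created": r_infons.get("created", "")}
            for role in ("subject", "predicate", "object"):
                comp_kind = r_infons.get(f"{role}_kind", "mention")
                if comp_kind == "concept":
                    rec[role] = {"kind": "concept",
                                 "concept": r_infons[f"{role}_concept"]}
                elif comp_kind == "text":
                    rec[role] = {"kind": "text",
                                 "text": r_infons[f"{role}_text"]}
                else:
                    mid = nodes.get(role)
                    mrec = mention_spans.get(mid)
                    if mrec is None:
                        raise ImportError_(
                            f"relation {rel.get('id')!r}: {role} node "
                            f"references unknown annotation {mid!r}")
                    rec[role] = {"kind": "mention", "mention_id": mid,
                                 "section": mrec["section"],
                                 "start": mrec["start"],
                                 "end": mrec["end"]}
            out[TYPE_RELATIONSHIP].append(rec)
    return out


def import_annotations(data: bytes, fmt: str, collection: Collection,
                       round_index: Optional[int] = None) -> ImportReport:
    """Validate and commit an annotation file (all-or-nothing).

    Every record is checked against the data-model invariants before any
    commit: documents must exist, spans must be in bounds with
    ``surface`` equal to the text slice, concepts must be registered (or
    auto-registered when full records are embedded, as in BioC), labels
    must belong to the collection's label set.  Duplicates (by identity
    key) are skipped and counted.
    """
    if fmt == "json":
        records = _parse_json(data)
    elif fmt == "csv":
        records = _parse_csv(data)
    elif fmt == "bioc":
        records = _parse_bioc(data, collection)
    else:
        raise AnnotationError(f"unknown import format {fmt!r}")

    # ---- validation pass (nothing committed on failure) ----
    for i, r in enumerate(records[TYPE_MENTION]):
        doc = collection.documents.get(r["document"])
        if doc is None:
            raise ImportError_(
                f"mention {r['id']!r}: unknown document {r['document']!r}")
        section = doc.section(r["section"])
        if not (0 <= r["start"] < r["end"] <= len(section.text)):
            raise ImportError_(
                f"mention {r['id']!r} (record {i + 1}): span "
                f"({r['start']}, {r['end']}) out of bounds")
        if section.text[r["start"]:r["end"]] != r["surface"]:
            raise ImportError_(
                f"mention {r['id']!r} (record {i + 1}): surface does not "
                f"match the document text slice")
        for cid in r["concepts"]:
            if cid not in collection.registry:
                raise ImportError_(
                    f"mention {r['id']!r}: unknown concept {cid!r}")
    for r in records[TYPE_RELATIONSHIP]:
        doc = collection.documents.get(r["document"])
        if doc is None:
            raise ImportError_(
                f"relationship {r['id']!r}: unknown document "
                f"{r['document']!r}")
        kinds = [r[role]["kind"]
                 for role in ("subject", "predicate", "object")]
        if "mention" not in kinds:
            raise ImportError_(
                f"relationship {r['id']!r}: no mention component")
        for role in ("subject", "object"):
            if r[role]["kind"] == "text":
                raise ImportError_(
                    f"relationship {r['id']!r}: free text in role {role}")
        for role in ("subject", "predicate", "object"):
            c = r[role]
            if c["kind"] == "concept" \
                    and c["concept"] not in collection.registry:
                raise ImportError_(
                    f"relationship {r['id']!r}: unknown concept "
                    f"{c['concept']!r}")
            if c["kind"] == "mention":
                section = doc.section(c["section"])
                if not (0 <= c["start"] < c["end"] <= len(section.text)):
                    raise ImportError_(
                        f"relationship {r['id']!r}: {role} span out of "
                        f"bounds")
    for r in records[TYPE_ASSERTION]:
        if r["document"] not in collection.documents:
            raise ImportError_(
                f"assertion {r['id']!r}: unknown document "
                f"{r['document']!r}")
        for role in ("subject", "predicate", "object"):
            if r[role] not in collection.registry:
                raise ImportError_(
                    f"assertion {r['id']!r}: unknown concept {r[role]!r}")
    for r in records[TYPE_LABEL]:
        if r["document"] not in collection.documents:
            raise ImportError_(
                f"label {r['id']!r}: unknown document {r['document']!r}")
        if r["label"] not in collection.labels:
            raise ImportError_(
                f"label {r['id']!r}: label {r['label']!r} not in the "
                f"collection's label set")

    # ---- commit ----
    report = ImportReport()
    rnd = collection.round(round_index)

    def target(annotator: str, doc_id: str) -> AnnotationSet:
        collection.member_ids.add(annotator)
        rnd.member_ids.add(annotator)
        return collection.annotation_set(annotator, doc_id,
                                         rnd.round_index, create=True)

    used_ids = {aid for aset in rnd.sets.values()
                for aid in aset.all_ids()}

    def claim_id(wanted: str, prefix: str) -> str:
        aid = wanted if wanted and wanted not in used_ids \
            else collection._new_id(prefix)
        while aid in used_ids:
            aid = collection._new_id(prefix)
        used_ids.add(aid)
        return aid

    for r in records[TYPE_MENTION]:
        aset = target(r["annotator"], r["document"])
        by_span = {m.span.key: m for m in aset.mentions.values()}
        span_key = (r["section"], r["start"], r["end"])
        existing = by_span.get(span_key)
        if existing is not None:
            report.skipped_duplicates += 1
            for cid in r["concepts"]:
                if cid not in existing.linked_concepts:
                    existing.linked_concepts.append(cid)
                    report.concept_links_added += 1
            continue
        mid = claim_id(r["id"], "m")
        span = Span(r["section"], r["start"], r["end"], r["surface"])
        aset.mentions[mid] = Mention(mid, r["document"], r["annotator"],
                                     span, list(r["concepts"]))
        aset.created[mid] = r["created"] or collection.clock()
        report.added[TYPE_MENTION] += 1

    for r in records[TYPE_RELATIONSHIP]:
        aset = target(r["annotator"], r["document"])
        by_span = {m.span.key: m for m in aset.mentions.values()}

        def resolve(c: dict) -> RelComponent:
            if c["kind"] == "concept":
                return RelComponent("concept", c["concept"])
            if c["kind"] == "text":
                return RelComponent("text", c["text"])
            span_key = (c["section"], c["start"], c["end"])
            m = by_span.get(span_key)
            if m is None:
                # component mention not in the file's mention list:
                # materialize it from the embedded span (closure import)
                doc = collection.documents[r["document"]]
                text = doc.section(c["section"]).text
                mid = claim_id(c.get("mention_id", ""), "m")
                m = Mention(mid, r["document"], r["annotator"],
                            Span(c["section"], c["start"], c["end"],
                                 text[c["start"]:c["end"]]))
                aset.mentions[mid] = m
                aset.created[mid] = r["created"] or collection.clock()
                by_span[span_key] = m
                report.added[TYPE_MENTION] += 1
            return RelComponent("mention", m.mention_id)

        rel = Relationship(claim_id(r["id"], "r"), r["annotator"],
                           r["document"], resolve(r["subject"]),
                           resolve(r["predicate"]), resolve(r["object"]))
        key = relationship_key(rel, aset)
        if any(relationship_key(x, aset) == key
               for x in aset.relationships.values()):
            report.skipped_duplicates += 1
            used_ids.discard(rel.relationship_id)
            continue
        aset.relationships[rel.relationship_id] = rel
        aset.created[rel.relationship_id] = r["created"] \
            or collection.clock()
        report.added[TYPE_RELATIONSHIP] += 1

    for r in records[TYPE_ASSERTION]:
        aset = target(r["annotator"], r["document"])
        if any((a.subject, a.predicate, a.object) ==
               (r["subject"], r["predicate"], r["object"])
               for a in aset.assertions.values()):
            report.skipped_duplicates += 1
            continue
        aid = claim_id(r["id"], "a")
        aset.assertions[aid] = Assertion(aid, r["annotator"],
                                         r["document"], r["subject"],
                                         r["predicate"], r["object"])
        aset.created[aid] = r["created"] or collection.clock()
        report.added[TYPE_ASSERTION] += 1

    for r in records[TYPE_LABEL]:
        aset = target(r["annotator"], r["document"])
        if any(la.label == r["label"] for la in aset.labels.values()):
            report.skipped_duplicates += 1
            continue
        lid = claim_id(r["id"], "l")
        aset.labels[lid] = LabelAnnotation(lid, r["annotator"],
                                           r["document"], r["label"])
        aset.created[lid] = r["created"] or collection.clock()
        report.added[TYPE_LABEL] += 1

    return report


# --------------------------------------------------------------------------
# round-trip check
# --------------------------------------------------------------------------

def roundtrip_check(collection: Collection, fmt: str,
                    round_index: Optional[int] = None
                    ) -> tuple[bool, str]:
    """Export the current state, import it into a fresh store with the
    same documents and registry, re-export, and compare canonical
    serializations; returns (equal, unified diff on failure)."""
    request = ExportRequest(fmt=fmt, round_index=round_index)
    blob = export_annotations(collection, request)
    fresh = Collection(collection.collection_id, collection.name,
                       collection.description, collection.creator_id,
                       labels=collection.labels,
                       clock=collection.clock)
    for concept in collection.registry.values():
        fresh.register_concept(concept)
    for doc in collection.documents.values():
        fresh.add_document(Document(doc.document_id, list(doc.sections),
                                    dict(doc.metadata)))
    import_annotations(blob, fmt, fresh)
    canon_request = ExportRequest(fmt="json")
    first = export_annotations(collection,
                               ExportRequest(fmt="json",
                                             round_index=round_index))
    second = export_annotations(fresh, canon_request)
    if first == second:
        return True, ""
    diff = "\n".join(difflib.unified_diff(
        first.decode("utf-8").splitlines(),
        second.decode("utf-8").splitlines(),
        "original", "reimported", lineterm=""))
    return False, diff


# --------------------------------------------------------------------------
# directory-per-collection store
# --------------------------------------------------------------------------

def _safe_name(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def save_collection(collection: Collection, root: Union[str, Path]) -> Path:
    """Write the collection to ``root/<collection_id>/`` (metadata,
    registry, documents, one annotation file per annotator/document/
    round)."""
    base = Path(root) / _safe_name(collection.collection_id)
    base.mkdir(parents=True, exist_ok=True)
    meta = {
        "collection_id": collection.collection_id,
        "name": collection.name,
        "description": collection.description,
        "creator_id": collection.creator_id,
        "member_ids": sorted(collection.member_ids),
        "labels": sorted(collection.labels),
        "rounds": [{"round_index": r.round_index,
                    "member_ids": sorted(r.member_ids),
                    "source_round": r.source_round}
                   for r in collection.rounds],
        "next_id": next(collection._id_counter),
    }
    (base / "collection.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n", encoding="utf-8")
    concepts = [{"identifier": c.identifier, "name": c.name,
                 "type": c.concept_type, "description": c.description}
                for c in sorted(collection.registry.values(),
                                key=lambda c: c.identifier)]
    (base / "concepts.json").write_text(
        json.dumps(concepts, sort_keys=True, indent=1) + "\n",
        encoding="utf-8")
    docs_dir = base / "documents"
    docs_dir.mkdir(exist_ok=True)
    for doc in collection.documents.values():
        payload = {"document_id": doc.document_id,
                   "sections": [{"name": s.name, "text": s.text}
                                for s in doc.sections],
                   "metadata": doc.metadata}
        (docs_dir / f"{_safe_name(doc.document_id)}.json").write_text(
            json.dumps(payload, sort_keys=True, ensure_ascii=False,
                       indent=1) + "\n", encoding="utf-8")
    for rnd in collection.rounds:
        for (ann, doc_id), aset in sorted(rnd.sets.items()):
            out_dir = base / "annotations" / f"round-{rnd.round_index}" \
                / _safe_name(ann)
            out_dir.mkdir(parents=True, exist_ok=True)
            blob = export_annotations(collection, ExportRequest(
                fmt="json", annotator_id=ann, document_id=doc_id,
                round_index=rnd.round_index))
            (out_dir / f"{_safe_name(doc_id)}.json").write_bytes(blob)
    return base


def load_collection(path: Union[str, Path],
                    clock=None) -> Collection:
    """Read a collection directory back; every annotation file is passed
    through the same validation as an ordinary import (span/surface
    consistency is re-validated on load)."""
    base = Path(path)
    meta = json.loads((base / "collection.json").read_text("utf-8"))
    kwargs = {"clock": clock} if clock is not None else {}
    collection = Collection(meta["collection_id"], meta["name"],
                            meta["description"], meta["creator_id"],
                            member_ids=meta["member_ids"],
                            labels=meta["labels"], **kwargs)
    for rec in json.loads((base / "concepts.json").read_text("utf-8")):
        collection.register_concept(Concept(
            rec["identifier"], rec["name"], rec["type"],
            rec.get("description")))
    for doc_file in sorted((base / "documents").glob("*.json")):
        payload = json.loads(doc_file.read_text("utf-8"))
        collection.add_document(Document(
            payload["document_id"],
            [Section(s["name"], s["text"]) for s in payload["sections"]],
            payload.get("metadata", {})))
    rounds_meta = meta["rounds"]
    collection.rounds[0].member_ids = set(rounds_meta[0]["member_ids"])
    for r_meta in rounds_meta[1:]:
        from .model import Round
        collection.rounds.append(Round(r_meta["round_index"],
                                       set(r_meta["member_ids"]),
                                       r_meta["source_round"]))
    ann_root = base / "annotations"
    if ann_root.is_dir():
        for rnd in collection.rounds:
            round_dir = ann_root / f"round-{rnd.round_index}"
            if not round_dir.is_dir():
                continue
            for blob_path in sorted(round_dir.glob("*/*.json")):
                import_annotations(blob_path.read_bytes(), "json",
                                   collection, rnd.round_index)
    import itertools as _it
    collection._id_counter = _it.count(meta.get("next_id", 1))
    collection.validate()
    return collection
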
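"""Stand-off annotation data model.

Documents, collections, annotation rounds, an ontology-agnostic concept
registry, and the five annotation types — mentions, concept links,
relationships, assertions, document labels — together with their mutation
and collaborative operations.

Conventions
-----------
* Character offsets are 0-based, half-open ``[start, end)``, computed per
  section over the text exactly as ingested (no Unicode normalisation).
* Mentions are contiguous spans; overlap between mentions (of the same or
  of different annotators) is permitted.
* A relationship is a subject–predicate–object triple mixing mention and
  concept components, with at least one mention; the predicate may also be
  free text.  An assertion is a pure-concept triple at document level.
* Each annotator owns their annotations; only the owner may modify or
  delete them.  Deleting a mention cascades to relationships that
  reference it, and the cascade is reported, never silent.
* Every annotation has an *identity key* (offsets + concept ids, not
  database ids); identity keys drive duplicate-skipping on copy,
  consensus counting, diffing and import deduplication.
"""

from __future__ import annotations

import copy as _copy
import itertools
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Iterable, Iterator, Optional, Sequence


# --------------------------------------------------------------------------
# errors and small helpers
# --------------------------------------------------------------------------

class AnnotationError(Exception):
    """Domain-rule violation (invalid span, unknown id, ownership, ...)."""


class NotFoundError(AnnotationError):
    """A referenced entity (document, concept, annotation) does not exist."""


class OwnershipError(AnnotationError):
    """Attempt to modify an annotation owned by another annotator."""


def utc_now() -> str:
    """Current UTC time as an ISO-8601 string (second resolution)."""
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


ROLE_SUBJECT = "subject"
ROLE_PREDICATE = "predicate"
ROLE_OBJECT = "object"
ROLES = (ROLE_SUBJECT, ROLE_PREDICATE, ROLE_OBJECT)

#: annotation-type names used throughout agreement / stats / export
TYPE_MENTION = "mention"
TYPE_CONCEPT = "concept"          # concept links on mentions
TYPE_RELATIONSHIP = "relationship"
TYPE_ASSERTION = "assertion"
TYPE_LABEL = "label"
ANNOTATION_TYPES = (TYPE_MENTION, TYPE_CONCEPT, TYPE_RELATIONSHIP,
                    TYPE_ASSERTION, TYPE_LABEL)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Concept:
    """Registry entry: a concept identified by a URI (or ID), a display
    name and a type; concepts need not come from a single ontology."""

    identifier: str
    name: str
    concept_type: str
    description: Optional[str] = None

    def __post_init__(self) -> None:
        for fld in ("identifier", "name", "concept_type"):
            if not getattr(self, fld):
                raise AnnotationError(f"concept {fld} must be non-empty")

    def same_record(self, other: "Concept") -> bool:
        return (self.identifier, self.name, self.concept_type,
                self.description or "") == (
            other.identifier, other.name, other.concept_type,
            other.description or "")


@dataclass(frozen=True)
class Section:
    name: str
    text: str


@dataclass
class Document:
    """A document is an ordered list of named sections of immutable text."""

    document_id: str
    sections: list[Section]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.document_id:
            raise AnnotationError("document_id must be non-empty")
        names = [s.name for s in self.sections]
        if len(names) != len(set(names)):
            raise AnnotationError(
                f"duplicate section names in document {self.document_id!r}")

    def section(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise NotFoundError(
            f"document {self.document_id!r} has no section {name!r}")

    @property
    def section_names(self) -> list[str]:
        return [s.name for s in self.sections]


@dataclass(frozen=True)
class Span:
    """Contiguous character span in one section; ``surface`` always equals
    the section text slice ``[start, end)``."""

    section_name: str
    start: int
    end: int
    surface: str

    @property
    def key(self) -> tuple:
        return (self.section_name, self.start, self.end)


@dataclass
class Mention:
    mention_id: str
    document_id: str
    annotator_id: str
    span: Span
    linked_concepts: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        """Identity key: (document, section, start, end)."""
        return (self.document_id,) + self.span.key


@dataclass(frozen=True)
class RelComponent:
    """One relationship component.  ``kind`` is 'mention' (ref = mention
    id), 'concept' (ref = concept identifier) or 'text' (free-text
    predicate)."""

    kind: str
    ref: str

    def __post_init__(self) -> None:
        if self.kind not in ("mention", "concept", "text"):
            raise AnnotationError(f"unknown component kind {self.kind!r}")


def mention_ref(mention_id: str) -> RelComponent:
    return RelComponent("mention", mention_id)


def concept_ref(identifier: str) -> RelComponent:
    return RelComponent("concept", identifier)


def text_predicate(text: str) -> RelComponent:
    return RelComponent("text", text)


@dataclass
class Relationship:
    relationship_id: str
    annotator_id: str
    document_id: str
    subject: RelComponent
    predicate: RelComponent
    object: RelComponent

    def components(self) -> dict[str, RelComponent]:
        return {ROLE_SUBJECT: self.subject, ROLE_PREDICATE: self.predicate,
                ROLE_OBJECT: self.object}


@dataclass
class Assertion:
    """Document-level subject–predicate–object triple of pure concepts,
    unbound to any span."""

    assertion_id: str
    annotator_id: str
    document_id: str
    subject: str
    predicate: str
    object: str

    @property
    def key(self) -> tuple:
        return (self.document_id, self.subject, self.predicate, self.object)


@dataclass
class LabelAnnotation:
    label_id: str
    annotator_id: str
    document_id: str
    label: str

    @property
    def key(self) -> tuple:
        return (self.document_id, self.label)


@dataclass
class AnnotationSet:
    """All annotations of one (annotator, document, round)."""

    annotator_id: str
    document_id: str
    round_index: int
    mentions: dict[str, Mention] = field(default_factory=dict)
    relationships: dict[str, Relationship] = field(default_factory=dict)
    assertions: dict[str, Assertion] = field(default_factory=dict)
    labels: dict[str, LabelAnnotation] = field(default_factory=dict)
    created: dict[str, str] = field(default_factory=dict)  # ann id -> ISO ts

    def is_empty(self) -> bool:
        return not (self.mentions or self.relationships
                    or self.assertions or self.labels)

    def all_ids(self) -> set[str]:
        return (set(self.mentions) | set(self.relationships)
                | set(self.assertions) | set(self.labels))


@dataclass
class Round:
    round_index: int
    member_ids: set[str]
    source_round: Optional[int] = None
    # (annotator_id, document_id) -> AnnotationSet
    sets: dict[tuple[str, str], AnnotationSet] = field(default_factory=dict)

    def sets_for_document(self, document_id: str) -> list[AnnotationSet]:
        return [s for (a, d), s in sorted(self.sets.items())
                if d == document_id]

    def sets_for_annotator(self, annotator_id: str) -> list[AnnotationSet]:
        return [s for (a, d), s in sorted(self.sets.items())
                if a == annotator_id]


@dataclass
class DeletionReport:
    """What a deletion removed, including cascades (never silent)."""

    deleted_mentions: list[str] = field(default_factory=list)
    deleted_relationships: list[str] = field(default_factory=list)
    deleted_assertions: list[str] = field(default_factory=list)
    deleted_labels: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (len(self.deleted_mentions) + len(self.deleted_relationships)
                + len(self.deleted_assertions) + len(self.deleted_labels))


# --------------------------------------------------------------------------
# identity keys
# --------------------------------------------------------------------------

def normalize_predicate_text(text: str) -> str:
    """Free-text predicates are trimmed + case-folded for identity."""
    return text.strip().casefold()


def component_key(comp: RelComponent, aset: AnnotationSet) -> tuple:
    """Identity key of one relationship component: concept id, mention
    span key, or normalised free text."""
    if comp.kind == "concept":
        return ("concept", comp.ref)
    if comp.kind == "text":
        return ("text", normalize_predicate_text(comp.ref))
    mention = aset.mentions.get(comp.ref)
    if mention is None:
        raise NotFoundError(f"dangling mention reference {comp.ref!r}")
    return ("mention",) + mention.key


def relationship_key(rel: Relationship, aset: AnnotationSet) -> tuple:
    return (component_key(rel.subject, aset),
            component_key(rel.predicate, aset),
            component_key(rel.object, aset))


def identity_key(ann, aset: AnnotationSet) -> tuple:
    """Identity key of any annotation object within its set."""
    if isinstance(ann, Mention):
        return ("mention",) + ann.key
    if isinstance(ann, Relationship):
        return ("relationship",) + relationship_key(ann, aset)
    if isinstance(ann, Assertion):
        return ("assertion",) + ann.key
    if isinstance(ann, LabelAnnotation):
        return ("label",) + ann.key
    raise TypeError(f"not an annotation: {ann!r}")


def link_keys(mention: Mention) -> list[tuple]:
    """Identity keys of a mention's concept links (mention key + id)."""
    return [mention.key + (cid,) for cid in mention.linked_concepts]


# --------------------------------------------------------------------------
# collection
# --------------------------------------------------------------------------

class Collection:
    """A collection of documents with members, labels, a concept registry
    and an ordered list of annotation rounds.

    All mutation operations live here.  ``round_index`` arguments default
    to the current (last) round.
    """

    def __init__(self, collection_id: str, name: str, description: str,
                 creator_id: str, member_ids: Iterable[str] = (),
                 labels: Iterable[str] = (),
                 clock: Callable[[], str] = utc_now) -> None:
        if not name or not description:
            raise AnnotationError(
                "collection name and description are mandatory at creation")
        self.collection_id = collection_id
        self.name = name
        self.description = description
        self.creator_id = creator_id
        self.member_ids: set[str] = set(member_ids) | {creator_id}
        self.labels: set[str] = set(labels)
        self.registry: dict[str, Concept] = {}
        self.documents: dict[str, Document] = {}
        self.rounds: list[Round] = [Round(1, set(self.member_ids))]
        self.clock = clock
        self._id_counter = itertools.count(1)

    # -- administration ----------------------------------------------------

    def _require_creator(self, caller: str, action: str) -> None:
        if caller != self.creator_id:
            raise OwnershipError(
                f"only the collection creator may {action}")

    def add_member(self, caller: str, member_id: str) -> None:
        self._require_creator(caller, "add members")
        self.member_ids.add(member_id)
        self.current_round.member_ids.add(member_id)

    def add_label(self, caller: str, label: str) -> None:
        self._require_creator(caller, "edit the label set")
        if not label:
            raise AnnotationError("label must be non-empty")
        self.labels.add(label)

    def register_concept(self, concept: Concept) -> Concept:
        """Idempotent for identical records; conflicting re-registration
        is an error."""
        existing = self.registry.get(concept.identifier)
        if existing is not None:
            if existing.same_record(concept):
                return existing
            raise AnnotationError(
                f"concept {concept.identifier!r} already registered "
                f"with a conflicting record")
        self.registry[concept.identifier] = concept
        return concept

    def add_document(self, document: Document) -> Document:
        if document.document_id in self.documents:
            raise AnnotationError(
                f"duplicate document id {document.document_id!r}")
        self.documents[document.document_id] = document
        return document

    def delete_document(self, caller: str, document_id: str) -> None:
        self._require_creator(caller, "delete documents")
        self._document(document_id)
        del self.documents[document_id]
        for rnd in self.rounds:
            for key in [k for k in rnd.sets if k[1] == document_id]:
                del rnd.sets[key]

    # -- lookup ------------------------------------------------------------

    @property
    def current_round(self) -> Round:
        return self.rounds[-1]

    def round(self, round_index: Optional[int] = None) -> Round:
        if round_index is None:
            return self.current_round
        for rnd in self.rounds:
            if rnd.round_index == round_index:
                return rnd
        raise NotFoundError(f"no round {round_index}")

    def _document(self, document_id: str) -> Document:
        doc = self.documents.get(document_id)
        if doc is None:
            raise NotFoundError(f"unknown document {document_id!r}")
        return doc

    def _require_member(self, annotator_id: str) -> None:
        if annotator_id not in self.member_ids:
            raise AnnotationError(
                f"annotator {annotator_id!r} is not a collection member")

    def annotation_set(self, annotator_id: str, document_id: str,
                       round_index: Optional[int] = None,
                       create: bool = False) -> AnnotationSet:
        rnd = self.round(round_index)
        key = (annotator_id, document_id)
        aset = rnd.sets.get(key)
        if aset is None:
            aset = AnnotationSet(annotator_id, document_id, rnd.round_index)
            if create:
                rnd.sets[key] = aset
        return aset

    def _new_id(self, prefix: str) -> str:
        return f"{prefix}{next(self._id_counter)}"

    def _find_annotation(self, annotation_id: str,
                         round_index: Optional[int] = None):
        rnd = self.round(round_index)
        for aset in rnd.sets.values():
            for pool in (aset.mentions, aset.relationships,
                         aset.assertions, aset.labels):
                if annotation_id in pool:
                    return aset, pool[annotation_id]
        raise NotFoundError(f"unknown annotation id {annotation_id!r}")

    # -- mention annotation ------------------------------------------------

    def create_mention(self, annotator_id: str, document_id: str,
                       section_name: str, start: int, end: int,
                       round_index: Optional[int] = None) -> Mention:
        """Create a stand-off mention over [start, end) of a section.

        Overlap with existing mentions (own or teammates') is permitted;
        the surface string is always recomputed from the section text.
        """
        self._require_member(annotator_id)
        doc = self._document(document_id)
        section = doc.section(section_name)
        if not section.text:
            raise AnnotationError(
                f"section {section_name!r} is empty; annotation disabled")
        if start >= end:
            raise AnnotationError(
                f"invalid span: start {start} >= end {end}")
        if start < 0 or end > len(section.text):
            raise AnnotationError(
                f"span ({start}, {end}) out of bounds for section "
                f"{section_name!r} of length {len(section.text)}")
        span = Span(section_name, start, end, section.text[start:end])
        mention = Mention(self._new_id("m"), document_id, annotator_id, span)
        aset = self.annotation_set(annotator_id, document_id,
                                   round_index, create=True)
        aset.mentions[mention.mention_id] = mention
        aset.created[mention.mention_id] = self.clock()
        return mention

    def annotate_all_occurrences(
            self, annotator_id: str, document_id: str, surface: str,
            template_concepts: Sequence[str] = (),
            case_insensitive: bool = False,
            round_index: Optional[int] = None) -> list[Mention]:
        """Annotate every occurrence of ``surface`` across all sections.

        Matching is exact-substring, left to right, non-overlapping (the
        scan resumes at the end of each match); a case-insensitive flag is
        available.  Occurrences the annotator already annotated with an
        identical (span, concept-set) are skipped, not duplicated.
        """
        if not surface:
            raise AnnotationError("surface must be non-empty")
        for cid in template_concepts:
            if cid not in self.registry:
                raise NotFoundError(f"unknown concept {cid!r}")
        doc = self._document(document_id)
        aset = self.annotation_set(annotator_id, document_id,
                                   round_index, create=True)
        existing = {
            (m.span.key, frozenset(m.linked_concepts))
            for m in aset.mentions.values()}
        created: list[Mention] = []
        needle = surface.casefold() if case_insensitive else surface
        for section in doc.sections:
            hay = section.text.casefold() if case_insensitive else section.text
            pos = hay.find(needle)
            while pos != -1:
                span_key = (section.name, pos, pos + len(surface))
                if (span_key, frozenset(template_concepts)) not in existing:
                    m = self.create_mention(
                        annotator_id, document_id, section.name,
                        pos, pos + len(surface), round_index)
                    for cid in template_concepts:
                        self.link_concept(annotator_id, m.mention_id, cid,
                                          round_index=round_index)
                    created.append(m)
                pos = hay.find(needle, pos + len(needle))
        return created

    def link_concept(self, annotator_id: str, mention_id: str,
                     concept_identifier: str,
                     register_if_new: Optional[Concept] = None,
                     round_index: Optional[int] = None) -> Mention:
        """Link a concept to a mention; a mention can have more than one
        linked concept.  Re-linking the same concept is an idempotent
        no-op.  An unknown concept may be registered on the fly via
        ``register_if_new``."""
        aset, ann = self._find_annotation(mention_id, round_index)
        if not isinstance(ann, Mention):
            raise AnnotationError(f"{mention_id!r} is not a mention")
        if ann.annotator_id != annotator_id:
            raise OwnershipError(
                "annotators may link concepts only on their own mentions")
        if concept_identifier not in self.registry:
            if register_if_new is None:
                raise NotFoundError(
                    f"unknown concept {concept_identifier!r} "
                    f"(no register_if_new record supplied)")
            if register_if_new.identifier != concept_identifier:
                raise AnnotationError(
                    "register_if_new identifier does not match")
            self.register_concept(register_if_new)
        if concept_identifier not in ann.linked_concepts:
            ann.linked_concepts.append(concept_identifier)
        return ann

    # -- relationships and assertions ---------------------------------------

    def create_relationship(self, annotator_id: str, document_id: str,
                            subject: RelComponent, predicate: RelComponent,
                            object: RelComponent,
                            round_index: Optional[int] = None
                            ) -> Relationship:
        """Store a subject–predicate–object relationship.

        At least one component must be a mention; free text is allowed
        only in the predicate role; mention components must belong to the
        same (annotator, document).
        """
        self._require_member(annotator_id)
        self._document(document_id)
        comps = {ROLE_SUBJECT: subject, ROLE_PREDICATE: predicate,
                 ROLE_OBJECT: object}
        if not any(c.kind == "mention" for c in comps.values()):
            raise AnnotationError(
                "at least one relationship component must be a mention")
        for role in (ROLE_SUBJECT, ROLE_OBJECT):
            if comps[role].kind == "text":
                raise AnnotationError(
                    f"free-text payload is allowed only in the predicate "
                    f"role, not {role}")
        aset = self.annotation_set(annotator_id, document_id,
                                   round_index, create=True)
        mention_refs = [c.ref for c in comps.values() if c.kind == "mention"]
        for mid in mention_refs:
            m = aset.mentions.get(mid)
            if m is None:
                raise NotFoundError(
                    f"mention {mid!r} does not belong to annotator "
                    f"{annotator_id!r} on document {document_id!r}")
        if len(mention_refs) > len(set(mention_refs)):
            warnings.warn("relationship uses the same mention in two roles "
                          "(self-relation)", stacklevel=2)
        for comp in comps.values():
            if comp.kind == "concept" and comp.ref not in self.registry:
                raise NotFoundError(f"unknown concept {comp.ref!r}")
        rel = Relationship(self._new_id("r"), annotator_id, document_id,
                           subject, predicate, object)
        aset.relationships[rel.relationship_id] = rel
        aset.created[rel.relationship_id] = self.clock()
        return rel

    def change_role(self, annotator_id: str, relationship_id: str,
                    role_a: str, role_b: str,
                    round_index: Optional[int] = None) -> Relationship:
        """Swap two component roles of a relationship (e.g. a mention that
        was the subject becomes the object)."""
        aset, rel = self._find_annotation(relationship_id, round_index)
        if not isinstance(rel, Relationship):
            raise AnnotationError(f"{relationship_id!r} is not a relationship")
        if rel.annotator_id != annotator_id:
            raise OwnershipError("cannot edit another annotator's annotation")
        if role_a not in ROLES or role_b not in ROLES:
            raise AnnotationError(f"unknown role in swap ({role_a}, {role_b})")
        comps = rel.components()
        comps[role_a], comps[role_b] = comps[role_b], comps[role_a]
        for role in (ROLE_SUBJECT, ROLE_OBJECT):
            if comps[role].kind == "text":
                raise AnnotationError(
                    "swap would place free text outside the predicate role")
        rel.subject = comps[ROLE_SUBJECT]
        rel.predicate = comps[ROLE_PREDICATE]
        rel.object = comps[ROLE_OBJECT]
        return rel

    def create_assertion(self, annotator_id: str, document_id: str,
                         subject_concept: str, predicate_concept: str,
                         object_concept: str,
                         round_index: Optional[int] = None) -> Assertion:
        """Store a document-level concept triple.  A duplicate identical
        assertion by the same annotator is an idempotent no-op (the
        existing assertion is returned)."""
        self._require_member(annotator_id)
        self._document(document_id)
        for cid in (subject_concept, predicate_concept, object_concept):
            if not cid:
                raise AnnotationError("assertion component missing")
            if cid not in self.registry:
                raise NotFoundError(f"unknown concept {cid!r}")
        aset = self.annotation_set(annotator_id, document_id,
                                   round_index, create=True)
        for existing in aset.assertions.values():
            if (existing.subject, existing.predicate, existing.object) == (
                    subject_concept, predicate_concept, object_concept):
                return existing
        a = Assertion(self._new_id("a"), annotator_id, document_id,
                      subject_concept, predicate_concept, object_concept)
        aset.assertions[a.assertion_id] = a
        aset.created[a.assertion_id] = self.clock()
        return a

    # -- labels --------------------------------------------------------------

    def set_labels(self, annotator_id: str, document_id: str,
                   labels: Iterable[str],
                   round_index: Optional[int] = None) -> list[LabelAnnotation]:
        """Replace the annotator's label set on a document
        (select/deselect semantics; the empty set deselects all)."""
        self._require_member(annotator_id)
        self._document(document_id)
        wanted = set(labels)
        outside = wanted - self.labels
        if outside:
            raise AnnotationError(
                f"labels not in the collection's label set: "
                f"{sorted(outside)}")
        aset = self.annotation_set(annotator_id, document_id,
                                   round_index, create=True)
        current = {la.label: lid for lid, la in aset.labels.items()}
        for label, lid in current.items():
            if label not in wanted:
                del aset.labels[lid]
                aset.created.pop(lid, None)
        for label in sorted(wanted - set(current)):
            la = LabelAnnotation(self._new_id("l"), annotator_id,
                                 document_id, label)
            aset.labels[la.label_id] = la
            aset.created[la.label_id] = self.clock()
        return sorted(aset.labels.values(), key=lambda la: la.label)

    # -- deletion --------------------------------------------------------------

    def delete_annotation(self, annotator_id: str, annotation_id: str,
                          round_index: Optional[int] = None
                          ) -> DeletionReport:
        """Delete one annotation.  Deleting a mention cascades to every
        relationship referencing it; cascaded ids are reported."""
        aset, ann = self._find_annotation(annotation_id, round_index)
        if ann.annotator_id != annotator_id:
            raise OwnershipError(
                "annotators may delete only their own annotations")
        report = DeletionReport()
        if isinstance(ann, Mention):
            for rid, rel in list(aset.relationships.items()):
                refs = [c.ref for c in rel.components().values()
                        if c.kind == "mention"]
                if annotation_id in refs:
                    del aset.relationships[rid]
                    aset.created.pop(rid, None)
                    report.deleted_relationships.append(rid)
            del aset.mentions[annotation_id]
            report.deleted_mentions.append(annotation_id)
        elif isinstance(ann, Relationship):
            del aset.relationships[annotation_id]
            report.deleted_relationships.append(annotation_id)
        elif isinstance(ann, Assertion):
            del aset.assertions[annotation_id]
            report.deleted_assertions.append(annotation_id)
        elif isinstance(ann, LabelAnnotation):
            del aset.labels[annotation_id]
            report.deleted_labels.append(annotation_id)
        aset.created.pop(annotation_id, None)
        return report

    def clear_annotator_document(self, annotator_id: str, document_id: str,
                                 round_index: Optional[int] = None) -> int:
        """Remove the whole annotation set of (annotator, document);
        returns the number of annotations removed."""
        rnd = self.round(round_index)
        aset = rnd.sets.pop((annotator_id, document_id), None)
        if aset is None:
            return 0
        return len(aset.all_ids())

    # -- collaborative operations ----------------------------------------------

    def copy_annotations(self, document_id: str, from_annotator: str,
                         to_annotator: str,
                         selection: Optional[Iterable[str]] = None,
                         round_index: Optional[int] = None) -> int:
        """Deep-copy annotations from a teammate.

        Copying a relationship pulls in its component mentions (dependency
        closure).  Copies identical (by identity key) to annotations the
        target already holds are skipped; returns the number actually
        added.
        """
        self._require_member(from_annotator)
        self._require_member(to_annotator)
        self._document(document_id)
        src = self.annotation_set(from_annotator, document_id, round_index)
        dst = self.annotation_set(to_annotator, document_id,
                                  round_index, create=True)
        if selection is None:
            ids = sorted(src.all_ids())
        else:
            ids = list(selection)
            unknown = set(ids) - src.all_ids()
            if unknown:
                raise NotFoundError(
                    f"selection not in source annotator's annotations on "
                    f"{document_id!r}: {sorted(unknown)}")

        # dependency closure: relationships pull their mentions
        closure: set[str] = set()
        for aid in ids:
            closure.add(aid)
            rel = src.relationships.get(aid)
            if rel is not None:
                for comp in rel.components().values():
                    if comp.kind == "mention":
                        closure.add(comp.ref)

        dst_mention_by_span = {m.span.key: m.mention_id
                               for m in dst.mentions.values()}
        dst_rel_keys = {relationship_key(r, dst)
                        for r in dst.relationships.values()}
        dst_assert_keys = {(a.subject, a.predicate, a.object)
                           for a in dst.assertions.values()}
        dst_label_set = {la.label for la in dst.labels.values()}

        added = 0
        mention_id_map: dict[str, str] = {}
        # copy mentions first so relationships can be rewired; a mention's
        # identity is its span key — an existing same-span mention is
        # reused, with missing concept links merged in (each counted)
        for aid in sorted(closure):
            m = src.mentions.get(aid)
            if m is None:
                continue
            existing_id = dst_mention_by_span.get(m.span.key)
            if existing_id is not None:
                mention_id_map[aid] = existing_id
                target = dst.mentions[existing_id]
                for cid in m.linked_concepts:
                    if cid not in target.linked_concepts:
                        target.linked_concepts.append(cid)
                        added += 1
                continue
            new = Mention(self._new_id("m"), document_id, to_annotator,
                          m.span, list(m.linked_concepts))
            dst.mentions[new.mention_id] = new
            dst.created[new.mention_id] = self.clock()
            dst_mention_by_span[m.span.key] = new.mention_id
            mention_id_map[aid] = new.mention_id
            added += 1
        for aid in sorted(closure):
            if aid in src.relationships:
                rel = src.relationships[aid]

                def rewire(comp: RelComponent) -> RelComponent:
                    if comp.kind == "mention":
                        return RelComponent("mention", mention_id_map[comp.ref])
                    return comp

                new = Relationship(self._new_id("r"), to_annotator,
                                   document_id, rewire(rel.subject),
                                   rewire(rel.predicate), rewire(rel.object))
                if relationship_key(new, dst) in dst_rel_keys:
                    continue
                dst.relationships[new.relationship_id] = new
                dst.created[new.relationship_id] = self.clock()
                dst_rel_keys.add(relationship_key(new, dst))
                added += 1
            elif aid in src.assertions:
                a = src.assertions[aid]
                if (a.subject, a.predicate, a.object) in dst_assert_keys:
                    continue
                new_a = Assertion(self._new_id("a"), to_annotator,
                                  document_id, a.subject, a.predicate,
                                  a.object)
                dst.assertions[new_a.assertion_id] = new_a
                dst.created[new_a.assertion_id] = self.clock()
                dst_assert_keys.add((a.subject, a.predicate, a.object))
                added += 1
            elif aid in src.labels:
                la = src.labels[aid]
                if la.label in dst_label_set:
                    continue
                new_l = LabelAnnotation(self._new_id("l"), to_annotator,
                                        document_id, la.label)
                dst.labels[new_l.label_id] = new_l
                dst.created[new_l.label_id] = self.clock()
                dst_label_set.add(la.label)
                added += 1
        return added

    def suggest_concepts(self, annotator_id: str, mention_id: str,
                         round_index: Optional[int] = None
                         ) -> list[tuple[Concept, int]]:
        """Concepts other annotators linked to mentions with the identical
        span, with per-concept annotator counts, sorted by count
        descending (ties by identifier).  The caller's own links are
        excluded."""
        _, mention = self._find_annotation(mention_id, round_index)
        if not isinstance(mention, Mention):
            raise AnnotationError(f"{mention_id!r} is not a mention")
        rnd = self.round(round_index)
        counts: dict[str, set[str]] = {}
        for (ann, doc), aset in rnd.sets.items():
            if ann == annotator_id or doc != mention.document_id:
                continue
            for m in aset.mentions.values():
                if m.span.key == mention.span.key:
                    for cid in m.linked_concepts:
                        counts.setdefault(cid, set()).add(ann)
        ranked = sorted(((self.registry[cid], len(who))
                         for cid, who in counts.items()),
                        key=lambda pair: (-pair[1], pair[0].identifier))
        return ranked

    # -- rounds --------------------------------------------------------------

    def new_round(self, caller: str, member_ids: Iterable[str]) -> Round:
        """Open round r+1, duplicating the last round's annotations for
        each carried-over member.  Rounds are isolated after creation:
        later edits in either round never affect the other."""
        self._require_creator(caller, "create rounds")
        members = set(member_ids)
        if not members:
            raise AnnotationError("a round needs at least one member")
        last = self.current_round
        rnd = Round(last.round_index + 1, members,
                    source_round=last.round_index)
        for (ann, doc), aset in last.sets.items():
            if ann not in members:
                continue
            dup = _copy.deepcopy(aset)
            dup.round_index = rnd.round_index
            rnd.sets[(ann, doc)] = dup
        self.member_ids |= members
        self.rounds.append(rnd)
        return rnd

    # -- validation ------------------------------------------------------------

    def validate(self) -> None:
        """Exhaustive referential-integrity and invariant check; raises
        AnnotationError on the first violation found."""
        for rnd in self.rounds:
            for (ann, doc_id), aset in rnd.sets.items():
                doc = self._document(doc_id)
                for m in aset.mentions.values():
                    sec = doc.section(m.span.section_name)
                    if not (0 <= m.span.start < m.span.end
                            <= len(sec.text)):
                        raise AnnotationError(
                            f"mention {m.mention_id} span out of bounds")
                    if sec.text[m.span.start:m.span.end] != m.span.surface:
                        raise AnnotationError(
                            f"mention {m.mention_id} surface/text mismatch")
                    if len(m.linked_concepts) != len(set(m.linked_concepts)):
                        raise AnnotationError(
                            f"mention {m.mention_id} has duplicate links")
                    for cid in m.linked_concepts:
                        if cid not in self.registry:
                            raise AnnotationError(
                                f"mention {m.mention_id} links unregistered "
                                f"concept {cid!r}")
                for rel in aset.relationships.values():
                    comps = rel.components()
                    if not any(c.kind == "mention" for c in comps.values()):
                        raise AnnotationError(
                            f"relationship {rel.relationship_id} has no "
                            f"mention component")
                    for role, comp in comps.items():
                        if comp.kind == "mention" \
                                and comp.ref not in aset.mentions:
                            raise AnnotationError(
                                f"relationship {rel.relationship_id} "
                                f"{role} references missing mention")
                        if comp.kind == "concept" \
                                and comp.ref not in self.registry:
                            raise AnnotationError(
                                f"relationship {rel.relationship_id} "
                                f"{role} references unregistered concept")
                        if comp.kind == "text" and role != ROLE_PREDICATE:
                            raise AnnotationError(
                                f"relationship {rel.relationship_id} has "
                                f"free text in role {role}")
                for a in aset.assertions.values():
                    for cid in (a.subject, a.predicate, a.object):
                        if cid not in self.registry:
                            raise AnnotationError(
                                f"assertion {a.assertion_id} references "
                                f"unregistered concept {cid!r}")
                for la in aset.labels.values():
                    if la.label not in self.labels:
                        raise AnnotationError(
                            f"label annotation {la.label_id} uses unknown "
                            f"label {la.label!r}")

    # -- canonical serialization -------------------------------------------

    def canonical_round_state(self, round_index: int) -> str:
        """Deterministic JSON of one round's annotations (identity-level
        content, sorted), used for isolation checks and diffs."""
        rnd = self.round(round_index)
        state: dict = {}
        for (ann, doc), aset in sorted(rnd.sets.items()):
            entry = {
                "mentions": sorted(
                    [list(m.span.key) + [m.span.surface,
                                         sorted(m.linked_concepts)]
                     for m in aset.mentions.values()]),
                "relationships": sorted(
                    [[list(map(list, relationship_key(r, aset)))]
                     for r in aset.relationships.values()]),
                "assertions": sorted(
                    [[a.subject, a.predicate, a.object]
                     for a in aset.assertions.values()]),
                "labels": sorted(la.label for la in aset.labels.values()),
            }
            state[f"{ann}␟{doc}"] = entry
        return json.dumps(state, sort_keys=True, ensure_ascii=False)


def token_boundaries(text: str, start: int, end: int) -> tuple[int, int]:
    """Convenience helper: widen [start, end) to whitespace-delimited token
    boundaries (a token is a maximal run of non-space characters).  Not
    enforced by create_mention — arbitrary substrings are annotatable."""
    if not (0 <= start < end <= len(text)):
        raise AnnotationError("offsets out of bounds")
    while start > 0 and not text[start - 1].isspace():
        start -= 1
    while end < len(text) and not text[end].isspace():
        end += 1
    return start, end


def iter_annotation_sets(collection: Collection,
                         round_index: Optional[int] = None
                         ) -> Iterator[AnnotationSet]:
    rnd = collection.round(round_index)
    for key in sorted(rnd.sets):
        yield rnd.sets[key]
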
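"""Statistics panels and baseline-diff provenance.

Personal (single annotator) and global summaries, concept-type
distributions (overall and per relationship/assertion role), per-document
annotation and annotator counts with collection progress, and the
added / updated / deleted / confirmed classification of a final
annotation set against a baseline (typically the machine annotator's
output).

Diff matching rules
-------------------
Relationships and assertions are matched on their endpoint pair;
endpoints are matched by concept id when linked (else by span key for
mentions without links).  The same pair with a different predicate is an
*update*; the same pair with the same predicate is *confirmed*; pairs
only in the final set are *added*, only in the baseline *deleted*.  A
relationship whose endpoints changed counts as one deletion plus one
addition, not an update.  Concept links are matched on span key (same
concept set = confirmed, different = updated); mentions on span key
(present/absent only).  The four classes always partition the union of
baseline and final pair keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .agreement import CONSENSUS_ANNOTATOR, fleiss_for
from .model import (
    AnnotationError,
    AnnotationSet,
    Collection,
    TYPE_ASSERTION,
    TYPE_CONCEPT,
    TYPE_LABEL,
    TYPE_MENTION,
    TYPE_RELATIONSHIP,
    normalize_predicate_text,
)

#: progress-percentage presentation thresholds carried in report metadata
PROGRESS_GREEN_ABOVE = 80.0
PROGRESS_RED_BELOW = 20.0


@dataclass
class StatsReport:
    scope: str
    mode: str                      # "personal:<annotator>" | "global"
    round_index: int
    n_mentions: int
    n_concept_links: int
    n_relationships: int
    n_assertions: int
    n_labels: int
    n_annotated_documents: int
    n_annotators: Optional[int]    # omitted (None) in personal mode
    fleiss: Optional[dict] = None  # type -> kappa, global mode only

    def as_dict(self) -> dict:
        out = {
            "scope": self.scope, "mode": self.mode,
            "round": self.round_index,
            "mentions": self.n_mentions,
            "concept_links": self.n_concept_links,
            "relationships": self.n_relationships,
            "assertions": self.n_assertions,
            "labels": self.n_labels,
            "annotated_documents": self.n_annotated_documents,
        }
        if self.n_annotators is not None:
            out["annotators"] = self.n_annotators
        if self.fleiss is not None:
            out["fleiss"] = self.fleiss
        return out


@dataclass
class DistributionReport:
    concept_type_counts: dict           # linking + relationships + assertions
    link_concept_counts: dict           # (type -> {concept id -> count})
    role_type_counts: dict              # role -> {concept type -> count}
    free_text_predicates: int

    def role_total(self, role: str) -> int:
        return sum(self.role_type_counts.get(role, {}).values())


@dataclass
class DiffReport:
    annotation_type: str
    added: list = field(default_factory=list)
    updated: list = field(default_factory=list)
    deleted: list = field(default_factory=list)
    confirmed: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        return {"added": len(self.added), "updated": len(self.updated),
                "deleted": len(self.deleted),
                "confirmed": len(self.confirmed)}


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def _sets_in_scope(collection: Collection, document_id: Optional[str],
                   round_index: Optional[int],
                   annotator_id: Optional[str]) -> list[AnnotationSet]:
    rnd = collection.round(round_index)
    out = []
    for (ann, doc), aset in sorted(rnd.sets.items()):
        if ann == CONSENSUS_ANNOTATOR:
            continue
        if annotator_id is not None and ann != annotator_id:
            continue
        if document_id is not None and doc != document_id:
            continue
        out.append(aset)
    return out


def summarize(collection: Collection, document_id: Optional[str] = None,
              annotator_id: Optional[str] = None,
              round_index: Optional[int] = None,
              with_fleiss: bool = True) -> StatsReport:
    """Exact annotation counts for the scope; personal mode
    (``annotator_id`` given) omits the annotator-count panel, global mode
    attaches per-type Fleiss' kappa."""
    rnd = collection.round(round_index)
    sets = _sets_in_scope(collection, document_id, round_index,
                          annotator_id)
    n_links = sum(len(m.linked_concepts) for aset in sets
                  for m in aset.mentions.values())
    annotated_docs = {aset.document_id for aset in sets
                      if not aset.is_empty()}
    personal = annotator_id is not None
    fleiss = None
    if not personal and with_fleiss:
        fleiss = {t: fleiss_for(collection, t, document_id,
                                rnd.round_index).kappa
                  for t in (TYPE_MENTION, TYPE_CONCEPT, TYPE_RELATIONSHIP,
                            TYPE_ASSERTION, TYPE_LABEL)}
    return StatsReport(
        scope=f"document:{document_id}" if document_id else "collection",
        mode=f"personal:{annotator_id}" if personal else "global",
        round_index=rnd.round_index,
        n_mentions=sum(len(a.mentions) for a in sets),
        n_concept_links=n_links,
        n_relationships=sum(len(a.relationships) for a in sets),
        n_assertions=sum(len(a.assertions) for a in sets),
        n_labels=sum(len(a.labels) for a in sets),
        n_annotated_documents=len(annotated_docs),
        n_annotators=None if personal else len(
            {a.annotator_id for a in sets if not a.is_empty()}),
        fleiss=fleiss,
    )


def concept_distributions(collection: Collection,
                          document_id: Optional[str] = None,
                          round_index: Optional[int] = None
                          ) -> DistributionReport:
    """Concept-frequency and concept-type distribution tables.

    Free-text predicates have no concept type: they are excluded from
    the role distributions and reported in a separate counter.
    """
    sets = _sets_in_scope(collection, document_id, round_index, None)
    type_counts: dict[str, int] = {}
    link_counts: dict[str, dict[str, int]] = {}
    role_counts: dict[str, dict[str, int]] = {
        "subject": {}, "predicate": {}, "object": {}}
    free_text = 0

    def bump(table: dict, key: str) -> None:
        table[key] = table.get(key, 0) + 1

    for aset in sets:
        for m in aset.mentions.values():
            for cid in m.linked_concepts:
                c = collection.registry[cid]
                bump(type_counts, c.concept_type)
                bump(link_counts.setdefault(c.concept_type, {}), cid)
        for rel in aset.relationships.values():
            for role, comp in rel.components().items():
                if comp.kind == "text":
                    free_text += 1
                    continue
                if comp.kind == "concept":
                    ctype = collection.registry[comp.ref].concept_type
                else:
                    mention = aset.mentions[comp.ref]
                    if not mention.linked_concepts:
                        continue  # unlinked mention has no concept type
                    ctype = collection.registry[
                        mention.linked_concepts[0]].concept_type
                bump(role_counts[role], ctype)
                bump(type_counts, ctype)
        for a in aset.assertions.values():
            for role, cid in (("subject", a.subject),
                              ("predicate", a.predicate),
                              ("object", a.object)):
                ctype = collection.registry[cid].concept_type
                bump(role_counts[role], ctype)
                bump(type_counts, ctype)
    return DistributionReport(type_counts, link_counts, role_counts,
                              free_text)


def per_document_counts(collection: Collection,
                        round_index: Optional[int] = None) -> dict:
    """One row per document with per-type annotation counts, plus the
    collection's annotated-documents progress percentage."""
    rows = {}
    for doc_id in sorted(collection.documents):
        report = summarize(collection, document_id=doc_id,
                           round_index=round_index, with_fleiss=False)
        rows[doc_id] = {
            "mentions": report.n_mentions,
            "concept_links": report.n_concept_links,
            "relationships": report.n_relationships,
            "assertions": report.n_assertions,
            "labels": report.n_labels,
        }
    n_docs = len(collection.documents)
    annotated = sum(1 for r in rows.values() if any(r.values()))
    progress = 100.0 * annotated / n_docs if n_docs else 0.0
    return {"documents": rows, "progress_percent": progress,
            "progress_color": ("green" if progress > PROGRESS_GREEN_ABOVE
                               else "red" if progress < PROGRESS_RED_BELOW
                               else "neutral")}


def annotators_per_document(collection: Collection,
                            round_index: Optional[int] = None) -> dict:
    """Number of annotators (with >= 1 annotation) per document."""
    rnd = collection.round(round_index)
    out = {doc_id: 0 for doc_id in sorted(collection.documents)}
    seen: dict[str, set] = {}
    for (ann, doc), aset in rnd.sets.items():
        if ann != CONSENSUS_ANNOTATOR and not aset.is_empty():
            seen.setdefault(doc, set()).add(ann)
    for doc, who in seen.items():
        if doc in out:
            out[doc] = len(who)
    return out


# --------------------------------------------------------------------------
# baseline diff (added / updated / deleted / confirmed)
# --------------------------------------------------------------------------

def _endpoint_key(comp, aset: AnnotationSet) -> tuple:
    """Pair-matching key of a relationship endpoint: concept id when the
    component is (or is linked to) a concept, else the span key."""
    if comp.kind == "concept":
        return ("concept", comp.ref)
    mention = aset.mentions[comp.ref]
    if mention.linked_concepts:
        return ("concept-set", tuple(sorted(mention.linked_concepts)))
    return ("span",) + mention.key


def _predicate_identity(comp, aset: AnnotationSet) -> tuple:
    if comp.kind == "concept":
        return ("concept", comp.ref)
    if comp.kind == "text":
        return ("text", normalize_predicate_text(comp.ref))
    mention = aset.mentions[comp.ref]
    if mention.linked_concepts:
        return ("concept-set", tuple(sorted(mention.linked_concepts)))
    return ("span",) + mention.key


def _pairs(aset: AnnotationSet, annotation_type: str) -> dict:
    """pair key -> set of predicate identities (or per-type payload)."""
    out: dict = {}
    if annotation_type == TYPE_RELATIONSHIP:
        for rel in aset.relationships.values():
            pair = (rel.document_id, _endpoint_key(rel.subject, aset),
                    _endpoint_key(rel.object, aset))
            out.setdefault(pair, set()).add(
                _predicate_identity(rel.predicate, aset))
    elif annotation_type == TYPE_ASSERTION:
        for a in aset.assertions.values():
            pair = (a.document_id, ("concept", a.subject),
                    ("concept", a.object))
            out.setdefault(pair, set()).add(("concept", a.predicate))
    elif annotation_type == TYPE_CONCEPT:
        for m in aset.mentions.values():
            if m.linked_concepts:
                out[m.key] = set(m.linked_concepts)
    elif annotation_type == TYPE_MENTION:
        for m in aset.mentions.values():
            out[m.key] = {"PRESENT"}
    elif annotation_type == TYPE_LABEL:
        for la in aset.labels.values():
            out[la.key] = {"PRESENT"}
    else:
        raise AnnotationError(
            f"unknown annotation type {annotation_type!r}")
    return out


def _merge_pairs(sets: list[AnnotationSet], annotation_type: str) -> dict:
    merged: dict = {}
    for aset in sets:
        for pair, payload in _pairs(aset, annotation_type).items():
            merged.setdefault(pair, set()).update(payload)
    return merged


def diff_against_baseline(collection: Collection, baseline_annotator: str,
                          final_annotators: list[str] | str,
                          annotation_type: str,
                          document_id: Optional[str] = None,
                          round_index: Optional[int] = None) -> DiffReport:
    """Classify the final set against the baseline (e.g. the machine
    annotator's output).

    ``final_annotators`` may be one annotator or a list, in which case
    the union of their distinct annotations forms the final set.
    """
    if isinstance(final_annotators, str):
        final_annotators = [final_annotators]
    baseline_sets = _sets_in_scope(collection, document_id, round_index,
                                   None)
    baseline = _merge_pairs(
        [s for s in baseline_sets
         if s.annotator_id == baseline_annotator], annotation_type)
    final = _merge_pairs(
        [s for s in baseline_sets
         if s.annotator_id in final_annotators], annotation_type)
    report = DiffReport(annotation_type)
    for pair in sorted(set(baseline) | set(final), key=repr):
        in_b, in_f = pair in baseline, pair in final
        if in_b and in_f:
            if baseline[pair] == final[pair]:
                report.confirmed.append(pair)
            else:
                report.updated.append(pair)
        elif in_f:
            report.added.append(pair)
        else:
            report.deleted.append(pair)
    return report
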
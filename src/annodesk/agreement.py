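"""Inter-annotator agreement: unitization, Fleiss' and Cohen's kappa,
majority-voting consensus, and per-round agreement trajectories.

Free-form stand-off annotations are first *unitized* into a fixed
item x category rating table so that chance-corrected agreement applies:

===============  =====================================  ======================
annotation type  item                                   categories
===============  =====================================  ======================
mention          span key (doc, section, start, end)    PRESENT / ABSENT
concept link     (span key, concept id)                 PRESENT / ABSENT
relationship     (subject key, object key)              predicate identity
                                                        + ABSENT
assertion        (doc, subject id, object id)           predicate id + ABSENT
label            (document, label)                      PRESENT / ABSENT
===============  =====================================  ======================

Every annotator in scope contributes exactly one category per item, which
gives the constant rater count per item that Fleiss' kappa requires, and
makes relationship/assertion agreement measure predicate choice.  When an
annotator holds two different predicates for the same item the
lexicographically smallest predicate key is taken (deterministic).

Kappa statistics (both in [-1, 1] when defined):

* Fleiss (1971), >= 2 raters:
  ``P_i = (sum_j n_ij^2 - n) / (n (n - 1))``;  ``Pbar = mean_i P_i``;
  ``p_j = sum_i n_ij / (N n)``;  ``Pbar_e = sum_j p_j^2``;
  ``kappa = (Pbar - Pbar_e) / (1 - Pbar_e)``.
* Cohen, exactly 2 raters:
  ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the fraction of items
  rated identically and ``p_e = sum_j P_a(j) P_b(j)``.

In the degenerate case ``Pbar = Pbar_e = 1`` (every rater places every
item in the same single category) agreement is literally perfect and
kappa is defined as exactly 1.  An empty item universe yields UNDEFINED
(represented as ``None``).

Majority voting selects every annotation held by *more than half* of the
document's annotators (strict majority over annotators with at least one
annotation of any type on the document in the round); the result is
materializable as a virtual annotator that can be loaded and copied like
a teammate's set.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    ANNOTATION_TYPES,
    AnnotationError,
    AnnotationSet,
    Collection,
    Mention,
    RelComponent,
    Relationship,
    TYPE_ASSERTION,
    TYPE_CONCEPT,
    TYPE_LABEL,
    TYPE_MENTION,
    TYPE_RELATIONSHIP,
    component_key,
)

PRESENT = "PRESENT"
ABSENT = "ABSENT"

#: virtual-annotator id under which consensus annotations are materialized
CONSENSUS_ANNOTATOR = "IAA"


@dataclass
class RatingTable:
    """Item x category rater counts with a constant rater count per item."""

    items: list
    categories: list
    counts: np.ndarray  # shape (n_items, n_categories), integer
    n_raters: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.items:
            if self.counts.shape != (len(self.items), len(self.categories)):
                raise AnnotationError("rating table shape mismatch")
            if (self.counts < 0).any():
                raise AnnotationError("negative rater counts")
            row_sums = self.counts.sum(axis=1)
            if not (row_sums == self.n_raters).all():
                raise AnnotationError(
                    "every item must be rated by exactly n_raters raters")

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass
class AgreementReport:
    measure: str                 # "fleiss" | "cohen"
    annotation_type: str
    scope: str                   # "collection" | "document:<id>"
    round_index: int
    kappa: Optional[float]       # None == UNDEFINED
    n_items: int
    n_raters: int

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "annotation_type": self.annotation_type,
            "scope": self.scope,
            "round": self.round_index,
            "kappa": self.kappa,
            "n_items": self.n_items,
            "n_raters": self.n_raters,
        }


@dataclass
class ConsensusSet:
    document_id: str
    annotation_type: str
    n_annotators: int
    # (identity key, support count)
    entries: list[tuple[tuple, int]] = field(default_factory=list)


# --------------------------------------------------------------------------
# per-annotator key extraction
# --------------------------------------------------------------------------

def _pair_and_predicate_keys(aset: AnnotationSet
                             ) -> dict[tuple, tuple]:
    """(subject key, object key) -> smallest predicate key for one
    annotator's relationships."""
    out: dict[tuple, tuple] = {}
    for rel in aset.relationships.values():
        # document id is part of the item key so that collection-scope
        # pooling never collapses same-concept pairs across documents
        pair = (rel.document_id,
                component_key(rel.subject, aset),
                component_key(rel.object, aset))
        pred = component_key(rel.predicate, aset)
        if pair not in out or pred < out[pair]:
            out[pair] = pred
    return out


def _assertion_pair_keys(aset: AnnotationSet) -> dict[tuple, str]:
    out: dict[tuple, str] = {}
    for a in aset.assertions.values():
        pair = (a.document_id, a.subject, a.object)
        if pair not in out or a.predicate < out[pair]:
            out[pair] = a.predicate
    return out


def annotator_categories(sets: list[AnnotationSet], annotation_type: str
                         ) -> dict:
    """Map item key -> category for one annotator's pooled sets."""
    if annotation_type == TYPE_MENTION:
        return {m.key: PRESENT
                for aset in sets for m in aset.mentions.values()}
    if annotation_type == TYPE_CONCEPT:
        return {m.key + (cid,): PRESENT
                for aset in sets for m in aset.mentions.values()
                for cid in m.linked_concepts}
    if annotation_type == TYPE_RELATIONSHIP:
        out: dict = {}
        for aset in sets:
            for pair, pred in _pair_and_predicate_keys(aset).items():
                if pair not in out or pred < out[pair]:
                    out[pair] = pred
        return out
    if annotation_type == TYPE_ASSERTION:
        out = {}
        for aset in sets:
            for pair, pred in _assertion_pair_keys(aset).items():
                if pair not in out or pred < out[pair]:
                    out[pair] = pred
        return out
    if annotation_type == TYPE_LABEL:
        return {la.key: PRESENT
                for aset in sets for la in aset.labels.values()}
    raise AnnotationError(f"unknown annotation type {annotation_type!r}")


def unitize(sets_by_annotator: dict[str, list[AnnotationSet]],
            annotation_type: str) -> RatingTable:
    """Build the item x category rating table for >= 2 annotators.

    Items are the union of identity keys observed across annotators; an
    annotator who did not annotate an item contributes the ABSENT
    category, so every item has exactly ``n_raters`` ratings.
    """
    if len(sets_by_annotator) < 2:
        raise AnnotationError("unitization requires at least 2 annotators")
    annotators = sorted(sets_by_annotator)
    per_annotator = {a: annotator_categories(sets_by_annotator[a],
                                             annotation_type)
                     for a in annotators}
    items = sorted({k for cats in per_annotator.values() for k in cats},
                   key=repr)
    categories = sorted({c for cats in per_annotator.values()
                         for c in cats.values()}, key=repr)
    if any(len(per_annotator[a]) < len(items) for a in annotators):
        categories = sorted(set(categories) | {ABSENT}, key=repr)
    cat_index = {c: j for j, c in enumerate(categories)}
    counts = np.zeros((len(items), len(categories)), dtype=np.int64)
    for i, item in enumerate(items):
        for a in annotators:
            cat = per_annotator[a].get(item, ABSENT)
            counts[i, cat_index[cat]] += 1
    return RatingTable(items, categories, counts, len(annotators))


def filter_items(table: RatingTable, keep) -> RatingTable:
    """Restrict a rating table to the items for which ``keep(item)`` is
    true (e.g. consensus-covered items)."""
    idx = [i for i, item in enumerate(table.items) if keep(item)]
    return RatingTable([table.items[i] for i in idx], list(table.categories),
                       table.counts[idx], table.n_raters)


# --------------------------------------------------------------------------
# kappa statistics
# --------------------------------------------------------------------------

def fleiss_kappa(table: RatingTable) -> Optional[float]:
    """Fleiss' kappa of a rating table; ``None`` when undefined."""
    if table.n_items == 0:
        return None
    if table.n_raters < 2:
        raise AnnotationError("Fleiss' kappa requires >= 2 raters per item")
    counts = table.counts.astype(np.float64)
    n = float(table.n_raters)
    p_i = ((counts ** 2).sum(axis=1) - n) / (n * (n - 1.0))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (table.n_items * n)
    p_e = float((p_j ** 2).sum())
    if p_e >= 1.0:
        # all ratings in a single category: perfect by construction
        return 1.0 if p_bar >= 1.0 else None
    return (p_bar - p_e) / (1.0 - p_e)


def cohen_kappa(labels_a: list, labels_b: list) -> Optional[float]:
    """Cohen's kappa between two equal-length category sequences;
    ``None`` when undefined (empty input)."""
    if len(labels_a) != len(labels_b):
        raise AnnotationError(
            "Cohen's kappa needs equal-length rating sequences")
    n = len(labels_a)
    if n == 0:
        return None
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    if p_o == 1.0:
        return 1.0
    cats = sorted(set(labels_a) | set(labels_b))
    p_e = sum((labels_a.count(c) / n) * (labels_b.count(c) / n)
              for c in cats)
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


# --------------------------------------------------------------------------
# scope helpers
# --------------------------------------------------------------------------

def _scope_sets(collection: Collection, document_id: Optional[str],
                round_index: Optional[int],
                exclude: tuple[str, ...] = (CONSENSUS_ANNOTATOR,)
                ) -> dict[str, list[AnnotationSet]]:
    """Annotators with >= 1 annotation (any type) in scope, with their
    pooled annotation sets.  The consensus virtual annotator is excluded
    from agreement computations."""
    rnd = collection.round(round_index)
    out: dict[str, list[AnnotationSet]] = {}
    for (ann, doc), aset in sorted(rnd.sets.items()):
        if ann in exclude or aset.is_empty():
            continue
        if document_id is not None and doc != document_id:
            continue
        out.setdefault(ann, []).append(aset)
    return out


def fleiss_for(collection: Collection, annotation_type: str,
               document_id: Optional[str] = None,
               round_index: Optional[int] = None,
               exclude_annotators: tuple[str, ...] = ()) -> AgreementReport:
    """Collection- or document-scope Fleiss' kappa for one annotation
    type.  Collection scope pools items across documents (document ids
    are embedded in every item key).  ``exclude_annotators`` drops e.g.
    the machine annotator from the rater pool."""
    rnd = collection.round(round_index)
    scope = f"document:{document_id}" if document_id else "collection"
    sets = _scope_sets(collection, document_id, round_index,
                       exclude=(CONSENSUS_ANNOTATOR,)
                       + tuple(exclude_annotators))
    if len(sets) < 2:
        return AgreementReport("fleiss", annotation_type, scope,
                               rnd.round_index, None, 0, len(sets))
    table = unitize(sets, annotation_type)
    return AgreementReport("fleiss", annotation_type, scope,
                           rnd.round_index, fleiss_kappa(table),
                           table.n_items, table.n_raters)


def pairwise_cohen(collection: Collection, annotator_a: str,
                   annotator_b: str, annotation_type: str,
                   document_id: Optional[str] = None,
                   round_index: Optional[int] = None) -> AgreementReport:
    """Cohen's kappa between two annotators, unitized over the union of
    the pair's identity keys (single document or whole collection)."""
    if annotator_a == annotator_b:
        raise AnnotationError(
            "pairwise agreement needs two distinct annotators")
    rnd = collection.round(round_index)
    scope = f"document:{document_id}" if document_id else "collection"
    sets = _scope_sets(collection, document_id, round_index)
    for ann in (annotator_a, annotator_b):
        if ann not in sets:
            raise AnnotationError(
                f"annotator {ann!r} has no annotations in scope")
    pair = {a: sets[a] for a in (annotator_a, annotator_b)}
    table = unitize(pair, annotation_type)
    if table.n_items == 0:
        return AgreementReport("cohen", annotation_type, scope,
                               rnd.round_index, None, 0, 2)
    cats = {a: annotator_categories(pair[a], annotation_type)
            for a in pair}
    seq_a = [cats[annotator_a].get(item, ABSENT) for item in table.items]
    seq_b = [cats[annotator_b].get(item, ABSENT) for item in table.items]
    return AgreementReport("cohen", annotation_type, scope,
                           rnd.round_index, cohen_kappa(seq_a, seq_b),
                           table.n_items, 2)


def agreement_by_round(collection: Collection, annotation_type: str,
                       document_id: Optional[str] = None
                       ) -> list[AgreementReport]:
    """One Fleiss report per round (rounds with < 2 annotators are
    reported UNDEFINED, not dropped)."""
    return [fleiss_for(collection, annotation_type, document_id,
                       rnd.round_index)
            for rnd in collection.rounds]


# --------------------------------------------------------------------------
# majority voting
# --------------------------------------------------------------------------

def _consensus_keys(aset: AnnotationSet, annotation_type: str) -> set:
    """Full identity keys (predicate included) used for consensus
    support counting."""
    if annotation_type == TYPE_MENTION:
        return {m.key for m in aset.mentions.values()}
    if annotation_type == TYPE_CONCEPT:
        return {m.key + (cid,) for m in aset.mentions.values()
                for cid in m.linked_concepts}
    if annotation_type == TYPE_RELATIONSHIP:
        return {(component_key(r.subject, aset),
                 component_key(r.predicate, aset),
                 component_key(r.object, aset))
                for r in aset.relationships.values()}
    if annotation_type == TYPE_ASSERTION:
        return {a.key for a in aset.assertions.values()}
    if annotation_type == TYPE_LABEL:
        return {la.key for la in aset.labels.values()}
    raise AnnotationError(f"unknown annotation type {annotation_type!r}")


def majority_vote(collection: Collection, document_id: str,
                  annotation_type: str,
                  round_index: Optional[int] = None,
                  exclude_annotators: tuple[str, ...] = ()) -> ConsensusSet:
    """Annotations held by more than half of the document's annotators.

    ``n`` counts distinct annotators with at least one annotation of any
    type on the document in the round; an entry needs support strictly
    greater than ``n / 2``.
    """
    collection._document(document_id)
    sets = _scope_sets(collection, document_id, round_index,
                       exclude=(CONSENSUS_ANNOTATOR,)
                       + tuple(exclude_annotators))
    n = len(sets)
    support: dict[tuple, int] = {}
    for ann in sorted(sets):
        keys: set = set()
        for aset in sets[ann]:
            keys |= _consensus_keys(aset, annotation_type)
        for key in keys:
            support[key] = support.get(key, 0) + 1
    entries = [(key, count) for key, count in sorted(support.items())
               if count * 2 > n]
    return ConsensusSet(document_id, annotation_type, n, entries)


def consensus_annotation_set(collection: Collection, document_id: str,
                             round_index: Optional[int] = None
                             ) -> AnnotationSet:
    """Materialize the majority-voting consensus over all five annotation
    types as a virtual annotator's set (loadable / copyable like a
    teammate's annotations)."""
    rnd = collection.round(round_index)
    out = AnnotationSet(CONSENSUS_ANNOTATOR, document_id, rnd.round_index)
    sets = _scope_sets(collection, document_id, round_index)
    counter = iter(range(1, 10_000_000))

    span_to_id: dict[tuple, str] = {}

    def ensure_mention(span_key: tuple) -> str:
        # span_key = (document, section, start, end)
        if span_key in span_to_id:
            return span_to_id[span_key]
        for ann in sorted(sets):
            for aset in sets[ann]:
                for m in aset.mentions.values():
                    if m.key == span_key:
                        new = Mention(f"c{next(counter)}", document_id,
                                      CONSENSUS_ANNOTATOR, m.span, [])
                        out.mentions[new.mention_id] = new
                        span_to_id[span_key] = new.mention_id
                        return new.mention_id
        raise AnnotationError(f"no holder found for span {span_key!r}")

    for key, _cnt in majority_vote(collection, document_id, TYPE_MENTION,
                                   round_index).entries:
        ensure_mention(key)
    for key, _cnt in majority_vote(collection, document_id, TYPE_CONCEPT,
                                   round_index).entries:
        span_key, cid = key[:4], key[4]
        mid = ensure_mention(span_key)
        mention = out.mentions[mid]
        if cid not in mention.linked_concepts:
            mention.linked_concepts.append(cid)

    def rebuild_component(ckey: tuple) -> RelComponent:
        if ckey[0] == "concept":
            return RelComponent("concept", ckey[1])
        if ckey[0] == "text":
            return RelComponent("text", ckey[1])
        return RelComponent("mention", ensure_mention(ckey[1:]))

    for key, _cnt in majority_vote(collection, document_id,
                                   TYPE_RELATIONSHIP, round_index).entries:
        skey, pkey, okey = key
        rel = Relationship(f"c{next(counter)}", CONSENSUS_ANNOTATOR,
                           document_id, rebuild_component(skey),
                           rebuild_component(pkey), rebuild_component(okey))
        out.relationships[rel.relationship_id] = rel
    for key, _cnt in majority_vote(collection, document_id, TYPE_ASSERTION,
                                   round_index).entries:
        from .model import Assertion
        _doc, s, p, o = key
        a = Assertion(f"c{next(counter)}", CONSENSUS_ANNOTATOR,
                      document_id, s, p, o)
        out.assertions[a.assertion_id] = a
    for key, _cnt in majority_vote(collection, document_id, TYPE_LABEL,
                                   round_index).entries:
        from .model import LabelAnnotation
        la = LabelAnnotation(f"c{next(counter)}", CONSENSUS_ANNOTATOR,
                             document_id, key[1])
        out.labels[la.label_id] = la
    return out


def load_consensus(collection: Collection, document_id: str,
                   round_index: Optional[int] = None) -> AnnotationSet:
    """Store the consensus virtual annotator's set in the round so it can
    be copied from like a teammate (replaces any previous consensus
    materialization for the document)."""
    aset = consensus_annotation_set(collection, document_id, round_index)
    rnd = collection.round(round_index)
    collection.member_ids.add(CONSENSUS_ANNOTATOR)
    rnd.sets[(CONSENSUS_ANNOTATOR, document_id)] = _copy.deepcopy(aset)
    return aset
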
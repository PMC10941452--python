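"""Pluggable automatic annotation: entity linking, multi-instance bag
construction, and relation/assertion extraction behind a fixed I/O
contract, with deterministic rule-based reference scorers.

Two tasks are supported:

* **GDA** (gene–disease association) — document-level *assertions*.
  Sentences are divided into bags keyed by (gene concept, disease
  concept) pairs; prediction happens at bag level by averaging
  per-sentence predicate scores and taking the argmax.  The predicate
  vocabulary is fixed: Therapeutic, Biomarker, Genomic Alterations, NA;
  NA means "no association" and suppresses output.
* **GCA** (gene-expression–cancer association) — sentence-level
  *relationships* with gene subject and cancer-disease object.  Three
  aspects are scored per sentence — Change of Gene Expression (CGE),
  Change of Cancer Status (CCS), Gene–Cancer Interaction (GCI) — and an
  inference rule table maps the aspect-value triple to one of the
  predicates biomarker / tumor suppressor / oncogene.

Every emitted annotation carries concept id, name, and type on all three
components, plus mention positions when the component is grounded in
text.  Scorers are pluggable: any object with a ``task`` attribute and a
``score(...)`` method satisfies the contract; the shipped defaults are
keyword-trigger rules, so the whole pipeline is deterministic (identical
inputs produce identical outputs).

Entity linking is a deterministic dictionary scan: per lexicon, a
left-to-right longest-match pass over each text field; matches within one
lexicon never overlap, matches from different lexicons may.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

from .model import (
    AnnotationError,
    Collection,
    Concept,
    concept_ref,
    mention_ref,
)

logger = logging.getLogger(__name__)

#: reserved machine-annotator id; its set is the baseline for diffing
AUTO_ANNOTATOR = "auto"

GDA_PREDICATES = ("Therapeutic", "Biomarker", "Genomic Alterations", "NA")
GCA_PREDICATES = ("biomarker", "tumor suppressor", "oncogene")

#: registry records for the fixed predicate vocabularies
GDA_PREDICATE_CONCEPTS = {
    p: Concept(f"gda:{p.lower().replace(' ', '-')}", p, "GDA predicate")
    for p in GDA_PREDICATES
}
GCA_PREDICATE_CONCEPTS = {
    p: Concept(f"gca:{p.replace(' ', '-')}", p, "gene role")
    for p in GCA_PREDICATES
}


class ContractError(AnnotationError):
    """A plugin emitted output violating the I/O contract."""


# --------------------------------------------------------------------------
# lexicons and entity linking
# --------------------------------------------------------------------------

@dataclass
class Lexicon:
    """Surface -> concept dictionary for one entity type.

    One concept per surface (ambiguity is handled by separate lexicons
    per type); optional case-insensitive matching.
    """

    entries: dict[str, Concept]
    case_insensitive: bool = False

    def __post_init__(self) -> None:
        if any(not s for s in self.entries):
            raise AnnotationError("lexicon surfaces must be non-empty")
        if self.case_insensitive:
            folded: dict[str, Concept] = {}
            for surface, concept in self.entries.items():
                key = surface.casefold()
                if key in folded and folded[key].identifier \
                        != concept.identifier:
                    raise AnnotationError(
                        f"case-fold collision on surface {surface!r}")
                folded[key] = concept
            self.entries = folded

    @classmethod
    def from_csv(cls, path: Union[str, Path],
                 case_insensitive: bool = False) -> "Lexicon":
        """Columns: surface, id, name, type[, description]."""
        text = Path(path).read_text(encoding="utf-8")
        reader = csv.DictReader(io.StringIO(text, newline=""))
        entries: dict[str, Concept] = {}
        for row_no, row in enumerate(reader, start=2):
            surface = (row.get("surface") or "").strip()
            if not surface:
                raise AnnotationError(f"{path}: row {row_no}: empty surface")
            entries[surface] = Concept(
                row["id"].strip(), row["name"].strip(),
                row["type"].strip(), (row.get("description") or None))
        return cls(entries, case_insensitive)


@dataclass(frozen=True)
class EntityLink:
    """One linked entity occurrence in a text field."""

    concept: Concept
    section_name: str
    start: int
    end: int
    surface: str


def link_entities(text_fields: Sequence[tuple[str, str]],
                  lexicons: Sequence[Lexicon]) -> list[EntityLink]:
    """Deterministic dictionary entity linking.

    For each lexicon, scan each field left to right; at every position
    the longest matching surface wins and the scan resumes after it
    (non-overlapping within a lexicon).  Results are sorted by (section,
    start, end, concept id).
    """
    if not lexicons:
        raise AnnotationError("at least one lexicon is required")
    links: list[EntityLink] = []
    for lexicon in lexicons:
        surfaces = sorted(lexicon.entries, key=len, reverse=True)
        for section_name, text in text_fields:
            hay = text.casefold() if lexicon.case_insensitive else text
            pos = 0
            while pos < len(hay):
                hit = None
                for surface in surfaces:
                    if hay.startswith(surface, pos):
                        hit = surface
                        break
                if hit is None:
                    pos += 1
                    continue
                links.append(EntityLink(
                    lexicon.entries[hit], section_name,
                    pos, pos + len(hit), text[pos:pos + len(hit)]))
                pos += len(hit)
    links.sort(key=lambda e: (e.section_name, e.start, e.end,
                              e.concept.identifier))
    return links


# --------------------------------------------------------------------------
# sentence splitting
# --------------------------------------------------------------------------

DEFAULT_ABBREVIATIONS = ("e.g.", "i.e.", "et al.", "Fig.", "fig.", "cf.",
                         "vs.", "Dr.", "approx.", "No.")

_BOUNDARY = re.compile(r"[.?!]+(\s+)(?=[A-Z0-9])")


def split_sentences(text: str,
                    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS
                    ) -> list[tuple[int, int]]:
    """Rule-based sentence spans: split after ``[.?!]`` + whitespace when
    the next character is an uppercase letter or digit, except inside a
    configured abbreviation.  The spans tile the text: concatenating the
    spans plus the inter-span gaps reproduces the input exactly.
    """
    if not text:
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _BOUNDARY.finditer(text):
        boundary = match.start(1)  # first whitespace char after [.?!]+
        prefix = text[:boundary]
        if any(prefix.endswith(abbr) for abbr in abbreviations):
            continue
        spans.append((start, boundary))
        start = match.end(1)
    if start < len(text):
        spans.append((start, len(text)))
    return spans


# --------------------------------------------------------------------------
# bags (multi-instance grouping)
# --------------------------------------------------------------------------

@dataclass
class Bag:
    """All sentences co-mentioning one (concept_a, concept_b) pair; the
    unit of bag-level predicate prediction."""

    pair: tuple[str, str]  # (concept_a id, concept_b id)
    concept_a: Concept
    concept_b: Concept
    # (sentence span, links of a in sentence, links of b in sentence)
    sentences: list[tuple[tuple[int, int], list[EntityLink],
                          list[EntityLink]]] = field(default_factory=list)


def build_bags(entity_links: Sequence[EntityLink],
               sentence_spans: Sequence[tuple[int, int]],
               type_a: str, type_b: str,
               section_name: Optional[str] = None) -> list[Bag]:
    """Group sentences into bags keyed by concept pairs of the two types.

    A sentence joins the bag of pair (A, B) when it contains at least one
    mention of each; pairs with no co-occurring sentence produce no bag.
    Sentence spans refer to one text field (``section_name``).
    """
    links = [e for e in entity_links
             if section_name is None or e.section_name == section_name]
    a_concepts = {e.concept.identifier: e.concept for e in links
                  if e.concept.concept_type == type_a}
    b_concepts = {e.concept.identifier: e.concept for e in links
                  if e.concept.concept_type == type_b}
    bags: dict[tuple[str, str], Bag] = {}
    for span in sentence_spans:
        in_sentence = [e for e in links
                       if span[0] <= e.start and e.end <= span[1]]
        for a_id in sorted(a_concepts):
            a_links = [e for e in in_sentence
                       if e.concept.identifier == a_id]
            if not a_links:
                continue
            for b_id in sorted(b_concepts):
                b_links = [e for e in in_sentence
                           if e.concept.identifier == b_id]
                if not b_links:
                    continue
                bag = bags.setdefault(
                    (a_id, b_id),
                    Bag((a_id, b_id), a_concepts[a_id], b_concepts[b_id]))
                bag.sentences.append((span, a_links, b_links))
    return [bags[k] for k in sorted(bags)]


# --------------------------------------------------------------------------
# scorer plugin contract
# --------------------------------------------------------------------------

class PredicateScorer(Protocol):
    """Anything exposing ``task`` ('GDA' | 'GCA' aspect name) and a
    ``score`` method returning per-category scores in [0, 1]."""

    task: str

    def score(self, sentence_text: str) -> dict[str, float]:
        ...  # pragma: no cover


@dataclass
class TriggerScorer:
    """Deterministic keyword-trigger scorer.

    ``triggers`` maps a category to a list of trigger substrings; a
    category scores 1.0 when any of its triggers occurs in the sentence
    (case-insensitively), else 0.0.  When no category fires and a
    ``fallback`` category is configured, the fallback scores 1.0.
    """

    task: str
    triggers: dict[str, list[str]]
    fallback: Optional[str] = None

    def score(self, sentence_text: str) -> dict[str, float]:
        hay = sentence_text.casefold()
        scores = {cat: (1.0 if any(t.casefold() in hay for t in trigs)
                        else 0.0)
                  for cat, trigs in self.triggers.items()}
        if self.fallback is not None:
            if not any(scores.values()):
                scores[self.fallback] = 1.0
            else:
                scores.setdefault(self.fallback, 0.0)
        return scores


def default_gda_scorer() -> TriggerScorer:
    return TriggerScorer("GDA", {
        "Therapeutic": ["therapeutic", "treats", "treatment target"],
        "Biomarker": ["biomarker", "prognostic marker", "diagnostic marker"],
        "Genomic Alterations": ["mutation", "mutated", "deletion",
                                "amplification", "polymorphism"],
    }, fallback="NA")


#: aspect vocabularies for GCA
CGE_VALUES = ("increased", "decreased", "none")
CCS_VALUES = ("progression", "regression", "none")
GCI_VALUES = ("observed", "none")


def default_gca_aspect_scorers() -> dict[str, TriggerScorer]:
    return {
        "CGE": TriggerScorer("CGE", {
            "increased": ["overexpressed", "upregulated", "up-regulated"],
            "decreased": ["downregulated", "down-regulated", "silenced",
                          "underexpressed"],
        }, fallback="none"),
        "CCS": TriggerScorer("CCS", {
            "progression": ["promotes", "progression", "drives",
                            "accelerates"],
            "regression": ["suppresses", "inhibits", "regression",
                           "prevents"],
        }, fallback="none"),
        "GCI": TriggerScorer("GCI", {
            "observed": ["associated with", "correlates with",
                         "observed in", "detected in"],
        }, fallback="none"),
    }


# --------------------------------------------------------------------------
# GCA inference rule table
# --------------------------------------------------------------------------

@dataclass
class RuleTable:
    """(CGE, CCS, GCI) -> GCA predicate mapping with ``*`` wildcards.

    Rows are matched in order; the first row whose three cells equal the
    aspect values (or are ``*``) wins.  A row may map to the empty
    predicate, meaning "emit nothing" for that combination.
    """

    rows: list[tuple[str, str, str, str]]

    def lookup(self, cge: str, ccs: str, gci: str) -> Optional[str]:
        for r_cge, r_ccs, r_gci, predicate in self.rows:
            if all(r in ("*", v) for r, v in
                   ((r_cge, cge), (r_ccs, ccs), (r_gci, gci))):
                return predicate or None
        return None

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RuleTable":
        """Columns: cge, ccs, gci, predicate."""
        text = Path(path).read_text(encoding="utf-8")
        reader = csv.DictReader(io.StringIO(text, newline=""))
        rows = []
        for row_no, row in enumerate(reader, start=2):
            predicate = (row.get("predicate") or "").strip()
            if predicate and predicate not in GCA_PREDICATES:
                raise AnnotationError(
                    f"{path}: row {row_no}: unknown GCA predicate "
                    f"{predicate!r}")
            rows.append((row["cge"].strip(), row["ccs"].strip(),
                         row["gci"].strip(), predicate))
        return cls(rows)


def default_rule_table() -> RuleTable:
    """Minimal default inference table: expression direction combined
    with the cancer-status direction determines the causal role; an
    expression change alone (interaction observed) marks a biomarker."""
    return RuleTable([
        ("increased", "progression", "*", "oncogene"),
        ("decreased", "regression", "*", "oncogene"),
        ("decreased", "progression", "*", "tumor suppressor"),
        ("increased", "regression", "*", "tumor suppressor"),
        ("increased", "none", "observed", "biomarker"),
        ("decreased", "none", "observed", "biomarker"),
        ("none", "*", "*", ""),
    ])


# --------------------------------------------------------------------------
# output contract
# --------------------------------------------------------------------------

@dataclass
class AutoComponent:
    concept_id: str
    name: str
    concept_type: str
    positions: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class AutoAnnotation:
    """One extracted relationship or assertion in the fixed I/O contract:
    subject/predicate/object concept ids, names and types, plus mention
    positions when grounded in text."""

    kind: str  # "relationship" | "assertion"
    subject: AutoComponent
    predicate: AutoComponent
    object: AutoComponent
    score: float = 1.0

    def components(self) -> tuple[AutoComponent, AutoComponent,
                                  AutoComponent]:
        return (self.subject, self.predicate, self.object)


def validate_contract(annotations: Sequence[AutoAnnotation]) -> None:
    """Reject any output missing concept id, name or type on a
    component, or with an unknown kind."""
    for i, ann in enumerate(annotations):
        if ann.kind not in ("relationship", "assertion"):
            raise ContractError(f"output {i}: unknown kind {ann.kind!r}")
        for role, comp in zip(("subject", "predicate", "object"),
                              ann.components()):
            for fld in ("concept_id", "name", "concept_type"):
                if not getattr(comp, fld):
                    raise ContractError(
                        f"output {i}: {role} component missing {fld}")


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def predict_gda(bags: Sequence[Bag], scorer, text: str,
                ground_mentions: bool = False) -> list[AutoAnnotation]:
    """Bag-level GDA prediction: per-sentence predicate scores are
    averaged over the bag, the argmax predicate is emitted as a
    document-level assertion (ties broken by fixed vocabulary order);
    bags resolving to NA are suppressed."""
    if getattr(scorer, "task", None) != "GDA":
        raise ContractError("predict_gda requires a scorer with task='GDA'")
    out: list[AutoAnnotation] = []
    for bag in bags:
        if not bag.sentences:
            continue
        totals = {p: 0.0 for p in GDA_PREDICATES}
        for (s, e), _a_links, _b_links in bag.sentences:
            scores = scorer.score(text[s:e])
            for p in GDA_PREDICATES:
                totals[p] += float(scores.get(p, 0.0))
        means = {p: totals[p] / len(bag.sentences) for p in GDA_PREDICATES}
        best = max(GDA_PREDICATES,
                   key=lambda p: (means[p], -GDA_PREDICATES.index(p)))
        if sum(1 for p in GDA_PREDICATES if means[p] == means[best]) > 1:
            logger.info("bag %s: predicate tie resolved to %r by "
                        "vocabulary order", bag.pair, best)
        if best == "NA":
            continue
        pred_concept = GDA_PREDICATE_CONCEPTS[best]

        def comp(concept: Concept, links) -> AutoComponent:
            positions = [(lk.section_name, lk.start, lk.end)
                         for (_sp, a_l, b_l) in bag.sentences
                         for lk in links(a_l, b_l)] if ground_mentions else []
            return AutoComponent(concept.identifier, concept.name,
                                 concept.concept_type, positions)

        out.append(AutoAnnotation(
            "assertion",
            comp(bag.concept_a, lambda a, b: a),
            AutoComponent(pred_concept.identifier, pred_concept.name,
                          pred_concept.concept_type),
            comp(bag.concept_b, lambda a, b: b),
            score=means[best]))
    return out


@dataclass
class GcaSkipReport:
    no_entity_pair: int = 0
    no_rule_match: int = 0


def predict_gca(sentence_spans: Sequence[tuple[int, int]],
                entity_links: Sequence[EntityLink], text: str,
                aspect_scorers: Optional[dict] = None,
                rule_table: Optional[RuleTable] = None,
                gene_type: str = "Gene", disease_type: str = "Disease",
                skip_report: Optional[GcaSkipReport] = None
                ) -> list[AutoAnnotation]:
    """Sentence-level GCA prediction: score the CGE/CCS/GCI aspects of
    each sentence containing a gene and a cancer-disease mention, map the
    aspect triple through the rule table, and emit a relationship with
    both mention positions populated."""
    if aspect_scorers is None:
        aspect_scorers = default_gca_aspect_scorers()
    for aspect in ("CGE", "CCS", "GCI"):
        if aspect not in aspect_scorers:
            raise ContractError(f"missing aspect scorer {aspect!r}")
    if rule_table is None:
        rule_table = default_rule_table()
    if skip_report is None:
        skip_report = GcaSkipReport()
    out: list[AutoAnnotation] = []
    for (s, e) in sentence_spans:
        in_sentence = [lk for lk in entity_links
                       if s <= lk.start and lk.end <= e]
        genes = [lk for lk in in_sentence
                 if lk.concept.concept_type == gene_type]
        diseases = [lk for lk in in_sentence
                    if lk.concept.concept_type == disease_type]
        if not genes or not diseases:
            skip_report.no_entity_pair += 1
            continue
        sentence = text[s:e]
        values = {}
        for aspect in ("CGE", "CCS", "GCI"):
            scores = aspect_scorers[aspect].score(sentence)
            values[aspect] = max(sorted(scores),
                                 key=lambda v: scores[v])
        predicate = rule_table.lookup(values["CGE"], values["CCS"],
                                      values["GCI"])
        if predicate is None:
            skip_report.no_rule_match += 1
            continue
        pred_concept = GCA_PREDICATE_CONCEPTS[predicate]
        for g in genes:
            for d in diseases:
                out.append(AutoAnnotation(
                    "relationship",
                    AutoComponent(g.concept.identifier, g.concept.name,
                                  g.concept.concept_type,
                                  [(g.section_name, g.start, g.end)]),
                    AutoComponent(pred_concept.identifier,
                                  pred_concept.name,
                                  pred_concept.concept_type),
                    AutoComponent(d.concept.identifier, d.concept.name,
                                  d.concept.concept_type,
                                  [(d.section_name, d.start, d.end)]),
                ))
    return out


# --------------------------------------------------------------------------
# storing outputs in the collection
# --------------------------------------------------------------------------

def _store_annotations(collection: Collection, document_id: str,
                       annotations: Sequence[AutoAnnotation],
                       round_index: Optional[int]) -> int:
    validate_contract(annotations)
    collection.member_ids.add(AUTO_ANNOTATOR)
    # idempotent refresh: re-running replaces the machine set
    collection.clear_annotator_document(AUTO_ANNOTATOR, document_id,
                                        round_index)
    stored = 0
    for ann in annotations:
        for comp in ann.components():
            collection.register_concept(
                Concept(comp.concept_id, comp.name, comp.concept_type))
        if ann.kind == "assertion":
            collection.create_assertion(
                AUTO_ANNOTATOR, document_id, ann.subject.concept_id,
                ann.predicate.concept_id, ann.object.concept_id,
                round_index)
            stored += 1
            continue
        components = []
        for comp in ann.components():
            if comp.positions:
                section, start, end = comp.positions[0]
                mention = collection.create_mention(
                    AUTO_ANNOTATOR, document_id, section, start, end,
                    round_index)
                collection.link_concept(AUTO_ANNOTATOR, mention.mention_id,
                                        comp.concept_id,
                                        round_index=round_index)
                components.append(mention_ref(mention.mention_id))
            else:
                components.append(concept_ref(comp.concept_id))
        collection.create_relationship(
            AUTO_ANNOTATOR, document_id, components[0], components[1],
            components[2], round_index)
        stored += 1
    return stored


def run_auto(collection: Collection, document_id: str, task: str,
             lexicons: Sequence[Lexicon],
             scorer=None, aspect_scorers: Optional[dict] = None,
             rule_table: Optional[RuleTable] = None,
             round_index: Optional[int] = None,
             gene_type: str = "Gene", disease_type: str = "Disease") -> int:
    """Run the automatic-annotation pipeline on one document and store
    the outputs under the reserved machine annotator, replacing any
    previous machine set for the document (idempotent refresh).

    Returns the number of annotations stored; they become the baseline
    for provenance diffing and the starting point users edit.
    """
    if task not in ("GDA", "GCA"):
        raise AnnotationError(f"unknown task {task!r} (GDA or GCA)")
    doc = collection._document(document_id)
    fields = [(s.name, s.text) for s in doc.sections if s.text]
    if not any(text for _n, text in fields):
        raise AnnotationError("no non-empty text field to annotate")
    links = link_entities(fields, lexicons)
    annotations: list[AutoAnnotation] = []
    for section_name, text in fields:
        spans = split_sentences(text)
        section_links = [lk for lk in links
                         if lk.section_name == section_name]
        if task == "GDA":
            bags = build_bags(section_links, spans, gene_type,
                              disease_type, section_name)
            annotations.extend(predict_gda(
                bags, scorer or default_gda_scorer(), text))
        else:
            annotations.extend(predict_gca(
                spans, section_links, text, aspect_scorers, rule_table,
                gene_type, disease_type))
    return _store_annotations(collection, document_id, annotations,
                              round_index)
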
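"""Seeded synthetic corpora, lexicons and multi-annotator annotation sets
with controllable agreement.

The generator emulates the shape of a small expert annotation campaign:
a handful of abstracts per task (GCA sentence-level relationships, GDA
document-level assertions), three annotators, a machine baseline, and a
second round in which annotators adopt consensus annotations with some
probability.  Documents are assembled from sentence templates so that
every planted association is expressed by in-lexicon entity surfaces plus
an in-rule-table trigger inside a single sentence — gold character
offsets are exact by construction and no NLP is needed to verify them.

Everything is a pure function of the configuration (seed included):
generation twice with the same config is byte-identical.  Randomness is
drawn from stage-scoped substreams (corpus / annotator edits / adoption)
spawned from the master seed, so adding a later stage never reshuffles an
earlier one.  A :class:`GoldLedger` records every planted annotation key
and every per-annotator edit actually applied, sufficient to recompute
every expected statistic without re-parsing text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .autoannotate import (
    AUTO_ANNOTATOR,
    GCA_PREDICATE_CONCEPTS,
    GDA_PREDICATE_CONCEPTS,
    Lexicon,
)
from .model import (
    AnnotationError,
    Collection,
    Concept,
    Document,
    Section,
    concept_ref,
    mention_ref,
)

_FIXED_CLOCK = "2024-01-01T00:00:00Z"


def fixed_clock() -> str:
    """Deterministic timestamp source for reproducible fixtures."""
    return _FIXED_CLOCK


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic campaign.

    Defaults mirror a small expert campaign: ten abstracts per task,
    three annotators, a few associations per abstract.  ``keep_p`` is the
    probability an annotator retains a gold annotation, ``swap_q`` the
    probability a kept relationship/assertion predicate is swapped to a
    random alternative, ``adoption_p`` the probability a round-2
    annotator adopts a consensus entry they disagree with.
    """

    seed: int
    n_documents: int = 10
    task: str = "GCA"               # "GCA" | "GDA" | "both"
    n_annotators: int = 3
    associations_per_document: int = 3
    filler_sentences: tuple[int, int] = (2, 5)
    n_genes: int = 12
    n_diseases: int = 8
    keep_p: float = 0.8
    swap_q: float = 0.3
    adoption_p: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise AnnotationError("seed is mandatory")
        for name in ("keep_p", "swap_q", "adoption_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AnnotationError(f"{name} must be in [0, 1], got {v}")
        if self.task not in ("GCA", "GDA", "both"):
            raise AnnotationError(f"unknown task {self.task!r}")
        if self.n_annotators < 1:
            raise AnnotationError("n_annotators must be >= 1")
        if self.associations_per_document > self.n_genes * self.n_diseases:
            raise AnnotationError(
                "vocabulary too small for the requested association "
                "density")


# templates: gene first, trigger words drive the default scorers
_GCA_TEMPLATES = {
    "gca:oncogene": "{g} is overexpressed and promotes {d} .",
    "gca:tumor-suppressor": "{g} is downregulated and promotes {d} .",
    "gca:biomarker": "{g} is overexpressed and associated with {d} .",
}
_GDA_TEMPLATES = {
    "gda:therapeutic": "{g} treats {d} effectively .",
    "gda:biomarker": "{g} is a biomarker of {d} .",
    "gda:genomic-alterations": "{g} mutation occurs in {d} .",
}
_FILLERS = (
    "Further validation is required .",
    "The cohort included many participants .",
    "These findings warrant additional study .",
    "Samples were processed with standard protocols .",
)

LABELS = ("relevant", "not-relevant")


@dataclass
class GoldAssociation:
    """One planted association with its exact offsets."""

    document_id: str
    task: str                    # "GCA" | "GDA"
    sentence: tuple[int, int]    # span in the abstract section
    gene_id: str
    gene_span: tuple[int, int]
    disease_id: str
    disease_span: tuple[int, int]
    predicate_id: str            # gold predicate concept id


@dataclass
class GoldLedger:
    """Book-keeping sufficient to recompute every expected statistic."""

    associations: list[GoldAssociation] = field(default_factory=list)
    gold_labels: dict[str, str] = field(default_factory=dict)
    # annotator -> list of (association index, "kept"|"dropped", predicate)
    annotator_edits: dict[str, list[tuple[int, str, Optional[str]]]] = \
        field(default_factory=dict)
    # annotator -> association index -> adopted consensus predicate
    adoption_edits: dict[str, dict[int, str]] = field(default_factory=dict)

    def associations_for(self, document_id: str) -> list[GoldAssociation]:
        return [a for a in self.associations
                if a.document_id == document_id]

    def planted_counts(self) -> dict[str, int]:
        return {
            "relationships": sum(1 for a in self.associations
                                 if a.task == "GCA"),
            "assertions": sum(1 for a in self.associations
                              if a.task == "GDA"),
            "mentions": 2 * len(self.associations),
            "concept_links": 2 * len(self.associations),
            "labels": len(self.gold_labels),
        }


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    collection: Collection
    lexicons: dict[str, Lexicon]
    ledger: GoldLedger


def _vocabularies(config: GeneratorConfig
                  ) -> tuple[dict[str, Concept], dict[str, Concept]]:
    genes = {f"GENE{i:02d}": Concept(f"NCBI:{1000 + i}", f"GENE{i:02d}",
                                     "Gene")
             for i in range(1, config.n_genes + 1)}
    diseases = {f"DISEASE{i:02d}": Concept(f"MESH:D{i:04d}",
                                           f"DISEASE{i:02d}", "Disease")
                for i in range(1, config.n_diseases + 1)}
    return genes, diseases


def _instantiate(template: str, gene: str, disease: str
                 ) -> tuple[str, tuple[int, int], tuple[int, int]]:
    g_pos = template.index("{g}")
    before_d = template[:template.index("{d}")].replace("{g}", gene)
    d_pos = len(before_d)
    sentence = template.replace("{g}", gene).replace("{d}", disease)
    return (sentence, (g_pos, g_pos + len(gene)),
            (d_pos, d_pos + len(disease)))


def gen_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate documents, lexicons and the gold ledger (no annotations
    are stored yet — see :func:`materialize_gold` and
    :func:`gen_annotator_sets`)."""
    master = np.random.SeedSequence(config.seed)
    corpus_stream, _edit_stream, _adopt_stream = \
        [np.random.default_rng(s) for s in master.spawn(3)]
    genes, diseases = _vocabularies(config)
    gene_surfaces = sorted(genes)
    disease_surfaces = sorted(diseases)

    collection = Collection(
        f"synthetic-{config.seed}", "synthetic campaign",
        "template-generated corpus with planted associations",
        creator_id="creator",
        member_ids=[f"ann{i}" for i in range(1, config.n_annotators + 1)],
        labels=LABELS, clock=fixed_clock)
    for concept in list(genes.values()) + list(diseases.values()):
        collection.register_concept(concept)
    for concept in list(GCA_PREDICATE_CONCEPTS.values()) \
            + list(GDA_PREDICATE_CONCEPTS.values()):
        collection.register_concept(concept)

    ledger = GoldLedger()
    for d_idx in range(1, config.n_documents + 1):
        doc_id = f"doc-{d_idx:02d}"
        if config.task == "both":
            task = "GCA" if d_idx % 2 == 1 else "GDA"
        else:
            task = config.task
        templates = _GCA_TEMPLATES if task == "GCA" else _GDA_TEMPLATES
        pred_ids = sorted(templates)

        n_pairs = config.associations_per_document
        pair_codes = corpus_stream.choice(
            config.n_genes * config.n_diseases, size=n_pairs,
            replace=False)
        n_fill = int(corpus_stream.integers(config.filler_sentences[0],
                                            config.filler_sentences[1] + 1))
        sentences: list[tuple[str, Optional[dict]]] = []
        for code in pair_codes:
            g_surface = gene_surfaces[int(code) % config.n_genes]
            d_surface = disease_surfaces[int(code) // config.n_genes]
            predicate = pred_ids[int(corpus_stream.integers(len(pred_ids)))]
            sentence, g_span, d_span = _instantiate(
                templates[predicate], g_surface, d_surface)
            sentences.append((sentence, {
                "task": task, "gene": genes[g_surface].identifier,
                "disease": diseases[d_surface].identifier,
                "g_span": g_span, "d_span": d_span,
                "predicate": predicate}))
        for _ in range(n_fill):
            filler = _FILLERS[int(corpus_stream.integers(len(_FILLERS)))]
            sentences.append((filler, None))
        order = corpus_stream.permutation(len(sentences))
        sentences = [sentences[i] for i in order]

        offset = 0
        text_parts = []
        planted = []
        for sentence, info in sentences:
            if info is not None:
                planted.append(GoldAssociation(
                    doc_id, info["task"],
                    (offset, offset + len(sentence)),
                    info["gene"],
                    (offset + info["g_span"][0],
                     offset + info["g_span"][1]),
                    info["disease"],
                    (offset + info["d_span"][0],
                     offset + info["d_span"][1]),
                    info["predicate"]))
            text_parts.append(sentence)
            offset += len(sentence) + 1  # single-space joint
        text = " ".join(text_parts)
        collection.add_document(Document(doc_id,
                                         [Section("abstract", text)]))
        ledger.associations.extend(planted)
        ledger.gold_labels[doc_id] = "relevant" if planted \
            else "not-relevant"

    lexicons = {
        "Gene": Lexicon({s: c for s, c in genes.items()}),
        "Disease": Lexicon({s: c for s, c in diseases.items()}),
    }
    return SyntheticCorpus(config, collection, lexicons, ledger)


# --------------------------------------------------------------------------
# materializing annotation sets
# --------------------------------------------------------------------------

def _ensure_mention(collection: Collection, annotator: str, doc_id: str,
                    span: tuple[int, int], concept_id: str,
                    round_index: Optional[int]):
    aset = collection.annotation_set(annotator, doc_id, round_index)
    for m in aset.mentions.values():
        if m.span.key == ("abstract",) + span:
            if concept_id not in m.linked_concepts:
                collection.link_concept(annotator, m.mention_id,
                                        concept_id,
                                        round_index=round_index)
            return m
    m = collection.create_mention(annotator, doc_id, "abstract", *span,
                                  round_index)
    collection.link_concept(annotator, m.mention_id, concept_id,
                            round_index=round_index)
    return m


def _store_association(collection: Collection, annotator: str,
                       assoc: GoldAssociation, predicate_id: str,
                       round_index: Optional[int] = None) -> None:
    gm = _ensure_mention(collection, annotator, assoc.document_id,
                         assoc.gene_span, assoc.gene_id, round_index)
    dm = _ensure_mention(collection, annotator, assoc.document_id,
                         assoc.disease_span, assoc.disease_id, round_index)
    if assoc.task == "GCA":
        collection.create_relationship(
            annotator, assoc.document_id, mention_ref(gm.mention_id),
            concept_ref(predicate_id), mention_ref(dm.mention_id),
            round_index)
    else:
        collection.create_assertion(
            annotator, assoc.document_id, assoc.gene_id, predicate_id,
            assoc.disease_id, round_index)


def materialize_gold(corpus: SyntheticCorpus, annotator: str,
                     round_index: Optional[int] = None) -> int:
    """Store the full gold standard under ``annotator`` (used for the
    machine baseline); returns the number of associations stored."""
    collection = corpus.collection
    collection.member_ids.add(annotator)
    for assoc in corpus.ledger.associations:
        _store_association(collection, annotator, assoc,
                           assoc.predicate_id, round_index)
    for doc_id, label in corpus.ledger.gold_labels.items():
        collection.set_labels(annotator, doc_id, {label}, round_index)
    return len(corpus.ledger.associations)


def _alternative_predicates(assoc: GoldAssociation) -> list[str]:
    pool = _GCA_TEMPLATES if assoc.task == "GCA" else _GDA_TEMPLATES
    return sorted(p for p in pool if p != assoc.predicate_id)


def gen_annotator_sets(corpus: SyntheticCorpus,
                       round_index: Optional[int] = None) -> None:
    """Create each annotator's imperfect copy of the gold standard.

    Per annotator and association: the association is kept with
    probability ``keep_p``; a kept relationship/assertion predicate is
    swapped to a seeded random alternative with probability ``swap_q``.
    Labels are kept with probability ``keep_p``.  Applied edits are
    written to the ledger.
    """
    config = corpus.config
    master = np.random.SeedSequence(config.seed)
    _c, edit_stream, _a = [np.random.default_rng(s)
                           for s in master.spawn(3)]
    collection = corpus.collection
    for i in range(1, config.n_annotators + 1):
        annotator = f"ann{i}"
        edits: list[tuple[int, str, Optional[str]]] = []
        for idx, assoc in enumerate(corpus.ledger.associations):
            if edit_stream.random() > config.keep_p:
                edits.append((idx, "dropped", None))
                continue
            predicate = assoc.predicate_id
            if edit_stream.random() < config.swap_q:
                alternatives = _alternative_predicates(assoc)
                predicate = alternatives[
                    int(edit_stream.integers(len(alternatives)))]
            _store_association(collection, annotator, assoc, predicate,
                               round_index)
            edits.append((idx, "kept", predicate))
        for doc_id, label in corpus.ledger.gold_labels.items():
            if edit_stream.random() <= config.keep_p:
                collection.set_labels(annotator, doc_id, {label},
                                      round_index)
        corpus.ledger.annotator_edits[annotator] = edits


# --------------------------------------------------------------------------
# two-round study
# --------------------------------------------------------------------------

def _adopt_consensus(corpus: SyntheticCorpus,
                     round_index: int) -> None:
    """Round-2 collaborative step: each annotator adopts, with
    probability ``adoption_p``, each consensus association entry they do
    not already hold with the consensus predicate."""
    config = corpus.config
    master = np.random.SeedSequence(config.seed)
    _c, _e, adopt_stream = [np.random.default_rng(s)
                            for s in master.spawn(3)]
    collection = corpus.collection
    annotators = [f"ann{i}" for i in range(1, config.n_annotators + 1)]

    # consensus predicate per association, from the round-1 sets
    consensus_pred: dict[int, str] = {}
    for idx, assoc in enumerate(corpus.ledger.associations):
        votes: dict[str, int] = {}
        n_voters = 0
        for annotator in annotators:
            edits = dict((e[0], e) for e in
                         corpus.ledger.annotator_edits[annotator])
            entry = edits.get(idx)
            if entry is not None and entry[1] == "kept":
                votes[entry[2]] = votes.get(entry[2], 0) + 1
            n_voters += 1
        for predicate, count in sorted(votes.items()):
            if count * 2 > n_voters:
                consensus_pred[idx] = predicate
    for annotator in annotators:
        adopted: dict[int, str] = {}
        edits = dict((e[0], e) for e in
                     corpus.ledger.annotator_edits[annotator])
        for idx, predicate in sorted(consensus_pred.items()):
            entry = edits.get(idx)
            holds = entry is not None and entry[1] == "kept" \
                and entry[2] == predicate
            if holds:
                continue
            if adopt_stream.random() <= config.adoption_p \
                    and config.adoption_p > 0.0:
                assoc = corpus.ledger.associations[idx]
                if entry is not None and entry[1] == "kept":
                    # switch predicate: drop the old triple first
                    _drop_association(collection, annotator, assoc,
                                      entry[2], round_index)
                _store_association(collection, annotator, assoc,
                                   predicate, round_index)
                adopted[idx] = predicate
        corpus.ledger.adoption_edits[annotator] = adopted


def _drop_association(collection: Collection, annotator: str,
                      assoc: GoldAssociation, predicate_id: str,
                      round_index: int) -> None:
    aset = collection.annotation_set(annotator, assoc.document_id,
                                     round_index)
    if assoc.task == "GCA":
        for rid, rel in list(aset.relationships.items()):
            subj = aset.mentions.get(rel.subject.ref) \
                if rel.subject.kind == "mention" else None
            obj = aset.mentions.get(rel.object.ref) \
                if rel.object.kind == "mention" else None
            if (subj is not None and obj is not None
                    and subj.span.key[1:3] == assoc.gene_span
                    and obj.span.key[1:3] == assoc.disease_span
                    and rel.predicate.kind == "concept"
                    and rel.predicate.ref == predicate_id):
                collection.delete_annotation(annotator, rid, round_index)
                return
    else:
        for aid, a in list(aset.assertions.items()):
            if (a.subject, a.predicate, a.object) == (
                    assoc.gene_id, predicate_id, assoc.disease_id):
                collection.delete_annotation(annotator, aid, round_index)
                return


@dataclass
class StudyResult:
    corpus: SyntheticCorpus

    @property
    def collection(self) -> Collection:
        return self.corpus.collection

    @property
    def ledger(self) -> GoldLedger:
        return self.corpus.ledger


def gen_round_study(config: GeneratorConfig) -> StudyResult:
    """Build the two-round campaign: round 1 = machine baseline plus
    per-annotator imperfect copies of the gold standard; round 2 =
    duplicate of round 1 in which each annotator adopts consensus
    entries with probability ``adoption_p``."""
    corpus = gen_corpus(config)
    collection = corpus.collection
    materialize_gold(corpus, AUTO_ANNOTATOR, round_index=1)
    gen_annotator_sets(corpus, round_index=1)
    members = [f"ann{i}" for i in range(1, config.n_annotators + 1)]
    collection.new_round("creator", set(members) | {AUTO_ANNOTATOR})
    _adopt_consensus(corpus, collection.current_round.round_index)
    return StudyResult(corpus)
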
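# Methods

This note documents the models, conventions and numerical choices behind
`annodesk`, and what the synthetic-data experiments do and do not show.

## Stand-off data model

Offsets are 0-based, half-open character positions per section, computed
over the text exactly as ingested.  No Unicode normalisation is applied
anywhere: ingestion decodes UTF-8 strictly (BOM stripped, decoding errors
are hard failures) because silent replacement characters would shift
every downstream offset.  A mention's `surface` is always recomputed
from the section text and re-validated on every load and import
(`surface == text[start:end)` is an enforced invariant, never an
assumption).

Mentions are single contiguous spans; discontinuous mentions are out of
scope.  Overlap is unrestricted, both within and across annotators.  A
token-boundary helper (`token_boundaries`, a token being a maximal run of
non-space characters) is provided for convenience but not enforced — the
headless API accepts arbitrary valid offsets, collapsing the GUI
gestures (token click, double click, drag) of interactive tools into one
operation.

**Identity keys.**  Annotations are deduplicated, counted and diffed by
content keys rather than database ids: a mention by
`(document, section, start, end)`; a concept link by mention key +
concept id; a relationship by the triple of component keys (concept id,
mention key, or trimmed case-folded free text for textual predicates); an
assertion by its `(subject, predicate, object)` concept ids; a label by
`(document, label)`.  Timestamps are stored (UTC ISO-8601) for reporting
only and never participate in identity.

**Cascade on mention deletion.**  Deleting a mention deletes every
relationship that references it.  The alternative — orphaning the
component — would leave relationships violating their own validity rule
(three resolvable components, at least one mention).  Cascaded deletions
are always itemized in the returned report, never silent.

**Rounds.**  Round *r+1* starts as a deep copy of round *r*'s
annotations for carried-over members; the copy is the only coupling, and
the round-isolation property (`canonical_round_state` of the prior round
is byte-identical under any edit script applied to the new round) is
tested exhaustively.

**annotate-all.**  Occurrence matching is exact substring, scanning left
to right with non-overlapping matches (the scan resumes at each match
end); a `case_insensitive` flag widens matching.  Occurrences already
annotated by the caller with the identical (span, concept-set) are
skipped.

**Self-relations.**  A relationship may use the same mention in two
roles; this is permitted with a warning, since nothing in the validity
rules forbids it and reflexive statements do occur in practice.

## Unitization and agreement

Kappa statistics require a fixed item × category design with a constant
rater count per item; free-form stand-off annotation provides neither.
The unitizer therefore maps each annotation type to items and
categories:

| type          | item                                   | categories |
|---------------|----------------------------------------|------------|
| mention       | span key                               | PRESENT / ABSENT |
| concept link  | (span key, concept id)                 | PRESENT / ABSENT |
| relationship  | (document, subject key, object key)    | predicate identity ∪ ABSENT |
| assertion     | (document, subject id, object id)      | predicate id ∪ ABSENT |
| label         | (document, label)                      | PRESENT / ABSENT |

Items are the union of keys observed across the annotators in scope;
annotators missing an item rate it ABSENT, which yields exactly
*n* ratings per item.  Keying relationships and assertions by their
endpoint pair makes their agreement measure *predicate choice* — two
annotators who marked the same gene–disease pair with different roles
disagree on that one item rather than silently producing two disjoint
items.  If one annotator holds several predicates for the same pair, the
lexicographically smallest predicate key is used (deterministic
tie-break).  Span matching across annotators is exact; partial-overlap
credit is out of scope.

Collection-scope kappa pools items across documents (the document id is
part of every item key) rather than averaging per-document kappas;
pooling weights documents by their annotation volume and never mixes
same-concept pairs from different documents.

**Degenerate cases.**  An empty item universe yields UNDEFINED
(`None`).  If every rater places every item in one single category,
P̄ = P̄ₑ = 1 and the ratio is 0/0; agreement is then literally perfect
and κ is defined as exactly 1.  Perfect agreement always returns the
float `1.0` exactly, not a value within rounding of it.

**Majority voting.**  *n* counts the annotators with at least one
annotation of any type on the document in the round (the document's
annotators, not all collection members); an entry needs support
strictly greater than *n*/2, so 2 of 3 is in and 2 of 4 is out.  The
consensus can be materialized as a virtual annotator (`IAA`) whose set
is loadable and copyable like a teammate's.

The implementation of both kappas is the package's own (closed-form over
the rating table); `statsmodels` and `scikit-learn` implementations are
used in the test suite only, as independent cross-checks alongside
plain-Python textbook-formula oracles (agreement to 1e-12 on 1,000
seeded random tables).

## Automatic annotation

The pipeline keeps the architecture of neural relation-extraction
systems — entity linking, sentence-level encoding, multi-instance
aggregation — behind a scorer interface, while the shipped reference
scorers are deterministic keyword-trigger rules.  Trained neural models
are deliberately not part of the package: they are external,
GPU-trained artifacts, and the framework is designed so that any scorer
satisfying the I/O contract plugs in.

* **Entity linking** is a per-lexicon left-to-right longest-match scan;
  matches within one lexicon never overlap (the scan resumes at each
  match end), matches from different lexicons may.  One concept per
  surface per lexicon; ambiguity is handled by separate lexicons per
  entity type.
* **Sentence splitting** is rule-based: split after `[.?!]` + whitespace
  when the next character is uppercase or a digit, except inside a
  configurable abbreviation list.  Spans tile the text exactly, so
  sentence-relative and absolute offsets interconvert without loss.
* **GDA (assertions).**  Sentences are grouped into bags keyed by
  (gene, disease) concept pairs; a bag collects every sentence
  containing at least one mention of each.  Per-sentence predicate
  scores are averaged over the bag — the score-level analogue of
  representation averaging, which is meaningless without a neural
  encoder — and the argmax is emitted as a document-level assertion.
  Ties break by fixed vocabulary order (Therapeutic, Biomarker, Genomic
  Alterations, NA) and are logged.  NA means "no association" and
  suppresses output.  Assertions carry no mention positions by default
  (a grounding flag exists), matching their definition as span-unbound.
* **GCA (relationships).**  Each sentence containing both a gene and a
  cancer-disease mention is scored on three aspects — change of gene
  expression (CGE: increased/decreased/none), change of cancer status
  (CCS: progression/regression/none), gene–cancer interaction (GCI:
  observed/none) — and the triple is mapped to a predicate through a
  rule table (CSV-configurable, `*` wildcards, first match wins).  The
  default table encodes the minimal biological reading: expression up +
  progression ⇒ oncogene, expression down + progression ⇒ tumor
  suppressor (and the two mirrored combinations), expression change with
  an observed interaction but no status change ⇒ biomarker.  This
  default makes the pipeline exercisable end-to-end; it makes no claim
  of fidelity to any published inference rule set.
* **Contract.**  Every emitted annotation must carry concept id, name
  and type on all three components; violations are rejected before
  anything is stored.  Outputs are stored under the reserved machine
  annotator id `auto`; re-running replaces the previous machine set for
  the document (idempotent refresh).

## Interchange formats

Exports are deterministic: stable key order, annotations sorted by
identity key, fixed zip member timestamps.  The BioC dialect maps one
section to one passage with absolute offsets over the concatenation of
sections joined by single newlines; mention annotations carry
`|`-joined concept ids/names/types in infons (concept ids must not
contain `|`); assertions become relations with zero nodes because BioC
relations normally reference annotations and a pure-concept triple has
none; free-text predicates are flagged distinctly in infons.  Import is
transactional: the whole file is validated against every data-model
invariant (including span/surface equality against the live document
text) before anything commits, and duplicates by identity key are
skipped and counted.

## Synthetic data: what it emulates and what it does not

The generator emulates the *shape* of a small expert campaign — ten
abstracts per task, three annotators, a machine baseline, a
consensus-informed second round — with template sentences ("GENE07 is
overexpressed and promotes DISEASE03 .") whose entity surfaces come from
the lexicons and whose trigger words drive the default scorers.  Default
parameters: 10 documents, 3 associations per document, 2–5 filler
sentences, 12 gene / 8 disease surfaces, keep probability p = 0.8
(annotator retains a gold annotation), swap probability q = 0.3 (a kept
predicate is replaced by a random alternative), adoption probability
0.5 (a round-2 annotator adopts a consensus entry they disagree with).
The keep/swap defaults produce round-1 kappas in the low-agreement
regime that motivates multi-round annotation; the adoption step then
raises round-2 agreement, reproducing qualitatively the improvement a
collaborative second round yields in practice.

Generation is a pure function of the config: one master seed spawns
stage-scoped substreams (corpus, annotator edits, adoption), so adding a
later stage never reshuffles earlier output.  The gold ledger records
every planted key and every per-annotator edit actually applied, which
is what the diff-provenance and recall tests compare against.

Template text is not natural language: no anaphora, no cross-sentence
relations, no lexical ambiguity, no entity-boundary noise.  Passing
tests therefore demonstrate the correctness of the bookkeeping,
statistics and pipeline plumbing under exactly expressed annotations —
not the linguistic robustness of the rule scorers on real abstracts,
which is the role of pluggable trained models.

## Problem sizes

The test suite and the acceptance script run at desk scale: 1,000 random
rating tables for the kappa oracles, 100 randomized consensus fixtures,
200-step edit scripts for round isolation, 50 collections × 3 formats
for round-trips (10 × 3 in the faster acceptance script), 100 seeded
replicates of the two-round study for the agreement trajectory.  These
sizes were chosen so the full suite completes in seconds while keeping
every Monte-Carlo bound (3σ binomial checks, the ≥95% trajectory rate)
statistically meaningful.

## Known limitations

* No chance-corrected span-overlap measures (Krippendorff's α, γ);
  agreement on spans is exact-match only.
* Relationship agreement treats endpoint pairs as the unit; alternative
  unitizations can be plugged in at the `unitize` boundary but are not
  provided.
* The CSV ingestion treats each cell as flat text; multi-valued cells
  are not sectioned further.
* Live HTTP fetching of bibliographic metadata and PDF parsing are
  declared interfaces with injected transports; no network client is
  bundled.
* The file store assumes collection, document and annotator ids that are
  safe after conservative filename sanitization; ids differing only in
  sanitized characters would collide.
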
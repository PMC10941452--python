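# annodesk

A headless, file-backed annotation store for biomedical text corpora,
built for teams that annotate the same documents independently and need
to quantify — and improve — how much they agree.

Creating gold-standard corpora for biomedical NLP (relation extraction,
entity linking, topic labelling) requires several experts to annotate the
same abstracts, reconcile their differences over multiple rounds, and
track how much of an automatically generated starting set they kept,
fixed, or discarded.  `annodesk` provides the data model and the
statistics for that workflow as a Python library and CLI, without any GUI
or database server.

## What it models

Annotations are *stand-off*: they reference document sections by 0-based,
half-open character offsets `[start, end)` and never modify the text.
Five annotation types are supported:

* **mention** — a contiguous span; overlapping mentions are allowed;
* **concept link** — a mention linked to one or more registry concepts
  (URI/ID + name + type; ontology-agnostic, e.g. MeSH and NCBI Gene ids
  side by side);
* **relationship** — a subject–predicate–object triple mixing mentions
  and concepts, with at least one mention (the predicate may be free
  text);
* **assertion** — a document-level pure-concept triple bound to no span;
* **label** — a document-level tag from the collection's label set.

Collections hold documents, members, a concept registry and an ordered
list of *rounds*; opening round *r+1* duplicates round *r*'s annotations
for the carried-over members, after which the rounds are fully isolated.

## Agreement statistics

Free-form annotations are unitized into an item × category rating table
(per annotation type) and scored with:

* **Fleiss' κ** (≥ 2 raters): with *n* raters, *N* items and n\_ij raters
  placing item *i* in category *j*,

  P̄ = (1/N) Σᵢ (Σⱼ n\_ij² − n) / (n(n−1)),  P̄ₑ = Σⱼ (Σᵢ n\_ij / Nn)²,
  κ = (P̄ − P̄ₑ) / (1 − P̄ₑ)

* **Cohen's κ** (2 raters): κ = (p₀ − pₑ)/(1 − pₑ) with p₀ the observed
  and pₑ the chance agreement;
* **majority voting**: every annotation held by strictly more than half
  of a document's annotators forms a consensus set, loadable and copyable
  like a virtual annotator.

A diff engine classifies a final annotation set against a baseline
(typically the machine annotator) into **added / updated / deleted /
confirmed**, where an *update* means the same subject–object pair with a
different predicate (or the same span with a different concept set).

## Automatic annotation

A pluggable pipeline produces the machine baseline: dictionary
(longest-match) entity linking, sentence splitting, multi-instance *bags*
of sentences keyed by concept pairs, and two extraction tasks —
gene–disease association **assertions** (predicates Therapeutic /
Biomarker / Genomic Alterations / NA, predicted per bag by averaging
sentence scores) and gene-expression–cancer **relationships** (predicates
biomarker / tumor suppressor / oncogene, inferred per sentence from the
CGE / CCS / GCI aspects through a configurable rule table).  The shipped
scorers are deterministic keyword-trigger rules; any scorer satisfying
the documented I/O contract (concept id + name + type on all three
components) can be plugged in.

## Worked example

```python
from annodesk import (GeneratorConfig, gen_round_study, fleiss_for,
                      majority_vote, diff_against_baseline)
from annodesk.autoannotate import AUTO_ANNOTATOR

study = gen_round_study(GeneratorConfig(seed=42, n_documents=10,
                                        task="GCA"))
col = study.collection

for rnd in (1, 2):
    for t in ("concept", "relationship"):
        k = fleiss_for(col, t, round_index=rnd,
                       exclude_annotators=(AUTO_ANNOTATOR,)).kappa
        print(f"round {rnd} {t:12s} Fleiss kappa = {k:+.4f}")

cons = majority_vote(col, "doc-01", "relationship", round_index=2,
                     exclude_annotators=(AUTO_ANNOTATOR,))
print(f"doc-01 consensus relationships: {len(cons.entries)} "
      f"(of {cons.n_annotators} annotators)")

diff = diff_against_baseline(col, AUTO_ANNOTATOR,
                             ["ann1", "ann2", "ann3"], "relationship",
                             round_index=2)
print("diff vs machine baseline:", diff.counts)
```

Output:

```
round 1 concept      Fleiss kappa = +0.0805
round 1 relationship Fleiss kappa = +0.1611
round 2 concept      Fleiss kappa = +0.1477
round 2 relationship Fleiss kappa = +0.3111
doc-01 consensus relationships: 1 (of 3 annotators)
diff vs machine baseline: {'added': 0, 'updated': 15, 'deleted': 0, 'confirmed': 15}
```

The simulated campaign plants gene–cancer associations in ten abstracts,
gives three annotators imperfect copies of the gold standard, and lets
them adopt consensus entries in round 2: agreement rises between rounds,
and the diff shows how much of the machine baseline the team confirmed
versus re-predicated.

The same workflow is available from the shell:

```bash
annodesk --store ./annostore --json simulate round-study --seed 42
annodesk --store ./annostore agree --collection synthetic-42 \
         --measure fleiss --type relationship
annodesk --store ./annostore diff --collection synthetic-42 \
         --baseline auto --against ann1 --type relationship
```

## Interchange

Annotations export and import in three formats — JSON (versioned
schema), CSV (RFC-4180, one file per annotation type), and BioC-XML
(passages with absolute offsets over newline-joined sections; assertions
as zero-node relations) — with deterministic byte-identical serialization
and all-or-nothing validated import.  Documents ingest from TXT, CSV
(headers become sections), JSON (keys become sections), and stubbed
PubMed / Semantic Scholar / OpenAIRE metadata fetchers.

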
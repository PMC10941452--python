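"""Automatic annotation: lexicon entity linking, sentence splitting,
multi-instance bags, rule-based GDA/GCA prediction, contract checks."""

import itertools

import pytest

from annodesk import (
    AnnotationError,
    Concept,
    Document,
    Lexicon,
    RuleTable,
    Section,
    TriggerScorer,
    build_bags,
    default_gda_scorer,
    default_rule_table,
    link_entities,
    predict_gca,
    predict_gda,
    run_auto,
    split_sentences,
)
from annodesk.autoannotate import (
    AUTO_ANNOTATOR,
    AutoAnnotation,
    AutoComponent,
    ContractError,
    validate_contract,
)

GENE_LEX = Lexicon({"TP53": Concept("NCBI:7157", "TP53", "Gene")})
DISEASE_LEX = Lexicon({
    "lung cancer": Concept("MESH:D008175", "Lung Neoplasms", "Disease"),
    "cancer": Concept("MESH:D009369", "Neoplasms", "Disease"),
})


class TestEntityLinking:
    def test_exact_offsets_for_two_lexicons(self):
        text = "TP53 suppresses lung cancer."
        links = link_entities([("text", text)], [GENE_LEX, DISEASE_LEX])
        got = [(e.start, e.end, e.concept.identifier) for e in links]
        assert got == [(0, 4, "NCBI:7157"), (16, 27, "MESH:D008175")]
        assert all(text[e.start:e.end] == e.surface for e in links)

    def test_empty_text_yields_nothing(self):
        assert link_entities([("text", "")], [GENE_LEX]) == []

    def test_longest_match_wins_within_lexicon(self):
        lex = Lexicon({
            "breast cancer": Concept("MESH:D001943", "Breast Neoplasms",
                                     "Disease"),
            "cancer": Concept("MESH:D009369", "Neoplasms", "Disease")})
        links = link_entities([("text", "breast cancer")], [lex])
        assert [e.concept.identifier for e in links] == ["MESH:D001943"]

    def test_matches_exhaustive_scan_oracle(self):
        import random
        rng = random.Random(3)
        surfaces = ["AA", "BBB", "CCCC"]
        lex = Lexicon({s: Concept(f"X:{s}", s, "T") for s in surfaces})
        for _ in range(50):
            text = "".join(rng.choice(["AA", "BBB", "CCCC", "z", " "])
                           for _ in range(rng.randint(0, 40)))
            got = [(e.start, e.end) for e in
                   link_entities([("t", text)], [lex])]
            # oracle: exhaustive scan, longest match, resume at match end
            expected, pos = [], 0
            while pos < len(text):
                for s in sorted(surfaces, key=len, reverse=True):
                    if text.startswith(s, pos):
                        expected.append((pos, pos + len(s)))
                        pos += len(s)
                        break
                else:
                    pos += 1
            assert got == expected


class TestSentenceSplitting:
    def test_basic_split(self):
        assert split_sentences("A. B.") == [(0, 2), (3, 5)]

    def test_empty_text(self):
        assert split_sentences("") == []

    def test_abbreviation_not_split(self):
        text = "Genes, e.g. TP53, matter. Second sentence."
        spans = split_sentences(text)
        assert len(spans) == 2
        assert text[spans[0][0]:spans[0][1]].endswith("matter.")

    def test_spans_tile_the_text(self):
        text = "One sentence. Another one? Yes! And 4 numbers."
        spans = split_sentences(text)
        rebuilt = ""
        prev_end = 0
        for start, end in spans:
            rebuilt += text[prev_end:start] + text[start:end]
            prev_end = end
        rebuilt += text[prev_end:]
        assert rebuilt == text


class TestBags:
    def _links(self, text):
        return link_entities([("text", text)], [GENE_LEX, DISEASE_LEX])

    def test_two_cooccurring_sentences_one_bag(self):
        text = "TP53 mutated in lung cancer. TP53 alters lung cancer."
        spans = split_sentences(text)
        bags = build_bags(self._links(text), spans, "Gene", "Disease")
        pairs = [(b.pair, len(b.sentences)) for b in bags]
        assert (("NCBI:7157", "MESH:D008175"), 2) in pairs

    def test_no_cooccurrence_no_bag(self):
        text = "TP53 is a gene. Many have lung cancer."
        spans = split_sentences(text)
        bags = build_bags(self._links(text), spans, "Gene", "Disease")
        assert bags == []

    def test_matches_bruteforce_enumeration(self):
        import random
        rng = random.Random(17)
        genes = {f"G{i}": Concept(f"NCBI:{i}", f"G{i}", "Gene")
                 for i in range(1, 6)}
        diseases = {f"D{i}": Concept(f"MESH:{i}", f"D{i}", "Disease")
                    for i in range(1, 6)}
        lexes = [Lexicon(genes), Lexicon(diseases)]
        for _ in range(20):
            sentences = []
            for _s in range(rng.randint(1, 20)):
                tokens = rng.sample(sorted(genes) + sorted(diseases),
                                    rng.randint(0, 4))
                sentences.append(" ".join(tokens + ["end ."]))
            text = " ".join(sentences)
            spans = split_sentences(text)
            links = link_entities([("text", text)], lexes)
            bags = build_bags(links, spans, "Gene", "Disease")
            got = {b.pair: len(b.sentences) for b in bags}
            # oracle: brute-force pair x sentence containment check
            expected = {}
            for g, d in itertools.product(genes.values(),
                                          diseases.values()):
                count = 0
                for start, end in spans:
                    inside = [e for e in links
                              if start <= e.start and e.end <= end]
                    ids = {e.concept.identifier for e in inside}
                    if g.identifier in ids and d.identifier in ids:
                        count += 1
                if count:
                    expected[(g.identifier, d.identifier)] = count
            assert got == expected


class TestGdaPrediction:
    def test_scores_averaged_and_argmax_emitted(self):
        text = "TP53 is a biomarker of lung cancer. TP53 in lung cancer."
        spans = split_sentences(text)
        links = link_entities([("text", text)], [GENE_LEX, DISEASE_LEX])
        bags = build_bags(links, spans, "Gene", "Disease")

        class FixedScorer:
            task = "GDA"

            def score(self, sentence):
                if "biomarker" in sentence:
                    return {"Biomarker": 0.8}
                return {"Biomarker": 0.6}

        out = predict_gda(bags, FixedScorer(), text)
        assert len(out) == 1
        assert out[0].kind == "assertion"
        assert out[0].predicate.name == "Biomarker"
        assert out[0].score == pytest.approx(0.7)

    def test_all_na_bag_suppressed(self):
        text = "TP53 occurs near lung cancer."
        spans = split_sentences(text)
        links = link_entities([("text", text)], [GENE_LEX, DISEASE_LEX])
        bags = build_bags(links, spans, "Gene", "Disease")
        assert predict_gda(bags, default_gda_scorer(), text) == []

    def test_tie_breaks_by_vocabulary_order(self):
        text = "TP53 therapeutic biomarker lung cancer."
        spans = split_sentences(text)
        links = link_entities([("text", text)], [GENE_LEX, DISEASE_LEX])
        bags = build_bags(links, spans, "Gene", "Disease")
        out = predict_gda(bags, default_gda_scorer(), text)
        assert out[0].predicate.name == "Therapeutic"

    def test_wrong_scorer_task_rejected(self):
        with pytest.raises(ContractError):
            predict_gda([], TriggerScorer("GCA", {}), "")


class TestGcaPrediction:
    def test_trigger_maps_through_rule_table(self):
        text = "TP53 is downregulated and promotes lung cancer ."
        spans = split_sentences(text)
        links = link_entities([("text", text)], [GENE_LEX, DISEASE_LEX])
        out = predict_gca(spans, links, text)
        assert len(out) == 1
        rel = out[0]
        assert rel.kind == "relationship"
        assert rel.predicate.name == "tumor suppressor"
        assert rel.subject.positions == [("text", 0, 4)]
        assert rel.object.positions  # grounded object mention

    def test_gene_only_sentence_skipped(self):
        text = "TP53 is overexpressed and promotes growth ."
        spans = split_sentences(text)
        links = link_entities([("text", text)], [GENE_LEX, DISEASE_LEX])
        assert predict_gca(spans, links, text) == []

    def test_unmapped_aspect_combination_counted_in_skip_report(self):
        from annodesk.autoannotate import GcaSkipReport
        text = "TP53 occurs near lung cancer ."
        spans = split_sentences(text)
        links = link_entities([("text", text)], [GENE_LEX, DISEASE_LEX])
        report = GcaSkipReport()
        out = predict_gca(spans, links, text, skip_report=report)
        assert out == []
        assert report.no_rule_match == 1

    def test_rule_table_csv_roundtrip(self, tmp_path):
        path = tmp_path / "rules.csv"
        path.write_text("cge,ccs,gci,predicate\n"
                        "increased,progression,*,oncogene\n"
                        "none,*,*,\n", encoding="utf-8")
        table = RuleTable.from_csv(path)
        assert table.lookup("increased", "progression", "none") == \
            "oncogene"
        assert table.lookup("none", "progression", "observed") is None

    def test_default_rule_table_covers_all_predicates(self):
        table = default_rule_table()
        got = {table.lookup(cge, ccs, "observed")
               for cge in ("increased", "decreased")
               for ccs in ("progression", "regression", "none")}
        assert got == {"oncogene", "tumor suppressor", "biomarker"}


class TestRunAuto:
    def test_contract_violation_rejected_nothing_stored(self, collection):
        bad = AutoAnnotation(
            "assertion",
            AutoComponent("X:1", "x", "Gene"),
            AutoComponent("X:2", "pred", ""),  # missing type
            AutoComponent("X:3", "y", "Disease"))
        with pytest.raises(ContractError, match="concept_type"):
            validate_contract([bad])

    def test_unknown_task_rejected(self, collection):
        with pytest.raises(AnnotationError):
            run_auto(collection, "d1", "NER", [GENE_LEX])

    def test_rerun_replaces_machine_set(self):
        from annodesk.synthetic import GeneratorConfig, gen_corpus
        corpus = gen_corpus(GeneratorConfig(seed=13, n_documents=2))
        col = corpus.collection
        lexicons = list(corpus.lexicons.values())
        doc = sorted(col.documents)[0]
        first = run_auto(col, doc, "GCA", lexicons)
        second = run_auto(col, doc, "GCA", lexicons)
        assert first == second
        aset = col.annotation_set(AUTO_ANNOTATOR, doc)
        assert len(aset.relationships) == first

    def test_outputs_are_deterministic(self):
        from annodesk.io_formats import ExportRequest, export_annotations
        from annodesk.synthetic import GeneratorConfig, gen_corpus
        blobs = []
        for _ in range(2):
            corpus = gen_corpus(GeneratorConfig(seed=21, n_documents=3,
                                                task="both"))
            col = corpus.collection
            lexicons = list(corpus.lexicons.values())
            for doc in sorted(col.documents):
                for task in ("GCA", "GDA"):
                    run_auto(col, doc, task, lexicons)
            blobs.append(export_annotations(
                col, ExportRequest(fmt="json",
                                   annotator_id=AUTO_ANNOTATOR)))
        assert blobs[0] == blobs[1]
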
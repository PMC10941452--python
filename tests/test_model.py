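"""Data-model behaviour: spans, mentions, links, relationships,
assertions, labels, deletion cascades, copying, suggestions, rounds."""

import random

import pytest

from annodesk import (
    AnnotationError,
    Concept,
    Document,
    NotFoundError,
    OwnershipError,
    Section,
    concept_ref,
    mention_ref,
    text_predicate,
    token_boundaries,
)
from annodesk.model import identity_key


class TestMentions:
    def test_surface_recomputed_from_section(self, collection):
        m = collection.create_mention("alice", "d1", "text", 0, 5)
        assert m.span.surface == "BRCA1"
        m2 = collection.create_mention("alice", "d1", "text", 24, 37)
        assert m2.span.surface == "breast cancer"

    def test_overlapping_mentions_permitted(self, collection):
        collection.create_mention("alice", "d1", "text", 24, 37)
        inner = collection.create_mention("alice", "d1", "text", 24, 30)
        assert inner.span.surface == "breast"
        teammate = collection.create_mention("bob", "d1", "text", 24, 32)
        assert teammate.span.surface == "breast c"

    @pytest.mark.parametrize("start,end", [(5, 5), (7, 3), (-1, 4),
                                           (0, 999)])
    def test_invalid_spans_rejected(self, collection, start, end):
        with pytest.raises(AnnotationError):
            collection.create_mention("alice", "d1", "text", start, end)

    def test_unknown_section_and_non_member(self, collection):
        with pytest.raises(NotFoundError):
            collection.create_mention("alice", "d1", "missing", 0, 3)
        with pytest.raises(AnnotationError):
            collection.create_mention("mallory", "d1", "text", 0, 3)

    def test_token_boundary_helper(self):
        start, end = token_boundaries(
            "BRCA1 is an oncogene", 2, 4)
        assert (start, end) == (0, 5)


class TestAnnotateAll:
    def test_count_equals_substring_occurrences(self, collection):
        collection.add_document(Document(
            "d2", [Section("text", "BRCA1 and BRCA1 are BRCA1")]))
        got = collection.annotate_all_occurrences(
            "alice", "d2", "BRCA1", ["GENE:672"])
        assert len(got) == 3
        assert all(m.linked_concepts == ["GENE:672"] for m in got)

    def test_absent_surface_returns_empty(self, collection):
        assert collection.annotate_all_occurrences(
            "alice", "d1", "TP53") == []

    def test_existing_identical_annotation_not_duplicated(self, collection):
        collection.annotate_all_occurrences("alice", "d1", "oncogene")
        again = collection.annotate_all_occurrences("alice", "d1",
                                                    "oncogene")
        assert again == []

    def test_matches_naive_scan_oracle(self, collection):
        rng = random.Random(42)
        for trial in range(25):
            token = "TOK"
            words = [rng.choice(["filler", token, "pad", "xyz"])
                     for _ in range(rng.randint(5, 60))]
            text = " ".join(words)
            doc_id = f"rand-{trial}"
            collection.add_document(
                Document(doc_id, [Section("text", text)]))
            # oracle: naive left-to-right non-overlapping substring scan
            expected, pos = 0, text.find(token)
            while pos != -1:
                expected += 1
                pos = text.find(token, pos + len(token))
            got = collection.annotate_all_occurrences("alice", doc_id,
                                                      token)
            assert len(got) == expected

    def test_case_insensitive_flag(self, collection):
        collection.add_document(Document(
            "d3", [Section("text", "brca1 and BRCA1")]))
        got = collection.annotate_all_occurrences(
            "alice", "d3", "BRCA1", case_insensitive=True)
        assert [m.span.surface for m in got] == ["brca1", "BRCA1"]


class TestConceptLinking:
    def test_multiple_links_and_idempotence(self, collection):
        m = collection.create_mention("alice", "d1", "text", 24, 37)
        collection.link_concept("alice", m.mention_id, "MESH:D001943")
        assert len(m.linked_concepts) == 1
        collection.link_concept("alice", m.mention_id, "GENE:672")
        assert len(m.linked_concepts) == 2
        collection.link_concept("alice", m.mention_id, "MESH:D001943")
        assert len(m.linked_concepts) == 2

    def test_on_the_fly_concept_registration(self, collection):
        m = collection.create_mention("alice", "d1", "text", 0, 5)
        with pytest.raises(NotFoundError):
            collection.link_concept("alice", m.mention_id, "HGNC:1100")
        collection.link_concept(
            "alice", m.mention_id, "HGNC:1100",
            register_if_new=Concept("HGNC:1100", "BRCA1", "Gene"))
        assert "HGNC:1100" in collection.registry

    def test_cannot_link_on_teammates_mention(self, collection):
        m = collection.create_mention("bob", "d1", "text", 0, 5)
        with pytest.raises(OwnershipError):
            collection.link_concept("alice", m.mention_id, "GENE:672")


class TestRelationships:
    def test_worked_example_mixing_mentions_and_concept(
            self, collection, brca_relationship):
        subj, obj, rel = brca_relationship
        assert rel.subject.kind == "mention"
        assert rel.predicate == concept_ref("MESH:D009857")
        assert rel.object.kind == "mention"

    def test_all_concept_components_rejected(self, collection):
        with pytest.raises(AnnotationError, match="mention"):
            collection.create_relationship(
                "alice", "d1", concept_ref("GENE:672"),
                concept_ref("MESH:D009857"), concept_ref("MESH:D001943"))

    def test_single_mention_with_free_text_predicate_suffices(
            self, collection):
        obj = collection.create_mention("alice", "d1", "text", 24, 37)
        rel = collection.create_relationship(
            "alice", "d1", concept_ref("GENE:672"),
            text_predicate("inhibits"), mention_ref(obj.mention_id))
        assert rel.predicate.kind == "text"

    def test_free_text_forbidden_outside_predicate(self, collection):
        obj = collection.create_mention("alice", "d1", "text", 24, 37)
        with pytest.raises(AnnotationError):
            collection.create_relationship(
                "alice", "d1", text_predicate("x"),
                concept_ref("MESH:D009857"), mention_ref(obj.mention_id))

    def test_teammates_mention_not_usable(self, collection):
        other = collection.create_mention("bob", "d1", "text", 0, 5)
        with pytest.raises(NotFoundError):
            collection.create_relationship(
                "alice", "d1", mention_ref(other.mention_id),
                concept_ref("MESH:D009857"), concept_ref("MESH:D001943"))

    def test_self_relation_warns_but_is_permitted(self, collection):
        m = collection.create_mention("alice", "d1", "text", 0, 5)
        with pytest.warns(UserWarning, match="self-relation"):
            collection.create_relationship(
                "alice", "d1", mention_ref(m.mention_id),
                concept_ref("MESH:D009857"), mention_ref(m.mention_id))

    def test_change_role_swaps_subject_and_object(self, collection,
                                                  brca_relationship):
        subj, obj, rel = brca_relationship
        collection.change_role("alice", rel.relationship_id,
                               "subject", "object")
        assert rel.subject.ref == obj.mention_id
        assert rel.object.ref == subj.mention_id


class TestAssertions:
    def test_document_level_concept_triple(self, collection):
        a = collection.create_assertion("alice", "d1", "GENE:672",
                                        "MESH:D009857", "MESH:D001943")
        assert (a.subject, a.predicate, a.object) == (
            "GENE:672", "MESH:D009857", "MESH:D001943")

    def test_duplicate_assertion_is_idempotent(self, collection):
        a1 = collection.create_assertion("alice", "d1", "GENE:672",
                                         "MESH:D009857", "MESH:D001943")
        a2 = collection.create_assertion("alice", "d1", "GENE:672",
                                         "MESH:D009857", "MESH:D001943")
        assert a1.assertion_id == a2.assertion_id
        aset = collection.annotation_set("alice", "d1")
        assert len(aset.assertions) == 1

    def test_unknown_concept_rejected(self, collection):
        with pytest.raises(NotFoundError):
            collection.create_assertion("alice", "d1", "GENE:672",
                                        "nope", "MESH:D001943")


class TestLabels:
    def test_replace_semantics(self, collection):
        collection.set_labels("alice", "d1", {"relevant"})
        aset = collection.annotation_set("alice", "d1")
        assert [la.label for la in aset.labels.values()] == ["relevant"]
        collection.set_labels("alice", "d1", {"not-relevant"})
        assert [la.label for la in aset.labels.values()] == ["not-relevant"]
        collection.set_labels("alice", "d1", set())
        assert not aset.labels

    def test_label_outside_collection_set_rejected(self, collection):
        with pytest.raises(AnnotationError):
            collection.set_labels("alice", "d1", {"unknown-label"})


class TestDeletion:
    def test_mention_deletion_cascades_to_relationships(
            self, collection, brca_relationship):
        subj, obj, rel = brca_relationship
        report = collection.delete_annotation("alice", subj.mention_id)
        assert report.deleted_mentions == [subj.mention_id]
        assert report.deleted_relationships == [rel.relationship_id]
        aset = collection.annotation_set("alice", "d1")
        assert not aset.relationships
        assert obj.mention_id in aset.mentions

    def test_label_deletion_is_isolated(self, collection):
        collection.set_labels("alice", "d1", {"relevant"})
        aset = collection.annotation_set("alice", "d1")
        lid = next(iter(aset.labels))
        report = collection.delete_annotation("alice", lid)
        assert report.total == 1

    def test_double_delete_errors(self, collection):
        m = collection.create_mention("alice", "d1", "text", 0, 5)
        collection.delete_annotation("alice", m.mention_id)
        with pytest.raises(NotFoundError):
            collection.delete_annotation("alice", m.mention_id)

    def test_cannot_delete_teammates_annotation(self, collection):
        m = collection.create_mention("bob", "d1", "text", 0, 5)
        with pytest.raises(OwnershipError):
            collection.delete_annotation("alice", m.mention_id)


class TestCopy:
    def test_copy_mentions_into_empty_set(self, collection):
        for span in [(0, 5), (12, 20), (24, 37)]:
            collection.create_mention("alice", "d1", "text", *span)
        assert collection.copy_annotations("d1", "alice", "bob") == 3

    def test_relationship_copy_pulls_component_mentions(
            self, collection, brca_relationship):
        subj, obj, rel = brca_relationship
        added = collection.copy_annotations(
            "d1", "alice", "bob", [rel.relationship_id])
        assert added == 3  # relationship + its two mentions
        bob = collection.annotation_set("bob", "d1")
        assert len(bob.mentions) == 2 and len(bob.relationships) == 1
        key_alice = identity_key(rel, collection.annotation_set(
            "alice", "d1"))
        key_bob = identity_key(next(iter(bob.relationships.values())), bob)
        assert key_alice == key_bob

    def test_copy_is_idempotent(self, collection, brca_relationship):
        collection.copy_annotations("d1", "alice", "bob")
        state = collection.canonical_round_state(1)
        assert collection.copy_annotations("d1", "alice", "bob") == 0
        assert collection.canonical_round_state(1) == state


class TestSuggestions:
    def test_counts_sorted_desc_and_own_links_excluded(self, collection):
        spans = {}
        for who in ("alice", "bob", "carol"):
            spans[who] = collection.create_mention(who, "d1", "text",
                                                   24, 37)
        collection.link_concept("bob", spans["bob"].mention_id,
                                "MESH:D001943")
        collection.link_concept("carol", spans["carol"].mention_id,
                                "MESH:D001943")
        collection.link_concept("carol", spans["carol"].mention_id,
                                "GENE:672")
        collection.link_concept("alice", spans["alice"].mention_id,
                                "MESH:D009857")  # own link, excluded
        ranked = collection.suggest_concepts(
            "alice", spans["alice"].mention_id)
        assert [(c.identifier, n) for c, n in ranked] == [
            ("MESH:D001943", 2), ("GENE:672", 1)]

    def test_no_teammate_annotations_yields_empty(self, collection):
        m = collection.create_mention("alice", "d1", "text", 0, 5)
        assert collection.suggest_concepts("alice", m.mention_id) == []


class TestRounds:
    def test_new_round_duplicates_for_carried_members(self, collection):
        for span in [(0, 5), (24, 37)]:
            collection.create_mention("alice", "d1", "text", *span)
        collection.set_labels("alice", "d1", {"relevant"})
        rnd = collection.new_round("alice", {"alice", "bob"})
        assert rnd.round_index == 2
        aset = collection.annotation_set("alice", "d1", 2)
        assert len(aset.mentions) == 2 and len(aset.labels) == 1

    def test_rounds_are_isolated_after_creation(self, collection):
        m = collection.create_mention("alice", "d1", "text", 0, 5)
        collection.new_round("alice", {"alice"})
        before = collection.canonical_round_state(1)
        aset2 = collection.annotation_set("alice", "d1", 2)
        mid2 = next(iter(aset2.mentions))
        collection.delete_annotation("alice", mid2, round_index=2)
        collection.create_mention("alice", "d1", "text", 12, 20,
                                  round_index=2)
        assert collection.canonical_round_state(1) == before
        assert m.mention_id in collection.annotation_set(
            "alice", "d1", 1).mentions

    def test_new_member_starts_empty(self, collection):
        collection.create_mention("alice", "d1", "text", 0, 5)
        collection.new_round("alice", {"alice", "dave"})
        assert collection.annotation_set("dave", "d1", 2).is_empty()

    def test_only_creator_may_open_rounds(self, collection):
        with pytest.raises(OwnershipError):
            collection.new_round("bob", {"bob"})


def test_referential_integrity_after_random_operations(collection):
    """Randomized operation sequences never leave dangling references."""
    rng = random.Random(7)
    annotators = ["alice", "bob", "carol"]
    for _ in range(300):
        who = rng.choice(annotators)
        aset = collection.annotation_set(who, "d1")
        op = rng.random()
        if op < 0.4:
            start = rng.randrange(0, len("BRCA1 is an oncogene"))
            end = rng.randrange(start + 1, start + 10)
            try:
                collection.create_mention(who, "d1", "text", start, end)
            except AnnotationError:
                pass
        elif op < 0.6 and aset.mentions:
            mid = rng.choice(sorted(aset.mentions))
            collection.link_concept(who, mid, rng.choice(
                ["GENE:672", "MESH:D001943", "MESH:D009857"]))
        elif op < 0.75 and aset.mentions:
            mid = rng.choice(sorted(aset.mentions))
            collection.create_relationship(
                who, "d1", mention_ref(mid),
                concept_ref("MESH:D009857"), concept_ref("MESH:D001943"))
        elif op < 0.9 and aset.all_ids():
            collection.delete_annotation(who,
                                         rng.choice(sorted(aset.all_ids())))
        else:
            other = rng.choice([a for a in annotators if a != who])
            collection.copy_annotations("d1", other, who)
    collection.validate()
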
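"""Agreement statistics against independent brute-force oracles and
library implementations."""

import itertools
import random

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

from annodesk import (
    cohen_kappa,
    fleiss_kappa,
    fleiss_for,
    majority_vote,
    pairwise_cohen,
    unitize,
)
from annodesk.agreement import ABSENT, PRESENT, RatingTable, filter_items
from annodesk.model import AnnotationError


# -- independent textbook-formula oracles (plain Python, no numpy) ----------

def fleiss_oracle(counts):
    counts = [list(map(int, row)) for row in counts]
    n = sum(counts[0])
    big_n = len(counts)
    p_is = [(sum(c * c for c in row) - n) / (n * (n - 1))
            for row in counts]
    p_bar = sum(p_is) / big_n
    p_js = [sum(row[j] for row in counts) / (big_n * n)
            for j in range(len(counts[0]))]
    p_e = sum(p * p for p in p_js)
    if p_e == 1.0:
        return 1.0 if p_bar == 1.0 else None
    return (p_bar - p_e) / (1.0 - p_e)


def cohen_oracle(a, b):
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    if p_o == 1.0:
        return 1.0
    cats = set(a) | set(b)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    return (p_o - p_e) / (1.0 - p_e)


def random_table(rng):
    n_items = rng.integers(1, 25)
    n_cats = rng.integers(2, 6)
    n_raters = rng.integers(2, 7)
    counts = rng.multinomial(n_raters, np.ones(n_cats) / n_cats,
                             size=n_items)
    return RatingTable(list(range(n_items)), list(range(n_cats)), counts,
                       int(n_raters))


class TestFleiss:
    def test_hand_derived_one_third_table(self):
        table = RatingTable(list("wxyz"), ["a", "b"],
                            [[3, 0], [0, 3], [2, 1], [1, 2]], 3)
        kappa = fleiss_kappa(table)
        assert kappa == pytest.approx(1 / 3, abs=1e-12)
        assert sm_fleiss(np.asarray(table.counts)) == pytest.approx(
            kappa, abs=1e-12)

    def test_perfect_agreement_is_exactly_one(self):
        table = RatingTable([1, 2], ["a", "b"], [[3, 0], [0, 3]], 3)
        assert fleiss_kappa(table) == 1.0
        # single-category degenerate case is perfect by definition
        assert fleiss_kappa(
            RatingTable([1, 2], ["a"], [[3], [3]], 3)) == 1.0

    def test_empty_table_undefined(self):
        table = RatingTable([], [], np.zeros((0, 0)), 3)
        assert fleiss_kappa(table) is None

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            table = random_table(rng)
            got = fleiss_kappa(table)
            want = fleiss_oracle(table.counts)
            assert got == pytest.approx(want, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        table = random_table(rng)
        base = fleiss_kappa(table)
        for _ in range(10):
            rows = rng.permutation(table.n_items)
            cols = rng.permutation(len(table.categories))
            shuffled = RatingTable(
                [table.items[i] for i in rows],
                [table.categories[j] for j in cols],
                table.counts[np.ix_(rows, cols)], table.n_raters)
            assert fleiss_kappa(shuffled) == pytest.approx(base, abs=1e-12)


class TestCohen:
    def test_rater_against_itself(self):
        labels = list("abcabcab")
        assert cohen_kappa(labels, labels) == 1.0

    def test_hand_derived_half(self):
        assert cohen_kappa(list("xxyy"), list("xyyy")) == pytest.approx(
            0.5, abs=1e-12)

    def test_floor_minus_one(self):
        assert cohen_kappa(["x", "y"], ["y", "x"]) == pytest.approx(
            -1.0, abs=1e-12)

    def test_empty_undefined_and_length_mismatch(self):
        assert cohen_kappa([], []) is None
        with pytest.raises(AnnotationError):
            cohen_kappa(["x"], ["x", "y"])

    def test_matches_oracle_and_sklearn(self):
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(1, 40)
            cats = "abcd"[:rng.randint(2, 4)]
            a = [rng.choice(cats) for _ in range(n)]
            b = [rng.choice(cats) for _ in range(n)]
            got = cohen_kappa(a, b)
            want = cohen_oracle(a, b)
            if want is not None:
                assert got == pytest.approx(want, abs=1e-12)
                sk = cohen_kappa_score(a, b)
                if np.isfinite(sk) and set(a) | set(b) != set(a) & set(b):
                    continue  # sklearn treats one-sided categories oddly
                if np.isfinite(sk):
                    assert got == pytest.approx(sk, abs=1e-12)


class TestUnitize:
    def test_concept_links_present_absent(self, collection):
        spans = {who: collection.create_mention(who, "d1", "text", 24, 37)
                 for who in ("alice", "bob", "carol")}
        collection.link_concept("alice", spans["alice"].mention_id,
                                "MESH:D001943")
        collection.link_concept("bob", spans["bob"].mention_id,
                                "MESH:D001943")
        sets = {who: [collection.annotation_set(who, "d1")]
                for who in ("alice", "bob", "carol")}
        table = unitize(sets, "concept")
        assert table.n_items == 1
        assert sorted(table.categories) == [ABSENT, PRESENT]
        assert sorted(table.counts[0].tolist()) == [1, 2]

    def test_relationship_predicate_categories(self, collection):
        from annodesk import concept_ref, mention_ref
        for who, pred in (("alice", "MESH:D009857"),
                          ("bob", "MESH:D009857"),
                          ("carol", "MESH:D001943")):
            subj = collection.create_mention(who, "d1", "text", 0, 5)
            obj = collection.create_mention(who, "d1", "text", 24, 37)
            collection.create_relationship(
                who, "d1", mention_ref(subj.mention_id),
                concept_ref(pred), mention_ref(obj.mention_id))
        sets = {who: [collection.annotation_set(who, "d1")]
                for who in ("alice", "bob", "carol")}
        table = unitize(sets, "relationship")
        assert table.n_items == 1
        assert sorted(table.counts[0].tolist(), reverse=True) == [2, 1]

    def test_fewer_than_two_annotators_rejected(self, collection):
        with pytest.raises(AnnotationError):
            unitize({"alice": []}, "mention")

    def test_empty_sets_give_empty_table(self, collection):
        table = unitize({"alice": [], "bob": []}, "mention")
        assert table.n_items == 0
        assert fleiss_kappa(table) is None


class TestMajorityVote:
    @pytest.mark.parametrize("n,support,included", [
        (3, 2, True),   # 2 > 1.5
        (4, 2, False),  # 2 is not > 2
        (1, 1, True),   # 1 > 0.5
        (5, 3, True),
    ])
    def test_strict_majority_boundaries(self, collection, n, support,
                                        included):
        annotators = ["alice", "bob", "carol", "dave", "eve"][:n]
        for extra in annotators:
            collection.member_ids.add(extra)
        for i, who in enumerate(annotators):
            if i < support:
                collection.create_mention(who, "d1", "text", 0, 5)
            else:
                collection.create_mention(who, "d1", "text", 24, 37)
        consensus = majority_vote(collection, "d1", "mention")
        keys = [key for key, _count in consensus.entries]
        assert (("d1", "text", 0, 5) in keys) is included

    def test_matches_bruteforce_on_random_fixtures(self, collection):
        rng = random.Random(11)
        spans = [(0, 5), (6, 8), (12, 20), (24, 37), (24, 30)]
        annotators = ["alice", "bob", "carol", "dave", "eve"]
        for who in annotators:
            collection.member_ids.add(who)
        for trial in range(30):
            n = rng.randint(1, 5)
            chosen = annotators[:n]
            held = {who: set(rng.sample(spans, rng.randint(1, len(spans))))
                    for who in chosen}
            for who in chosen:
                collection.clear_annotator_document(who, "d1")
                for span in held[who]:
                    collection.create_mention(who, "d1", "text", *span)
            for who in annotators[n:]:
                collection.clear_annotator_document(who, "d1")
            consensus = majority_vote(collection, "d1", "mention")
            # oracle: brute-force support counting over identity keys
            expected = {("d1", "text", s, e)
                        for (s, e) in spans
                        if sum((s, e) in held[w] for w in chosen) * 2 > n}
            assert {k for k, _c in consensus.entries} == expected
            assert consensus.n_annotators == n


class TestScopedAgreement:
    def test_identical_annotators_reach_kappa_one_per_type(
            self, collection, brca_relationship):
        collection.set_labels("alice", "d1", {"relevant"})
        collection.create_assertion("alice", "d1", "GENE:672",
                                    "MESH:D009857", "MESH:D001943")
        m = collection.annotation_set("alice", "d1").mentions
        collection.link_concept("alice", sorted(m)[0], "GENE:672")
        collection.copy_annotations("d1", "alice", "bob")
        collection.set_labels("bob", "d1", {"relevant"})
        for annotation_type in ("mention", "concept", "relationship",
                                "assertion", "label"):
            report = fleiss_for(collection, annotation_type,
                                document_id="d1")
            assert report.kappa == 1.0

    def test_disjoint_pair_has_nonpositive_cohen(self, collection):
        collection.create_mention("alice", "d1", "text", 0, 5)
        collection.create_mention("bob", "d1", "text", 24, 37)
        report = pairwise_cohen(collection, "alice", "bob", "mention",
                                document_id="d1")
        assert report.kappa is not None and report.kappa <= 0

    def test_self_pair_rejected(self, collection):
        with pytest.raises(AnnotationError):
            pairwise_cohen(collection, "alice", "alice", "mention")

    def test_single_annotator_round_reported_undefined(self, collection):
        collection.create_mention("alice", "d1", "text", 0, 5)
        report = fleiss_for(collection, "mention")
        assert report.kappa is None
        assert report.n_raters == 1


def test_filter_items_restricts_universe():
    table = RatingTable(["a", "b", "c"], ["x", "y"],
                        [[3, 0], [0, 3], [2, 1]], 3)
    sub = filter_items(table, lambda item: item != "c")
    assert sub.items == ["a", "b"]
    assert fleiss_kappa(sub) == 1.0
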
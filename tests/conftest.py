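"""Shared fixtures: a small hand-built collection and seeded generators."""

import pytest

from annodesk import Collection, Concept, Document, Section
from annodesk.synthetic import fixed_clock

TEXT = "BRCA1 is an oncogene in breast cancer"


@pytest.fixture
def collection():
    """Three-member collection with one document and a tiny registry."""
    col = Collection("c1", "demo", "demo collection", "alice",
                     member_ids=["bob", "carol"],
                     labels=["relevant", "not-relevant"],
                     clock=fixed_clock)
    col.add_document(Document("d1", [Section("text", TEXT)]))
    col.register_concept(Concept("GENE:672", "BRCA1", "Gene"))
    col.register_concept(
        Concept("MESH:D001943", "Breast Neoplasms", "Disease"))
    col.register_concept(Concept("MESH:D009857", "Oncogenes", "Concept"))
    return col


@pytest.fixture
def brca_relationship(collection):
    """The worked example: subject mention BRCA1, concept predicate
    Oncogenes, object mention breast cancer."""
    from annodesk import concept_ref, mention_ref
    subj = collection.create_mention("alice", "d1", "text", 0, 5)
    obj = collection.create_mention("alice", "d1", "text", 24, 37)
    rel = collection.create_relationship(
        "alice", "d1", mention_ref(subj.mention_id),
        concept_ref("MESH:D009857"), mention_ref(obj.mention_id))
    return subj, obj, rel
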
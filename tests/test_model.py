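"""Object-model semantics: equality ignores ids, normalization is canonical."""

import copy
from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from psimif import fixtures, model as m, xml_io


def _renumber(doc: m.Document, offset: int) -> m.Document:
    doc = copy.deepcopy(doc)
    for entry in doc.entries:
        for obj in m.iter_identified(entry):
            obj.id += offset
    return doc


def test_empty_documents_are_equal():
    a = m.Document(entries=[m.Entry()])
    b = m.Document(entries=[m.Entry()])
    assert m.semantic_equal(a, b).equal


def test_id_values_are_not_semantic():
    doc = fixtures.build_use_case("f")
    shifted = _renumber(doc, 100)
    assert m.semantic_equal(doc, shifted).equal


def test_stoichiometry_change_yields_one_participant_diff():
    doc = fixtures.build_use_case("j")
    other = copy.deepcopy(doc)
    p = other.entries[0].interactions[0].participants[0]
    assert isinstance(p.stoichiometry, m.MeanStoichiometry)
    p.stoichiometry = m.StoichiometryRange(Decimal(2), Decimal(4))
    result = m.semantic_equal(doc, other)
    assert not result.equal
    assert len(result.diffs) == 1
    assert "participants[0].stoichiometry" in result.diffs[0].path


def test_attribute_order_is_not_semantic():
    doc = fixtures.build_use_case("k")
    other = copy.deepcopy(doc)
    exp = other.entries[0].experiments[0]
    exp.bibref.attributes.reverse()
    assert m.semantic_equal(doc, other).equal


def test_normalize_renumbers_densely_and_preserves_references():
    doc = fixtures.build_use_case("a")
    scrambled = _renumber(doc, 1000)
    norm = m.normalize(scrambled)
    ids = [obj.id for entry in norm.entries for obj in m.iter_identified(entry)]
    assert ids == list(range(1, len(ids) + 1))
    assert m.semantic_equal(norm, doc).equal


def test_normalize_is_idempotent_to_the_byte():
    spec = fixtures.GeneratorSpec(seed=7, feature_flags=fixtures.all_flags())
    doc = fixtures.generate_random(spec)
    once = m.normalize(doc)
    twice = m.normalize(once)
    assert (xml_io.write_mif(once, normalize=False)
            == xml_io.write_mif(twice, normalize=False))


def test_normalize_keeps_duplicate_attributes():
    doc = fixtures.build_use_case("b")
    inter = doc.entries[0].interactions[0]
    inter.attributes = [m.Attribute(name="comment", value="dup"),
                        m.Attribute(name="comment", value="dup")]
    norm = m.normalize(doc)
    assert len(norm.entries[0].interactions[0].attributes) == 2


def test_normalize_keeps_unreferenced_pool_objects():
    doc = fixtures.build_use_case("j")
    doc.entries[0].interactors.append(m.Interactor(
        names=m.Names(short_label="orphan"),
        interactor_type=m.CvTerm(short_label="protein",
                                 mi_accession="MI:0326")))
    norm = m.normalize(doc)
    labels = [i.names.short_label for i in norm.entries[0].interactors]
    assert "orphan" in labels


@pytest.mark.parametrize("seed", [0, 3, 11])
def test_semantic_equal_is_an_equivalence_relation(seed):
    spec = fixtures.GeneratorSpec(seed=seed, feature_flags=fixtures.all_flags())
    a = m.normalize(fixtures.generate_random(spec))
    b = _renumber(a, 50)
    c = copy.deepcopy(b)
    assert m.semantic_equal(a, a).equal          # reflexive
    assert m.semantic_equal(a, b).equal == m.semantic_equal(b, a).equal  # symmetric
    assert m.semantic_equal(a, b).equal and m.semantic_equal(b, c).equal
    assert m.semantic_equal(a, c).equal          # transitive


def test_reference_graph_is_closed_in_serialized_form():
    """Every id referenced in a written document must also be defined."""
    import re

    spec = fixtures.GeneratorSpec(seed=5, feature_flags=fixtures.all_flags())
    data = xml_io.write_mif(fixtures.generate_random(spec)).decode()
    defined = set(re.findall(r'id="(\d+)"', data))
    referenced = set(re.findall(r"Ref>(\d+)<", data))
    assert referenced <= defined


@settings(derandomize=True, max_examples=30)
@given(st.permutations(list(range(4))))
def test_secondary_xref_order_is_not_semantic(perm):
    refs = [m.DbReference(db="demo", id=f"x{i}") for i in range(4)]
    a = m.Document(entries=[m.Entry(source=m.Source(
        xref=m.Xref(primary=m.DbReference(db="demo", id="p"),
                    secondary=list(refs))))])
    b = m.Document(entries=[m.Entry(source=m.Source(
        xref=m.Xref(primary=m.DbReference(db="demo", id="p"),
                    secondary=[refs[i] for i in perm])))])
    assert m.semantic_equal(a, b).equal


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10**6),
       st.sets(st.sampled_from(fixtures.FLAGS), max_size=len(fixtures.FLAGS)))
def test_normalize_preserves_semantics_of_random_documents(seed, flags):
    spec = fixtures.GeneratorSpec(seed=seed, feature_flags=frozenset(flags))
    doc = fixtures.generate_random(spec)
    assert m.semantic_equal(m.normalize(doc), doc).equal
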
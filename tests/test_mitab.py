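"""MITAB 2.7 export: spoke expansion arithmetic and row shape."""

import pytest

from psimif import fixtures, mitab, model as m


def _nary_interaction(n: int, bait_index: int | None = None):
    doc = fixtures.build_use_case("j")
    entry = doc.entries[0]
    itors = [m.Interactor(
        names=m.Names(short_label=f"p{i}"),
        xref=m.Xref(primary=m.DbReference(db="demo", id=f"n-{i:03d}")),
        interactor_type=m.CvTerm(short_label="protein",
                                 mi_accession="MI:0326"))
        for i in range(n)]
    parts = []
    for i, itor in enumerate(itors):
        role = (m.CvTerm(short_label="bait", mi_accession="MI:0496")
                if i == bait_index
                else m.CvTerm(short_label="prey", mi_accession="MI:0498"))
        parts.append(m.Participant(entity=itor, experimental_roles=[role]))
    inter = m.InteractionEvidence(
        experiments=[entry.experiments[0]], participants=parts,
        interaction_types=[m.CvTerm(short_label="physical association",
                                    mi_accession="MI:0915")])
    entry.interactors = itors
    entry.interactions = [inter]
    return m.normalize(doc), inter


def test_two_participants_expand_to_one_unexpanded_pair():
    _, inter = _nary_interaction(2)
    pairs = mitab.expand_binary(inter)
    assert len(pairs) == 1 and pairs[0].expansion == "none"


def test_five_participants_with_bait_give_four_bait_pairs():
    _, inter = _nary_interaction(5, bait_index=2)
    pairs = mitab.expand_binary(inter)
    assert len(pairs) == 4
    bait = inter.participants[2]
    assert all(p.a is bait for p in pairs)
    assert all(p.expansion == "spoke" for p in pairs)


def test_three_participants_without_bait_hub_on_first_deterministically():
    _, inter = _nary_interaction(3)
    pairs = mitab.expand_binary(inter)
    assert [p.b for p in pairs] == inter.participants[1:]
    assert all(p.a is inter.participants[0] for p in pairs)


def test_single_intramolecular_participant_gives_a_self_pair():
    _, inter = _nary_interaction(1)
    inter.intra_molecular = True
    pairs = mitab.expand_binary(inter)
    assert len(pairs) == 1 and pairs[0].a is pairs[0].b


def test_zero_participants_is_an_error():
    _, inter = _nary_interaction(2)
    inter.participants = []
    with pytest.raises(ValueError):
        mitab.expand_binary(inter)


def test_empty_document_yields_header_comment_only():
    out = mitab.write_mitab(m.Document(entries=[m.Entry()]))
    lines = out.splitlines()
    assert len(lines) == 1 and lines[0].startswith("#")


def test_binary_interaction_yields_one_row_with_identifier_columns():
    doc, _ = _nary_interaction(2)
    rows = mitab.write_mitab(doc).splitlines()[1:]
    assert len(rows) == 1
    cols = rows[0].split("\t")
    assert cols[0] == "demo:n-000" and cols[1] == "demo:n-001"


def test_four_participants_give_three_rows_sharing_the_interaction_id():
    doc, _ = _nary_interaction(4)
    rows = [r.split("\t") for r in mitab.write_mitab(doc).splitlines()[1:]]
    assert len(rows) == 3
    assert len({row[13] for row in rows}) == 1
    assert all(row[15] == 'psi-mi:"MI:1060"(spoke expansion)' for row in rows)


def test_every_row_has_exactly_42_columns(random_docs):
    for doc in random_docs:
        for line in mitab.write_mitab(doc).splitlines():
            assert len(line.split("\t")) == 42


def test_row_count_matches_the_spoke_arithmetic(random_docs):
    for doc in random_docs:
        expected = 0
        for entry in m.normalize(doc).entries:
            for inter in entry.interactions:
                if isinstance(inter, m.AbstractInteraction):
                    continue
                n = len(inter.participants)
                expected += 1 if n <= 2 else n - 1
        rows = mitab.write_mitab(doc).splitlines()[1:]
        assert len(rows) == expected


def test_free_text_cannot_leak_tabs_pipes_or_newlines():
    doc, inter = _nary_interaction(2)
    inter.attributes.append(m.Attribute(name="comment",
                                        value="evil\tvalue|with\nbreaks"))
    target = doc.entries[0].interactions[0]
    target.attributes.append(m.Attribute(name="comment",
                                         value="evil\tvalue|with\nbreaks"))
    out = mitab.write_mitab(doc)
    data_rows = out.splitlines()[1:]
    assert all(len(r.split("\t")) == 42 for r in data_rows)
    assert "evil value" in out


def test_negative_interactions_are_exported_with_negative_true():
    doc, _ = _nary_interaction(2)
    doc.entries[0].interactions[0].negative = True
    row = mitab.write_mitab(doc).splitlines()[1].split("\t")
    assert row[35] == "true"


def test_abstract_interactions_are_skipped():
    doc = fixtures.build_use_case("g")  # abstract complex only
    assert mitab.write_mitab(doc).splitlines()[1:] == []


def test_candidate_set_exports_set_identity_with_members_as_aliases():
    doc = fixtures.build_use_case("i")
    row = mitab.write_mitab(doc).splitlines()[1].split("\t")
    assert row[1] == "psimif:calmodulin"
    assert "calm1" in row[5] and "calm3" in row[5]
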
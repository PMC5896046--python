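"""Reader/writer behaviour: level detection, both document forms,
reference resolution, lexical fidelity, strictness."""

import gzip
import re

import pytest

from psimif import fixtures, model as m, xml_io


def test_detect_level_30_and_25():
    doc30 = fixtures.build_use_case("j")
    assert xml_io.detect_level(xml_io.write_mif(doc30)) == "3.0"
    from psimif import convert25

    doc25, _ = convert25.downgrade(doc30)
    assert xml_io.detect_level(xml_io.write_mif(doc25)) == "2.5"


def test_unknown_namespace_is_named_in_the_error():
    data = b'<entrySet xmlns="urn:something-else" level="9" version="9"/>'
    with pytest.raises(xml_io.UnknownNamespaceError) as exc:
        xml_io.detect_level(data)
    assert "urn:something-else" in str(exc.value)


def test_compact_interactions_share_one_experiment_object():
    doc = fixtures.build_use_case("f")  # two interactions, one experiment
    rr = xml_io.read_mif(xml_io.write_mif(doc, form="compact"), strict=True)
    i1, i2 = rr.document.entries[0].interactions
    assert i1.experiments[0] is i2.experiments[0]


def test_extended_form_reads_to_the_same_graph_as_compact():
    for case in fixtures.USE_CASES:
        doc = fixtures.build_use_case(case)
        compact = xml_io.read_mif(xml_io.write_mif(doc, form="compact"))
        extended = xml_io.read_mif(xml_io.write_mif(doc, form="extended"))
        assert m.semantic_equal(compact.document, extended.document).equal, case


def test_negative_promoter_positions_survive_a_round_trip():
    doc = fixtures.build_use_case("a")
    rr = xml_io.read_mif(xml_io.write_mif(doc), strict=True)
    feature = rr.document.entries[0].interactions[0].participants[1].features[0]
    r = feature.ranges[0]
    assert r.begin == m.ExactPosition(-2000)
    assert r.end == m.ExactPosition(-1)


def test_repeated_detection_methods_keep_document_order():
    doc = fixtures.build_use_case("c")
    rr = xml_io.read_mif(xml_io.write_mif(doc), strict=True)
    feature = rr.document.entries[0].interactions[0].participants[0].features[0]
    accs = [dm.mi_accession for dm in feature.detection_methods]
    assert accs == ["MI:0113", "MI:0114"]


def test_bibref_with_both_xref_and_attributes_serializes_inside_bibref():
    data = xml_io.write_mif(fixtures.build_use_case("k")).decode()
    bib = re.search(r"<bibref>.*?</bibref>", data, re.S).group(0)
    assert "<primaryRef" in bib and "<attribute " in bib
    rr = xml_io.read_mif(data.encode(), strict=True)
    bibref = rr.document.entries[0].experiments[0].bibref
    assert bibref.xref is not None and len(bibref.attributes) == 2


def test_cooperative_effect_round_trips_with_kind_outcome_and_targets():
    doc = fixtures.build_use_case("h")
    rr = xml_io.read_mif(xml_io.write_mif(doc), strict=True)
    complexes = [i for i in rr.document.entries[0].interactions
                 if isinstance(i, m.AbstractInteraction)
                 and i.cooperative_effects]
    assert len(complexes) == 1
    effect = complexes[0].cooperative_effects[0]
    assert isinstance(effect, m.Allostery)
    assert effect.outcome.mi_accession == "MI:1154"
    assert len(effect.affected) == 1
    assert effect.affected[0] in rr.document.entries[0].interactions
    assert isinstance(effect.effector, m.MoleculeEffector)
    assert effect.allosteric_molecule in complexes[0].participants


def test_empty_single_entry_document_round_trips():
    doc = m.Document(entries=[m.Entry()])
    data = xml_io.write_mif(doc)
    assert xml_io.xsd_validate(data) == []
    rr = xml_io.read_mif(data, strict=True)
    assert m.semantic_equal(rr.document, m.normalize(doc)).equal


def test_decimal_lexical_forms_survive_a_round_trip():
    from decimal import Decimal

    doc = fixtures.build_use_case("j")
    p = doc.entries[0].interactions[0].participants[0]
    p.stoichiometry = m.MeanStoichiometry(Decimal("2.50"))
    data = xml_io.write_mif(doc).decode()
    assert 'stoichiometry value="2.50"' in data
    rr = xml_io.read_mif(data.encode(), strict=True)
    back = [pp.stoichiometry
            for i in rr.document.entries[0].interactions
            for pp in i.participants
            if isinstance(pp.stoichiometry, m.MeanStoichiometry)]
    assert str(back[0].value) == "2.50"
    # parameter factors keep their printed precision too
    data_e = xml_io.write_mif(fixtures.build_use_case("e")).decode()
    assert 'factor="4.0"' in data_e and 'factor="2.0"' in data_e


def test_gzip_streams_are_sniffed_from_magic_bytes():
    doc = fixtures.build_use_case("i")
    plain = xml_io.write_mif(doc)
    rr = xml_io.read_mif(gzip.compress(plain))
    assert not rr.fatal
    assert m.semantic_equal(rr.document, m.normalize(doc)).equal


def test_dangling_reference_is_fatal_only_in_strict_mode():
    data = xml_io.write_mif(fixtures.build_use_case("a"))
    bad = re.sub(rb"<interactorRef>\d+</", rb"<interactorRef>999</", data,
                 count=1)
    strict = xml_io.read_mif(bad, strict=True)
    assert strict.fatal
    assert strict.findings[0].code == "DANGLING_REF"
    assert "999" in strict.findings[0].message
    lenient = xml_io.read_mif(bad, strict=False)
    assert not lenient.fatal
    assert [f.code for f in lenient.findings] == ["DANGLING_REF"]


def test_malformed_xml_reports_parse_error_with_line():
    rr = xml_io.read_mif(b"<entrySet><oops")
    assert rr.fatal
    assert rr.findings[0].code == "PARSE_ERROR"
    assert "line" in rr.findings[0].message


def test_writer_refuses_level25_documents_with_30_content():
    doc = fixtures.build_use_case("g")
    doc.level = "2.5"
    with pytest.raises(xml_io.Level30ContentError) as exc:
        xml_io.write_mif(doc)
    assert "downgrade" in str(exc.value)


def test_compact_output_defines_each_experiment_and_interactor_once():
    spec = fixtures.GeneratorSpec(seed=9, feature_flags=fixtures.all_flags())
    data = xml_io.write_mif(fixtures.generate_random(spec)).decode()
    exp_ids = re.findall(r'<experimentDescription id="(\d+)"', data)
    itor_ids = re.findall(r'<interactor id="(\d+)"', data)
    assert len(exp_ids) == len(set(exp_ids))
    assert len(itor_ids) == len(set(itor_ids))


def test_written_documents_conform_to_the_structural_schema(goldens):
    for g in goldens:
        for form in ("compact", "extended"):
            assert xml_io.xsd_validate(
                xml_io.write_mif(g.document, form=form)) == [], g.case
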
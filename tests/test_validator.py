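"""Semantic validation: one targeted mutation per finding code, clean
golden fixtures, determinism, suppression, and the CV store."""

import copy
import io
from decimal import Decimal

import pytest

from psimif import fixtures, model as m, validator, xml_io


def _golden(case: str) -> m.Document:
    return fixtures.build_use_case(case)


# each mutator breaks exactly one rule on an otherwise clean document
def _mut_cvterm_empty(doc):
    doc.entries[0].interactions[0].interaction_types[0] = m.CvTerm()


def _mut_cv_format(doc):
    doc.entries[0].interactions[0].interaction_types[0].mi_accession = "MI:99"


def _mut_cv_unknown(doc):
    doc.entries[0].interactions[0].interaction_types[0].mi_accession = "MI:9999"


def _mut_xref_incomplete(doc):
    doc.entries[0].interactors[0].xref.primary.id = ""


def _mut_bibref_empty(doc):
    doc.entries[0].experiments[0].bibref = m.BibRef()


def _mut_experiment_incomplete(doc):
    doc.entries[0].experiments[0].interaction_detection_method = None


def _mut_taxid_zero(doc):
    doc.entries[0].interactors[0].organism.ncbi_tax_id = 0


def _mut_param_invalid(doc):
    doc.entries[0].interactions[0].parameters = [
        m.Parameter(term="kd", base=1, factor=Decimal("1"))]


def _mut_varparam_incomplete(doc):
    doc.entries[0].experiments[0].variable_parameters = [
        m.VariableParameter(description="broken", values=[])]


def _mut_feature_no_range(doc):
    doc.entries[0].interactions[0].participants[1].features[0].ranges = []


def _mut_feature_role_no_acc(doc):
    f = doc.entries[0].interactions[0].participants[0].features[0]
    f.feature_role.mi_accession = None


def _mut_resseq_empty(doc):
    f = doc.entries[0].interactions[0].participants[0].features[0]
    f.ranges[0].resulting_sequence = m.ResultingSequence()


def _mut_resseq_alphabet(doc):
    f = doc.entries[0].interactions[0].participants[0].features[0]
    f.ranges[0].resulting_sequence.new = "A!1"


def _mut_range_inverted(doc):
    f = doc.entries[0].interactions[0].participants[0].features[0]
    f.ranges[0].begin = m.ExactPosition(200)
    f.ranges[0].end = m.ExactPosition(100)


def _mut_position_zero(doc):
    f = doc.entries[0].interactions[0].participants[1].features[0]
    f.ranges[0].end = m.ExactPosition(0)


def _mut_neg_pos_on_protein(doc):
    f = doc.entries[0].interactions[0].participants[0].features[0]
    f.ranges[0].begin = m.ExactPosition(-5)
    f.ranges[0].begin_status = m.CvTerm(short_label="undetermined",
                                        mi_accession="MI:0339")


def _mut_stoich_inverted(doc):
    p = doc.entries[0].interactions[0].participants[1]
    p.stoichiometry = m.StoichiometryRange(Decimal(4), Decimal(2))


def _mut_stoich_negative(doc):
    p = doc.entries[0].interactions[0].participants[0]
    p.stoichiometry = m.MeanStoichiometry(Decimal(-1))


def _mut_candidate_set_empty(doc):
    p = doc.entries[0].interactions[0].participants[1]
    p.entity.candidates = []


def _mut_participant_no_entity(doc):
    doc.entries[0].interactions[0].participants[0].entity = None


def _mut_abstract_has_experiment(doc):
    exp = m.Experiment(
        bibref=m.BibRef(xref=m.Xref(primary=m.DbReference(db="pubmed",
                                                          id="1"))),
        interaction_detection_method=m.CvTerm(short_label="two hybrid",
                                              mi_accession="MI:0018"))
    doc.entries[0].interactions[0].experiments.append(exp)


def _mut_order_duplicate(doc):
    values = doc.entries[0].experiments[0].variable_parameters[0].values
    values[1].order = values[0].order


def _mut_duplicate_id(doc):
    itors = doc.entries[0].interactors
    itors[1].id = itors[0].id


def _mut_mixed_kinds(doc):
    other = fixtures.build_use_case("j")
    for obj in m.iter_identified(other.entries[0]):
        obj.id += 1000  # keep the merged id namespace collision-free
    doc.entries[0].experiments.extend(other.entries[0].experiments)
    doc.entries[0].interactors.extend(other.entries[0].interactors)
    doc.entries[0].interactions.extend(other.entries[0].interactions)


MUTATIONS = [
    ("CVTERM_EMPTY", "a", _mut_cvterm_empty, "error"),
    ("CV_FORMAT", "a", _mut_cv_format, "error"),
    ("CV_UNKNOWN", "a", _mut_cv_unknown, "warning"),
    ("XREF_INCOMPLETE", "a", _mut_xref_incomplete, "error"),
    ("BIBREF_EMPTY", "a", _mut_bibref_empty, "error"),
    ("EXPERIMENT_INCOMPLETE", "a", _mut_experiment_incomplete, "error"),
    ("ORGANISM_TAXID_ZERO", "a", _mut_taxid_zero, "error"),
    ("PARAM_INVALID", "a", _mut_param_invalid, "error"),
    ("VARPARAM_INCOMPLETE", "a", _mut_varparam_incomplete, "error"),
    ("FEATURE_NO_RANGE", "a", _mut_feature_no_range, "error"),
    ("FEATURE_ROLE_NO_ACC", "d", _mut_feature_role_no_acc, "error"),
    ("RESSEQ_EMPTY", "b", _mut_resseq_empty, "error"),
    ("RESSEQ_ALPHABET", "b", _mut_resseq_alphabet, "warning"),
    ("RANGE_INVERTED", "b", _mut_range_inverted, "error"),
    ("POSITION_ZERO", "a", _mut_position_zero, "warning"),
    ("NEG_POS_ON_PROTEIN", "b", _mut_neg_pos_on_protein, "warning"),
    ("STOICH_RANGE_INVERTED", "j", _mut_stoich_inverted, "error"),
    ("STOICH_NEGATIVE", "j", _mut_stoich_negative, "error"),
    ("CANDIDATE_SET_EMPTY", "i", _mut_candidate_set_empty, "error"),
    ("PARTICIPANT_NO_ENTITY", "a", _mut_participant_no_entity, "error"),
    ("ABSTRACT_HAS_EXPERIMENT", "g", _mut_abstract_has_experiment, "error"),
    ("ORDER_DUPLICATE", "f", _mut_order_duplicate, "warning"),
    ("DUPLICATE_ID", "a", _mut_duplicate_id, "error"),
    ("MIXED_INTERACTION_KINDS", "g", _mut_mixed_kinds, "warning"),
]


@pytest.mark.parametrize("code,case,mutate,severity",
                         MUTATIONS, ids=[mut[0] for mut in MUTATIONS])
def test_single_mutation_triggers_exactly_its_code(code, case, mutate, severity):
    doc = _golden(case)
    mutate(doc)
    findings = validator.validate(doc, profile="cv")
    codes = {f.code for f in findings}
    assert code in codes
    error_codes = {f.code for f in findings if f.severity == "error"}
    assert error_codes <= {code}, error_codes
    got = {f.severity for f in findings if f.code == code}
    assert got == {severity}


def test_dangling_reference_finding_comes_from_the_reader():
    import re

    data = xml_io.write_mif(_golden("f"))
    bad = re.sub(rb"<experimentRef>\d+</", rb"<experimentRef>777</", data)
    rr = xml_io.read_mif(bad, strict=False)
    assert "DANGLING_REF" in {f.code for f in rr.findings}


def test_golden_fixtures_are_finding_free(goldens):
    for g in goldens:
        assert validator.validate(g.document, profile="cv") == [], g.case


def test_validation_is_pure_and_deterministic():
    doc = _golden("b")
    _mut_range_inverted(doc)
    first = validator.validate(doc, profile="cv")
    second = validator.validate(doc, profile="cv")
    assert [f.to_json() for f in first] == [f.to_json() for f in second]


def test_each_rule_is_suppressible_by_code():
    doc = _golden("j")
    _mut_stoich_inverted(doc)
    assert any(f.code == "STOICH_RANGE_INVERTED"
               for f in validator.validate(doc))
    assert validator.validate(doc, suppress={"STOICH_RANGE_INVERTED"}) == []


def test_structural_profile_skips_semantic_rules():
    doc = _golden("j")
    _mut_stoich_inverted(doc)
    assert validator.validate(doc, profile="structural") == []


# -- CV store ---------------------------------------------------------------

def test_load_cv_empty_stream_equals_embedded_store():
    store, findings = validator.load_cv(io.StringIO(""))
    assert store.terms == validator.CvStore.embedded().terms
    assert findings == []


def test_load_cv_adds_exactly_one_term():
    obo = "format-version: 1.2\n\n[Term]\nid: MI:0000\nname: root\n\n" \
          "[Term]\nid: MI:1111\nname: brand new method\nis_a: MI:0000\n"
    store, _ = validator.load_cv(io.StringIO(obo))
    embedded = validator.CvStore.embedded()
    assert len(store) == len(embedded) + 1
    assert store.lookup("MI:1111")[0] == "brand new method"


def test_load_cv_file_label_wins_without_changing_count():
    obo = "format-version: 1.2\n\n[Term]\nid: MI:0326\nname: protein molecule\n"
    store, _ = validator.load_cv(io.StringIO(obo))
    assert len(store) == len(validator.CvStore.embedded())
    assert store.lookup("MI:0326")[0] == "protein molecule"


def test_cv_lookups_are_total():
    store = validator.CvStore.embedded()
    assert store.lookup("MI:4321") is None
    assert "MI:4321" not in store
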
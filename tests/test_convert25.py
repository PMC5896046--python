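"""Downgrade/upgrade semantics: loss accounting, the documented 2.5
workarounds, and the promotable round trip."""

from collections import Counter

import pytest

from psimif import convert25, fixtures, model as m, validator, xml_io


def _count_constructs(doc: m.Document) -> Counter:
    """Independent recount of 3.0-only constructs, mirroring the documented
    one-item-per-construct loss accounting."""
    doc = m.normalize(doc)
    c: Counter = Counter()
    for entry in doc.entries:
        for exp in entry.experiments:
            c["VARIABLE_PARAMETERS"] += len(exp.variable_parameters)
            if exp.bibref and exp.bibref.xref and exp.bibref.attributes:
                c["BIBREF_SPLIT"] += 1
        if entry.source and entry.source.bibref \
                and entry.source.bibref.xref \
                and entry.source.bibref.attributes:
            c["BIBREF_SPLIT"] += 1
        for inter in entry.interactions:
            if isinstance(inter, m.AbstractInteraction):
                c["ABSTRACT_INTERACTION"] += 1
                c["COOPERATIVE_EFFECT"] += len(inter.cooperative_effects)
            elif inter.condition_sets:
                c["VARIABLE_PARAMETERS"] += 1
            for p in inter.participants:
                if isinstance(p.entity, m.CandidateSet):
                    c["CANDIDATE_SET"] += 1
                if p.stoichiometry is not None:
                    c["STOICHIOMETRY_ELEMENT"] += 1
                for f in p.features:
                    if f.feature_role is not None:
                        c["FEATURE_ROLE"] += 1
                    if len(f.detection_methods) > 1:
                        c["EXTRA_DETECTION_METHODS"] += 1
                    c["FEATURE_PARAMETERS"] += len(f.parameters)
                    for r in f.ranges:
                        if r.resulting_sequence is not None:
                            c["RESULTING_SEQUENCE"] += 1
                        for pos in (r.begin, r.end):
                            if (isinstance(pos, m.ExactPosition)
                                    and pos.value <= 0) or (
                                    isinstance(pos, m.IntervalPosition)
                                    and min(pos.start, pos.end) <= 0):
                                c["NEGATIVE_POSITION"] += 1
                                break
    return c


def test_document_without_30_features_converts_with_empty_report():
    spec = fixtures.GeneratorSpec(seed=3)  # no flags
    doc = fixtures.generate_random(spec)
    d25, report = convert25.downgrade(doc)
    assert report.empty
    assert d25.level == "2.5"
    # content identical apart from the level tag
    d25.level = "3.0"
    assert m.semantic_equal(d25, m.normalize(doc)).equal


@pytest.mark.parametrize("case", fixtures.USE_CASES)
def test_loss_report_matches_the_fixture_manifest(case):
    g = fixtures.golden(case)
    _, report = convert25.downgrade(g.document)
    assert report.counts() == g.expected_loss


def test_all_features_fixture_covers_every_category_once_or_more():
    g = fixtures.build_all_features()
    _, report = convert25.downgrade(g.document)
    counts = report.counts()
    assert set(counts) == set(convert25.CATEGORIES)
    assert counts == g.expected_loss


def test_downgraded_abstract_complex_gets_inferred_by_curator_experiment():
    doc = fixtures.build_use_case("g")
    d25, _ = convert25.downgrade(doc)
    inter = d25.entries[0].interactions[0]
    assert isinstance(inter, m.InteractionEvidence)
    assert len(inter.experiments) == 1
    idm = inter.experiments[0].interaction_detection_method
    assert idm.mi_accession == "MI:0364"


def test_downgraded_documents_validate_as_25(goldens):
    for g in goldens:
        d25, _ = convert25.downgrade(g.document)
        data = xml_io.write_mif(d25)
        assert xml_io.detect_level(data) == "2.5"
        assert xml_io.xsd_validate(data) == [], g.case


def test_downgrade_then_promote_is_identity_on_all_goldens(goldens):
    for g in goldens:
        d25, _ = convert25.downgrade(g.document)
        up = convert25.upgrade(d25, promote=True)
        eq = m.semantic_equal(m.normalize(up), m.normalize(g.document))
        assert eq.equal, (g.case, [(d.path, d.description)
                                   for d in eq.diffs][:3])


def test_round_trip_survives_serialization_of_the_25_form():
    doc = fixtures.build_use_case("h")
    d25, _ = convert25.downgrade(doc)
    rr = xml_io.read_mif(xml_io.write_mif(d25), strict=True)
    up = convert25.upgrade(rr.document, promote=True)
    assert m.semantic_equal(m.normalize(up), m.normalize(doc)).equal


def test_upgrade_without_promotion_only_changes_the_level():
    doc = fixtures.build_use_case("j")
    d25, _ = convert25.downgrade(doc)
    up = convert25.upgrade(d25, promote=False)
    assert up.level == "3.0"
    d25_again, report = convert25.downgrade(up)
    # the psimi3: annotations are plain attributes, not 3.0 constructs
    assert report.empty
    d25_again.level = "2.5"
    assert m.semantic_equal(d25_again, m.normalize(d25)).equal


def test_downgrade_of_a_plain_25_upgrade_is_identity():
    spec = fixtures.GeneratorSpec(seed=12)
    doc = fixtures.generate_random(spec)
    d25, _ = convert25.downgrade(doc)
    up = convert25.upgrade(d25)
    down_again, report = convert25.downgrade(up)
    assert report.empty
    assert m.semantic_equal(down_again, m.normalize(d25)).equal


@pytest.mark.parametrize("seed", range(6))
def test_every_removed_construct_is_reported_exactly_once(seed):
    spec = fixtures.GeneratorSpec(seed=seed,
                                  feature_flags=fixtures.all_flags())
    doc = fixtures.generate_random(spec)
    _, report = convert25.downgrade(doc)
    assert Counter(report.counts()) == _count_constructs(doc)


def test_downgrade_is_total_on_validator_clean_random_documents(random_docs):
    for doc in random_docs:
        assert not validator.errors_only(validator.validate(doc))
        d25, _ = convert25.downgrade(doc)
        assert xml_io.xsd_validate(xml_io.write_mif(d25)) == []


def test_loss_report_serializes_with_counts_and_items():
    _, report = convert25.downgrade(fixtures.build_use_case("g"))
    blob = report.to_jsonable()
    assert blob["counts"]["ABSTRACT_INTERACTION"] == 1
    assert all({"category", "path", "detail"} <= set(i) for i in blob["items"])
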
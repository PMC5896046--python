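"""Document generators: determinism, use-case coverage, validator-clean
output, and agreement with the files shipped under fixtures/."""

from pathlib import Path

import pytest

from psimif import convert25, fixtures, model as m, validator, xml_io

FIXTURE_DIR = Path(__file__).resolve().parent.parent / "fixtures"


def test_same_spec_and_seed_is_byte_identical():
    spec = fixtures.GeneratorSpec(seed=42, feature_flags=fixtures.all_flags())
    a = xml_io.write_mif(fixtures.generate_random(spec))
    b = xml_io.write_mif(fixtures.generate_random(spec))
    assert a == b


def test_different_seeds_differ():
    flags = fixtures.all_flags()
    a = xml_io.write_mif(fixtures.generate_random(
        fixtures.GeneratorSpec(seed=1, feature_flags=flags)))
    b = xml_io.write_mif(fixtures.generate_random(
        fixtures.GeneratorSpec(seed=2, feature_flags=flags)))
    assert a != b


def test_no_flags_means_no_30_only_constructs():
    doc = fixtures.generate_random(fixtures.GeneratorSpec(seed=8))
    _, report = convert25.downgrade(doc)
    assert report.empty


def test_unknown_flag_or_case_is_rejected():
    with pytest.raises(ValueError):
        fixtures.GeneratorSpec(seed=0, feature_flags=frozenset({"warp"}))
    with pytest.raises(ValueError):
        fixtures.build_use_case("z")


def test_hundred_random_documents_have_zero_validator_errors():
    flags = fixtures.all_flags()
    for seed in range(100):
        doc = fixtures.generate_random(
            fixtures.GeneratorSpec(seed=seed, feature_flags=flags))
        errors = validator.errors_only(validator.validate(doc, profile="cv"))
        assert errors == [], (seed, [str(e) for e in errors][:3])


def test_generator_output_is_closed_under_the_full_pipeline():
    from psimif import mitab

    for seed in (0, 1):
        doc = fixtures.generate_random(fixtures.GeneratorSpec(
            seed=seed, feature_flags=fixtures.all_flags()))
        for form in ("compact", "extended"):
            rr = xml_io.read_mif(xml_io.write_mif(doc, form=form), strict=True)
            assert not rr.fatal
        d25, _ = convert25.downgrade(doc)
        up = convert25.upgrade(d25, promote=True)
        assert m.semantic_equal(m.normalize(up), m.normalize(doc)).equal
        mitab.write_mitab(doc)


def test_case_a_has_the_upstream_promoter_range():
    doc = fixtures.build_use_case("a")
    ranges = [r for i in doc.entries[0].interactions
              for f in m.iter_interaction_features(i) for r in f.ranges]
    assert any(r.begin == m.ExactPosition(-2000)
               and r.end == m.ExactPosition(-1) for r in ranges)


def test_case_f_has_three_ordered_values_and_distinct_conditions():
    doc = fixtures.build_use_case("f")
    exp = doc.entries[0].experiments[0]
    vp = exp.variable_parameters[0]
    assert "hours" in vp.description and "infection" in vp.description
    assert [v.order for v in vp.values] == [0, 1, 2]
    refs = [vv.value for i in doc.entries[0].interactions
            for s in i.condition_sets for vv in s]
    assert len(set(refs)) == 2


def test_case_h_allostery_is_fully_specified():
    doc = fixtures.build_use_case("h")
    effects = [e for i in doc.entries[0].interactions
               if isinstance(i, m.AbstractInteraction)
               for e in i.cooperative_effects]
    assert len(effects) == 1
    eff = effects[0]
    assert isinstance(eff, m.Allostery)
    assert eff.allosteric_molecule is not None
    assert eff.effector is not None
    assert eff.outcome.mi_accession is not None
    assert len(eff.affected) == 1


def test_case_i_has_one_candidate_per_calmodulin_gene():
    doc = fixtures.build_use_case("i")
    sets = [p.entity for i in doc.entries[0].interactions
            for p in i.participants if isinstance(p.entity, m.CandidateSet)]
    assert len(sets) == 1
    labels = sorted(c.interactor.names.short_label
                    for c in sets[0].candidates)
    assert labels == ["calm1", "calm2", "calm3"]


def test_all_features_manifest_is_the_sum_of_the_cases():
    g = fixtures.build_all_features()
    total: dict[str, int] = {}
    for case in fixtures.USE_CASES:
        for k, v in fixtures.golden(case).expected_loss.items():
            total[k] = total.get(k, 0) + v
    assert g.expected_loss == total
    assert len(g.document.entries) == len(fixtures.USE_CASES)


@pytest.mark.parametrize("case", fixtures.USE_CASES)
def test_shipped_fixture_files_are_regenerable(case):
    path = FIXTURE_DIR / f"use_case_{case}.xml"
    assert path.exists(), "run scripts/make_fixtures.py"
    assert path.read_bytes() == xml_io.write_mif(fixtures.build_use_case(case))
    import json

    manifest = json.loads(
        (FIXTURE_DIR / f"use_case_{case}.manifest.json").read_text())
    assert manifest == fixtures.golden(case).expected_loss
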
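"""Deterministic document generators.

Two families:

* :func:`build_use_case` — one small, validator-clean golden document per
  level-3.0 use case (a..k): negative promoter ranges, mutation resulting
  sequences, repeated feature detection methods, feature roles, feature
  kinetic parameters, dynamic interaction time courses, curated complexes,
  cooperative (allosteric) interactions, molecule sets, stoichiometries and
  combined publication references.  Each carries an expected-loss manifest
  stating exactly what a 2.5 downgrade must report.
* :func:`generate_random` — seeded random documents mixing any subset of
  those constructs, for property tests.  The same :class:`GeneratorSpec`
  always yields a byte-identical serialization.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from decimal import Decimal

from . import model as m

USE_CASES = tuple("abcdefghijk")

FLAGS = (
    "neg_range", "resseq", "multi_detect", "feature_role", "feature_params",
    "variable_params", "abstract", "cooperative", "candidate_set", "stoich",
    "bibref_both",
)

#: fixed vocabulary for generated free-text fields, to keep diffs readable
WORDS = (
    "alder", "birch", "cedar", "dogwood", "elm", "fir", "ginkgo", "hazel",
    "juniper", "larch", "maple", "oak", "pine", "rowan", "spruce", "willow",
)


def _cv(label: str, acc: str | None = None) -> m.CvTerm:
    return m.CvTerm(short_label=label, mi_accession=acc)


def _protein_type() -> m.CvTerm:
    return _cv("protein", "MI:0326")


def _dna_type() -> m.CvTerm:
    return _cv("dna", "MI:0319")


def _certain() -> m.CvTerm:
    return _cv("certain", "MI:0335")


def _human() -> m.Organism:
    return m.Organism(ncbi_tax_id=9606,
                      names=m.Names(short_label="human"))


def _pubmed(pmid: str) -> m.Xref:
    return m.Xref(primary=m.DbReference(db="pubmed", id=pmid,
                                        ref_type="primary-reference"))


def _demo_xref(ident: str) -> m.Xref:
    return m.Xref(primary=m.DbReference(db="demo", id=ident,
                                        ref_type="identity"))


def _protein(label: str, ident: str, sequence: str | None = None) -> m.Interactor:
    return m.Interactor(
        names=m.Names(short_label=label),
        xref=_demo_xref(ident),
        interactor_type=_protein_type(),
        organism=_human(),
        sequence=sequence,
    )


def _experiment(label: str, pmid: str, method: m.CvTerm) -> m.Experiment:
    return m.Experiment(
        names=m.Names(short_label=label),
        bibref=m.BibRef(xref=_pubmed(pmid)),
        host_organisms=[_human()],
        interaction_detection_method=method,
        participant_identification_method=_cv("predetermined participant",
                                              "MI:0396"),
    )


def _participant(itor: m.Interactor, role_label: str, role_acc: str,
                 **kwargs) -> m.Participant:
    return m.Participant(
        entity=itor,
        biological_role=_cv("unspecified role", "MI:0499"),
        experimental_roles=[_cv(role_label, role_acc)],
        **kwargs,
    )


def _bait(itor, **kw):
    return _participant(itor, "bait", "MI:0496", **kw)


def _prey(itor, **kw):
    return _participant(itor, "prey", "MI:0498", **kw)


def _range(begin: int, end: int) -> m.FeatureRange:
    return m.FeatureRange(begin_status=_certain(),
                          begin=m.ExactPosition(begin),
                          end_status=_certain(),
                          end=m.ExactPosition(end))


def _binding_feature(label: str, begin: int, end: int) -> m.Feature:
    return m.Feature(
        names=m.Names(short_label=label),
        feature_type=_cv("binding-associated region", "MI:0117"),
        ranges=[_range(begin, end)],
    )


def _interaction(experiment: m.Experiment,
                 participants: list[m.Participant]) -> m.InteractionEvidence:
    return m.InteractionEvidence(
        experiments=[experiment],
        participants=participants,
        interaction_types=[_cv("physical association", "MI:0915")],
    )


def _entry(experiments, interactors, interactions) -> m.Entry:
    return m.Entry(
        source=m.Source(names=m.Names(short_label="psimif",
                                      full_name="psimif fixture generator")),
        experiments=list(experiments),
        interactors=list(interactors),
        interactions=list(interactions),
    )


def _doc(*entries: m.Entry) -> m.Document:
    return m.normalize(m.Document(entries=list(entries), level=m.LEVEL_30))


# ---------------------------------------------------------------------------
# golden use cases
# ---------------------------------------------------------------------------

def _case_a() -> tuple[m.Document, dict[str, int]]:
    """Negative feature positions: a transcription factor bound to a gene
    promoter region located upstream of the sequence start."""
    promoter = m.Interactor(
        names=m.Names(short_label="prm1 gene"),
        xref=_demo_xref("gene-0001"),
        interactor_type=_dna_type(),
        organism=_human(),
    )
    tf = _protein("tfx1", "prot-0001")
    feature = m.Feature(
        names=m.Names(short_label="prm1 promoter element"),
        feature_type=_cv("binding-associated region", "MI:0117"),
        ranges=[_range(-2000, -1)],
    )
    exp = _experiment("promoter pulldown", "9100001",
                      _cv("affinity chromatography technology", "MI:0004"))
    inter = _interaction(exp, [_bait(tf), _prey(promoter, features=[feature])])
    doc = _doc(_entry([exp], [promoter, tf], [inter]))
    return doc, {"NEGATIVE_POSITION": 1}


def _case_b() -> tuple[m.Document, dict[str, int]]:
    """Resulting sequence: a site-directed R128A mutation with the original
    and the substituted residue recorded."""
    a = _protein("kin2", "prot-0002")
    b = _protein("sub7", "prot-0003")
    mutation = m.Feature(
        names=m.Names(short_label="r128a"),
        feature_type=_cv("mutation", "MI:0118"),
        ranges=[m.FeatureRange(
            begin_status=_certain(), begin=m.ExactPosition(128),
            end_status=_certain(), end=m.ExactPosition(128),
            resulting_sequence=m.ResultingSequence(original="R", new="A"),
        )],
    )
    exp = _experiment("mutant affinity", "9100002",
                      _cv("x-ray crystallography", "MI:0114"))
    inter = _interaction(exp, [_bait(a, features=[mutation]), _prey(b)])
    doc = _doc(_entry([exp], [a, b], [inter]))
    return doc, {"RESULTING_SEQUENCE": 1}


def _case_c() -> tuple[m.Document, dict[str, int]]:
    """Repeatable featureDetectionMethod: the same modification observed by
    two independent methods."""
    a = _protein("rcp5", "prot-0004")
    b = _protein("lig9", "prot-0005")
    ptm = m.Feature(
        names=m.Names(short_label="phosphosite"),
        feature_type=_cv("phosphorylated residue"),
        detection_methods=[_cv("western blot", "MI:0113"),
                           _cv("x-ray crystallography", "MI:0114")],
        ranges=[_range(211, 211)],
    )
    exp = _experiment("ptm mapping", "9100003", _cv("pull down", "MI:0096"))
    inter = _interaction(exp, [_bait(a, features=[ptm]), _prey(b)])
    doc = _doc(_entry([exp], [a, b], [inter]))
    return doc, {"EXTRA_DETECTION_METHODS": 1}


def _case_d() -> tuple[m.Document, dict[str, int]]:
    """featureRole: a PTM that must pre-exist for the interaction to occur
    (prerequisite-PTM, MI:0638)."""
    a = _protein("rcp5", "prot-0004")
    b = _protein("adp3", "prot-0006")
    ptm = m.Feature(
        names=m.Names(short_label="required phosphosite"),
        feature_type=_cv("phosphorylated residue"),
        feature_role=_cv("prerequisite-ptm", "MI:0638"),
        ranges=[_range(42, 42)],
    )
    exp = _experiment("dependency assay", "9100004",
                      _cv("pull down", "MI:0096"))
    inter = _interaction(exp, [_bait(a, features=[ptm]), _prey(b)])
    doc = _doc(_entry([exp], [a, b], [inter]))
    return doc, {"FEATURE_ROLE": 1}


def _case_e() -> tuple[m.Document, dict[str, int]]:
    """Feature-level kinetic parameters: the dissociation constant of a
    mutant, attached to the mutation itself; the wild-type constant stays at
    the interaction level."""
    a = _protein("kin2", "prot-0002")
    b = _protein("sub7", "prot-0003")
    mutation = m.Feature(
        names=m.Names(short_label="y77f"),
        feature_type=_cv("mutation", "MI:0118"),
        ranges=[_range(77, 77)],
        parameters=[m.Parameter(term="kd", unit="molar", base=10,
                                exponent=-6, factor=Decimal("4.0"))],
    )
    exp = _experiment("binding kinetics", "9100005",
                      _cv("x-ray crystallography", "MI:0114"))
    inter = _interaction(exp, [_bait(a, features=[mutation]), _prey(b)])
    inter.parameters = [m.Parameter(term="kd", unit="molar", base=10,
                                    exponent=-9, factor=Decimal("2.0"))]
    doc = _doc(_entry([exp], [a, b], [inter]))
    return doc, {"FEATURE_PARAMETERS": 1}


def _case_f() -> tuple[m.Document, dict[str, int]]:
    """Dynamic interactions: the interaction partners of STAT6 change with
    the number of hours post-Sendai viral infection; each interaction
    references the condition values under which it was observed."""
    stat6 = _protein("stat6", "prot-0007")
    pa = _protein("partner-a", "prot-0008")
    pb = _protein("partner-b", "prot-0009")
    vv0 = m.VariableValue(id=0, value="0", order=0)
    vv4 = m.VariableValue(id=0, value="4", order=1)
    vv8 = m.VariableValue(id=0, value="8", order=2)
    exp = _experiment("sendai time course", "9100006",
                      _cv("affinity chromatography technology", "MI:0004"))
    exp.variable_parameters = [m.VariableParameter(
        description="hours post-sendai viral infection",
        unit=_cv("hour"),
        values=[vv0, vv4, vv8],
    )]
    early = _interaction(exp, [_bait(stat6), _prey(pa)])
    early.condition_sets = [[vv4]]
    late = _interaction(exp, [_bait(stat6), _prey(pb)])
    late.condition_sets = [[vv8]]
    doc = _doc(_entry([exp], [stat6, pa, pb], [early, late]))
    return doc, {"VARIABLE_PARAMETERS": 3}


def _case_g() -> tuple[m.Document, dict[str, int]]:
    """A manually curated protein complex: an abstract interaction with
    stoichiometries, linked binding features and no experiment."""
    core = _protein("cplx-core", "prot-0010")
    ring = _protein("cplx-ring", "prot-0011")
    f_core = _binding_feature("core binding region", 10, 40)
    f_ring = _binding_feature("ring binding region", 100, 140)
    complex_ = m.AbstractInteraction(
        names=m.Names(short_label="core-ring complex"),
        xref=_demo_xref("cplx-0001"),
        interactor_type=_cv("complex", "MI:0314"),
        interaction_type=_cv("physical association", "MI:0915"),
        organism=_human(),
        participants=[
            _participant(core, "unspecified role", "MI:0499",
                         features=[f_core],
                         stoichiometry=m.MeanStoichiometry(Decimal("1"))),
            _participant(ring, "unspecified role", "MI:0499",
                         features=[f_ring],
                         stoichiometry=m.MeanStoichiometry(Decimal("4"))),
        ],
        binding_features=[[f_core, f_ring]],
        evidence_type=_cv("inferred from physical evidence"),
    )
    doc = _doc(_entry([], [core, ring], [complex_]))
    return doc, {"ABSTRACT_INTERACTION": 1, "STOICHIOMETRY_ELEMENT": 2}


def _case_h() -> tuple[m.Document, dict[str, int]]:
    """A cooperative interaction: binding of an effector within one modelled
    complex allosterically enhances a second modelled interaction."""
    rec = _protein("rec1", "prot-0012")
    eff = _protein("eff2", "prot-0013")
    lig = _protein("lig3", "prot-0014")
    p_rec_b = _participant(rec, "unspecified role", "MI:0499")
    p_lig = _participant(lig, "unspecified role", "MI:0499")
    affected = m.AbstractInteraction(
        names=m.Names(short_label="rec1-lig3 binding"),
        interaction_type=_cv("direct interaction", "MI:0407"),
        participants=[p_rec_b, p_lig],
    )
    p_rec = _participant(rec, "unspecified role", "MI:0499")
    p_eff = _participant(eff, "unspecified role", "MI:0499")
    allostery = m.Allostery(
        evidence=[m.CooperativityEvidence(
            bibref=m.BibRef(xref=_pubmed("9100007")),
            methods=[_cv("inferred by author", "MI:0363")],
        )],
        affected=[affected],
        outcome=_cv("positive cooperative effect", "MI:1154"),
        allosteric_molecule=p_rec,
        effector=m.MoleculeEffector(p_eff),
    )
    complex_ = m.AbstractInteraction(
        names=m.Names(short_label="rec1-eff2 complex"),
        interactor_type=_cv("complex", "MI:0314"),
        interaction_type=_cv("physical association", "MI:0915"),
        participants=[p_rec, p_eff],
        cooperative_effects=[allostery],
    )
    doc = _doc(_entry([], [rec, eff, lig], [affected, complex_]))
    return doc, {"ABSTRACT_INTERACTION": 2, "COOPERATIVE_EFFECT": 1}


def _case_i() -> tuple[m.Document, dict[str, int]]:
    """A molecule set: calmodulin is an identical protein produced by three
    genes (CALM1, CALM2, CALM3), so the participant is a candidate set."""
    calm = [_protein(label, ident) for label, ident in
            (("calm1", "prot-0015"), ("calm2", "prot-0016"),
             ("calm3", "prot-0017"))]
    kinase = _protein("camk1", "prot-0018")
    candidate_set = m.CandidateSet(
        set_type=_cv("molecule set", "MI:1304"),
        candidates=[m.Candidate(interactor=itor) for itor in calm],
    )
    p_set = m.Participant(
        names=m.Names(short_label="calmodulin"),
        entity=candidate_set,
        biological_role=_cv("unspecified role", "MI:0499"),
        experimental_roles=[_cv("prey", "MI:0498")],
    )
    exp = _experiment("calmodulin pulldown", "9100008",
                      _cv("pull down", "MI:0096"))
    inter = _interaction(exp, [_bait(kinase), p_set])
    doc = _doc(_entry([exp], calm + [kinase], [inter]))
    return doc, {"CANDIDATE_SET": 1}


def _case_j() -> tuple[m.Document, dict[str, int]]:
    """Stoichiometry: a mean value on one participant and a decimal range on
    the other."""
    a = _protein("oct4", "prot-0019")
    b = _protein("mer2", "prot-0020")
    exp = _experiment("native ms", "9100009",
                      _cv("x-ray crystallography", "MI:0114"))
    inter = _interaction(exp, [
        _bait(a, stoichiometry=m.MeanStoichiometry(Decimal("2"))),
        _prey(b, stoichiometry=m.StoichiometryRange(Decimal("2"),
                                                    Decimal("4"))),
    ])
    doc = _doc(_entry([exp], [a, b], [inter]))
    return doc, {"STOICHIOMETRY_ELEMENT": 2}


def _case_k() -> tuple[m.Document, dict[str, int]]:
    """bibref holding both a primary xref and descriptive publication
    attributes, so the publication is described entirely within bibref."""
    a = _protein("aux1", "prot-0021")
    b = _protein("bdl2", "prot-0022")
    exp = _experiment("reference assay", "26919541",
                      _cv("two hybrid", "MI:0018"))
    exp.bibref.attributes = [
        m.Attribute(name="publication title",
                    value="a molecular interaction reference dataset"),
        m.Attribute(name="publication year", value="2018"),
    ]
    inter = _interaction(exp, [_bait(a), _prey(b)])
    doc = _doc(_entry([exp], [a, b], [inter]))
    return doc, {"BIBREF_SPLIT": 1}


_CASES = {
    "a": _case_a, "b": _case_b, "c": _case_c, "d": _case_d, "e": _case_e,
    "f": _case_f, "g": _case_g, "h": _case_h, "i": _case_i, "j": _case_j,
    "k": _case_k,
}


@dataclass
class GoldenFixture:
    case: str
    document: m.Document
    expected_loss: dict[str, int]


def build_use_case(case: str) -> m.Document:
    """Build the golden document for one use case (``a``..``k``)."""
    if case not in _CASES:
        raise ValueError(f"unknown use case {case!r}; expected one of "
                         f"{''.join(USE_CASES)}")
    return _CASES[case]()[0]


def golden(case: str) -> GoldenFixture:
    """The golden document plus its expected 2.5 downgrade-loss manifest."""
    if case not in _CASES:
        raise ValueError(f"unknown use case {case!r}")
    doc, manifest = _CASES[case]()
    return GoldenFixture(case=case, document=doc, expected_loss=manifest)


def build_all_features() -> GoldenFixture:
    """All eleven use cases combined into one multi-entry document, with the
    summed expected-loss manifest."""
    entries = []
    manifest: dict[str, int] = {}
    for case in USE_CASES:
        doc, counts = _CASES[case]()
        entries.extend(doc.entries)
        for k, v in counts.items():
            manifest[k] = manifest.get(k, 0) + v
    return GoldenFixture(case="all",
                         document=m.normalize(m.Document(entries=entries)),
                         expected_loss=manifest)


# ---------------------------------------------------------------------------
# random documents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    seed: int
    n_entries: int = 1
    n_experiments: tuple[int, int] = (1, 2)
    n_interactors: tuple[int, int] = (2, 5)
    n_interactions: tuple[int, int] = (1, 4)
    feature_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        unknown = set(self.feature_flags) - set(FLAGS)
        if unknown:
            raise ValueError(f"unknown feature flags {sorted(unknown)}")
        if self.n_interactions[0] > 0 and self.n_interactors[1] <= 0:
            raise ValueError("interactions require at least one interactor")


def all_flags() -> frozenset[str]:
    return frozenset(FLAGS)


def generate_random(spec: GeneratorSpec) -> m.Document:
    """A validator-clean random document; every enabled flag is instantiated
    at least once; fully reproducible from the GeneratorSpec."""
    rng = random.Random(spec.seed)
    entries = [_random_entry(rng, spec, i) for i in range(spec.n_entries)]
    return m.normalize(m.Document(entries=entries, level=m.LEVEL_30))


def _rand_label(rng: random.Random, kind: str) -> str:
    return f"{rng.choice(WORDS)}-{kind}{rng.randint(1, 99)}"


def _random_entry(rng: random.Random, spec: GeneratorSpec, index: int) -> m.Entry:
    flags = spec.feature_flags
    n_itors = rng.randint(*spec.n_interactors)
    n_exps = max(1, rng.randint(*spec.n_experiments))
    n_inters = rng.randint(*spec.n_interactions)

    interactors = [
        _protein(_rand_label(rng, "p"), f"d{index}-{i:04d}")
        for i in range(max(2, n_itors))
    ]
    methods = (("two hybrid", "MI:0018"),
               ("affinity chromatography technology", "MI:0004"),
               ("pull down", "MI:0096"),
               ("x-ray crystallography", "MI:0114"))
    experiments = []
    for i in range(n_exps):
        label, acc = rng.choice(methods)
        experiments.append(_experiment(
            _rand_label(rng, "exp"), f"9{rng.randint(100000, 999999)}",
            _cv(label, acc)))
    if "bibref_both" in flags:
        experiments[0].bibref.attributes = [
            m.Attribute(name="publication title",
                        value=" ".join(rng.sample(WORDS, 3))),
        ]
    if "variable_params" in flags:
        experiments[0].variable_parameters = [m.VariableParameter(
            description="hours post-infection",
            unit=_cv("hour"),
            values=[m.VariableValue(id=0, value=str(4 * i), order=i)
                    for i in range(3)],
        )]

    def random_feature() -> m.Feature:
        begin = rng.randint(1, 400)
        return _binding_feature(_rand_label(rng, "f"), begin,
                                begin + rng.randint(0, 80))

    interactions: list[m.Interaction] = []
    for i in range(max(1, n_inters)):
        pair = rng.sample(interactors, k=min(2, len(interactors)))
        bait = _bait(pair[0])
        prey = _prey(pair[-1])
        if rng.random() < 0.5:
            prey.features.append(random_feature())
        inter = _interaction(rng.choice(experiments), [bait, prey])
        interactions.append(inter)

    first = interactions[0]
    if "variable_params" in flags:
        values = experiments[0].variable_parameters[0].values
        first.experiments = [experiments[0]]
        first.condition_sets = [[rng.choice(values)]]
    if "stoich" in flags:
        first.participants[0].stoichiometry = m.MeanStoichiometry(
            Decimal(rng.randint(1, 6)))
        low = rng.randint(1, 4)
        first.participants[1].stoichiometry = m.StoichiometryRange(
            Decimal(low), Decimal(low + rng.randint(0, 4)))
    if "resseq" in flags:
        pos = rng.randint(1, 300)
        first.participants[0].features.append(m.Feature(
            names=m.Names(short_label=_rand_label(rng, "mut")),
            feature_type=_cv("mutation", "MI:0118"),
            ranges=[m.FeatureRange(
                begin_status=_certain(), begin=m.ExactPosition(pos),
                end_status=_certain(), end=m.ExactPosition(pos),
                resulting_sequence=m.ResultingSequence(
                    original=rng.choice("ARNDCEQGHILKMFPSTWYV"),
                    new=rng.choice("ARNDCEQGHILKMFPSTWYV")),
            )],
        ))
    if "multi_detect" in flags:
        f = random_feature()
        f.detection_methods = [_cv("western blot", "MI:0113"),
                               _cv("x-ray crystallography", "MI:0114")]
        first.participants[1].features.append(f)
    if "feature_role" in flags:
        f = random_feature()
        f.feature_role = rng.choice(
            (_cv("prerequisite-ptm", "MI:0638"), _cv("observed-ptm", "MI:0925")))
        first.participants[0].features.append(f)
    if "feature_params" in flags:
        f = random_feature()
        f.parameters = [m.Parameter(
            term="kd", unit="molar", base=10,
            exponent=-rng.randint(3, 9),
            factor=Decimal(f"{rng.randint(1, 9)}.{rng.randint(0, 9)}"))]
        first.participants[1].features.append(f)
    if "neg_range" in flags:
        gene = m.Interactor(
            names=m.Names(short_label=_rand_label(rng, "gene")),
            xref=_demo_xref(f"g{index}-{rng.randint(0, 9999):04d}"),
            interactor_type=_dna_type(),
            organism=_human(),
        )
        interactors.append(gene)
        start = -rng.randint(500, 3000)
        promoter = m.Feature(
            names=m.Names(short_label=_rand_label(rng, "prm")),
            feature_type=_cv("binding-associated region", "MI:0117"),
            ranges=[_range(start, -rng.randint(1, 400))],
        )
        interactions.append(_interaction(
            rng.choice(experiments),
            [_bait(rng.choice(interactors[:2])),
             _prey(gene, features=[promoter])]))
    if "candidate_set" in flags:
        members = [
            _protein(_rand_label(rng, "cand"), f"c{index}-{i:04d}")
            for i in range(rng.randint(2, 4))
        ]
        interactors.extend(members)
        cset = m.CandidateSet(
            set_type=_cv("molecule set", "MI:1304"),
            candidates=[m.Candidate(interactor=itor) for itor in members])
        p_set = m.Participant(
            names=m.Names(short_label=_rand_label(rng, "set")),
            entity=cset,
            biological_role=_cv("unspecified role", "MI:0499"),
            experimental_roles=[_cv("prey", "MI:0498")],
        )
        interactions.append(_interaction(
            rng.choice(experiments), [_bait(rng.choice(interactors[:2])), p_set]))
    if "abstract" in flags or "cooperative" in flags:
        pa = _participant(interactors[0], "unspecified role", "MI:0499")
        pb = _participant(interactors[1], "unspecified role", "MI:0499")
        fa = random_feature()
        fb = random_feature()
        pa.features.append(fa)
        pb.features.append(fb)
        complex_ = m.AbstractInteraction(
            names=m.Names(short_label=_rand_label(rng, "cplx")),
            interactor_type=_cv("complex", "MI:0314"),
            interaction_type=_cv("physical association", "MI:0915"),
            organism=_human(),
            participants=[pa, pb],
            binding_features=[[fa, fb]],
            evidence_type=_cv("inferred from physical evidence"),
        )
        interactions.append(complex_)
        if "cooperative" in flags:
            if rng.random() < 0.5:
                effect: m.CooperativeEffect = m.Allostery(
                    evidence=[m.CooperativityEvidence(
                        bibref=m.BibRef(xref=_pubmed(
                            f"9{rng.randint(100000, 999999)}")),
                        methods=[_cv("inferred by author", "MI:0363")])],
                    affected=[interactions[0]],
                    outcome=_cv("positive cooperative effect", "MI:1154"),
                    allosteric_molecule=pa,
                    effector=m.FeatureModificationEffector(fb),
                )
            else:
                effect = m.Preassembly(
                    evidence=[m.CooperativityEvidence(
                        bibref=m.BibRef(xref=_pubmed(
                            f"9{rng.randint(100000, 999999)}")),
                        methods=[_cv("inferred by curator", "MI:0364")])],
                    affected=[interactions[0]],
                    outcome=_cv("negative cooperative effect", "MI:1155"),
                )
            complex_.cooperative_effects.append(effect)

    return _entry(experiments, interactors, interactions)
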
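"""Semantic validation beyond what the structural schema can check.

Three cumulative profiles:

``structural``
    identity and shape rules: unique ids, non-empty required lists,
    well-formed CV terms and cross-references;
``semantic``
    content rules for the level-3.0 constructs: a resultingSequence needs
    sequences or an xref, stoichiometry ranges must not be inverted,
    abstract interactions are evidence-free, negative coordinates only make
    biological sense off protein sequences, ...;
``cv``
    accession checks against the controlled-vocabulary store (embedded
    minimal table, optionally merged with a full OBO file).

``validate`` is pure and deterministic: findings are reported in document
walk order, and the same document always yields the same list.  Individual
rules can be suppressed by code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import model as m
from .findings import ERROR, INFO, WARNING, ValidationFinding

PROFILES = ("structural", "semantic", "cv")

#: all finding codes the validator (or the reader) can emit
CODES = (
    "CVTERM_EMPTY",
    "CV_FORMAT",
    "CV_UNKNOWN",
    "XREF_INCOMPLETE",
    "BIBREF_EMPTY",
    "EXPERIMENT_INCOMPLETE",
    "ORGANISM_TAXID_ZERO",
    "PARAM_INVALID",
    "VARPARAM_INCOMPLETE",
    "FEATURE_NO_RANGE",
    "FEATURE_ROLE_NO_ACC",
    "RESSEQ_EMPTY",
    "RESSEQ_ALPHABET",
    "RANGE_INVERTED",
    "POSITION_ZERO",
    "NEG_POS_ON_PROTEIN",
    "STOICH_RANGE_INVERTED",
    "STOICH_NEGATIVE",
    "CANDIDATE_SET_EMPTY",
    "PARTICIPANT_NO_ENTITY",
    "ABSTRACT_HAS_EXPERIMENT",
    "ORDER_DUPLICATE",
    "MIXED_INTERACTION_KINDS",
    "DUPLICATE_ID",
    "DANGLING_REF",
    "PARSE_ERROR",
    "UNKNOWN_NAMESPACE",
    "UNKNOWN_ELEMENT",
)

_IUPAC = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")  # amino acids + nucleotide letters ⊂

MI_PROTEIN = "MI:0326"

# ---------------------------------------------------------------------------
# controlled-vocabulary store
# ---------------------------------------------------------------------------

#: minimal embedded MI term table: accession -> (label, parent accessions).
#: Includes every accession the level-3.0 use cases rely on (sufficient
#: binding region, GFP tag, inferred by author/curator, prerequisite- and
#: observed-PTM, protein, polysaccharide) plus the terms the fixture
#: generator emits.
EMBEDDED_TERMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "MI:0000": ("molecular interaction", ()),
    "MI:0001": ("interaction detection method", ("MI:0000",)),
    "MI:0003": ("feature detection method", ("MI:0000",)),
    "MI:0004": ("affinity chromatography technology", ("MI:0001",)),
    "MI:0018": ("two hybrid", ("MI:0001",)),
    "MI:0096": ("pull down", ("MI:0004",)),
    "MI:0113": ("western blot", ("MI:0003",)),
    "MI:0114": ("x-ray crystallography", ("MI:0001",)),
    "MI:0117": ("binding-associated region", ("MI:0000",)),
    "MI:0118": ("mutation", ("MI:0000",)),
    "MI:0252": ("biological feature", ("MI:0000",)),
    "MI:0326": ("protein", ("MI:0000",)),
    "MI:0328": ("small molecule", ("MI:0000",)),
    "MI:0319": ("deoxyribonucleic acid", ("MI:0000",)),
    "MI:0320": ("ribonucleic acid", ("MI:0000",)),
    "MI:0314": ("complex", ("MI:0000",)),
    "MI:0335": ("certain", ("MI:0000",)),
    "MI:0339": ("undetermined", ("MI:0000",)),
    "MI:0363": ("inferred by author", ("MI:0001",)),
    "MI:0364": ("inferred by curator", ("MI:0001",)),
    "MI:0367": ("green fluorescent protein tag", ("MI:0252",)),
    "MI:0396": ("predetermined participant", ("MI:0000",)),
    "MI:0407": ("direct interaction", ("MI:0000",)),
    "MI:0442": ("sufficient binding region", ("MI:0117",)),
    "MI:0496": ("bait", ("MI:0000",)),
    "MI:0498": ("prey", ("MI:0000",)),
    "MI:0499": ("unspecified role", ("MI:0000",)),
    "MI:0500": ("biological role", ("MI:0000",)),
    "MI:0501": ("enzyme", ("MI:0500",)),
    "MI:0502": ("enzyme target", ("MI:0500",)),
    "MI:0638": ("prerequisite-ptm", ("MI:0252",)),
    "MI:0821": ("molecular weight estimation by staining", ("MI:0003",)),
    "MI:0904": ("polysaccharide", ("MI:0000",)),
    "MI:0915": ("physical association", ("MI:0000",)),
    "MI:0925": ("observed-ptm", ("MI:0252",)),
    "MI:1304": ("molecule set", ("MI:0000",)),
    "MI:1154": ("positive cooperative effect outcome", ("MI:0000",)),
    "MI:1155": ("negative cooperative effect outcome", ("MI:0000",)),
    "MI:1157": ("allostery", ("MI:0000",)),
    "MI:1158": ("pre-assembly", ("MI:0000",)),
}

_MI_RE = re.compile(r"MI:\d{4}\Z")


@dataclass
class CvStore:
    """Accession -> (label, parents) lookup; lookups are total (an unknown
    accession returns ``None``, never raises)."""

    terms: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    @classmethod
    def embedded(cls) -> "CvStore":
        return cls(terms=dict(EMBEDDED_TERMS))

    def lookup(self, accession: str) -> Optional[tuple[str, tuple[str, ...]]]:
        return self.terms.get(accession)

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def load_cv(obo_stream) -> tuple[CvStore, list[ValidationFinding]]:
    """Build a :class:`CvStore` from an OBO 1.2/1.4 stream, merged over the
    embedded minimal table (the file wins on label conflicts).

    Returns the store and any findings (stanzas that could not be parsed are
    skipped with a warning).
    """
    store = CvStore.embedded()
    findings: list[ValidationFinding] = []
    if obo_stream is None:
        return store, findings
    try:
        import obonet

        graph = obonet.read_obo(obo_stream, ignore_obsolete=False)
    except Exception as exc:  # noqa: BLE001 - malformed input is a finding
        findings.append(ValidationFinding(
            "PARSE_ERROR", WARNING, "/obo",
            f"could not parse OBO stream ({exc}); using embedded terms only"))
        return store, findings
    for node, data in graph.nodes(data=True):
        if not _MI_RE.match(str(node)):
            continue
        label = data.get("name") or store.terms.get(node, ("",))[0]
        parents = tuple(
            p for p in data.get("is_a", []) if _MI_RE.match(str(p))
        )
        if not parents and node in store.terms:
            parents = store.terms[node][1]
        store.terms[node] = (label, parents)
    return store, findings


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

class _Validator:
    def __init__(self, profile: str, cv_store: CvStore,
                 suppress: frozenset[str]):
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        self.depth = PROFILES.index(profile)
        self.cv_store = cv_store
        self.suppress = suppress
        self.findings: list[ValidationFinding] = []

    def add(self, code, severity, path, message):
        if code not in self.suppress:
            self.findings.append(ValidationFinding(code, severity, path, message))

    # -- leaf checks -------------------------------------------------------

    def check_cv(self, cv: Optional[m.CvTerm], path: str) -> None:
        if cv is None:
            return
        if cv.short_label is None and cv.mi_accession is None:
            self.add("CVTERM_EMPTY", ERROR, path,
                     "CV term has neither a short label nor an MI accession")
        if cv.mi_accession is not None and not _MI_RE.match(cv.mi_accession):
            self.add("CV_FORMAT", ERROR, path,
                     f"accession {cv.mi_accession!r} does not match MI:nnnn")
        elif (self.depth >= 2 and cv.mi_accession is not None
              and cv.mi_accession not in self.cv_store):
            self.add("CV_UNKNOWN", WARNING, path,
                     f"accession {cv.mi_accession} not in the CV store")
        self.check_xref(cv.xref, f"{path}/xref")

    def check_xref(self, xref: Optional[m.Xref], path: str) -> None:
        if xref is None:
            return
        for i, ref in enumerate([xref.primary, *xref.secondary]):
            if not ref.db or not ref.id:
                self.add("XREF_INCOMPLETE", ERROR, f"{path}/*[{i + 1}]",
                         "cross-reference with empty db or id")

    def check_bibref(self, bibref: Optional[m.BibRef], path: str) -> None:
        if bibref is None:
            return
        if bibref.xref is None and not bibref.attributes:
            self.add("BIBREF_EMPTY", ERROR, path,
                     "bibref carries neither an xref nor attributes")
        self.check_xref(bibref.xref, f"{path}/xref")

    def check_organism(self, org: Optional[m.Organism], path: str) -> None:
        if org is not None and org.ncbi_tax_id == 0:
            self.add("ORGANISM_TAXID_ZERO", ERROR, path,
                     "ncbiTaxId 0 is not a valid taxon (use negative "
                     "sentinels for non-organism contexts)")

    def check_parameter(self, p: m.Parameter, path: str) -> None:
        if p.base < 2:
            self.add("PARAM_INVALID", ERROR, path,
                     f"parameter base {p.base} < 2")
        if not p.factor.is_finite():
            self.add("PARAM_INVALID", ERROR, path,
                     "parameter factor is not finite")

    # -- feature checks ----------------------------------------------------

    def _interactor_is_protein(self, p: m.Participant) -> bool:
        itor = p.entity if isinstance(p.entity, m.Interactor) else None
        return (itor is not None and itor.interactor_type is not None
                and itor.interactor_type.mi_accession == MI_PROTEIN)

    def check_feature(self, f: m.Feature, path: str,
                      on_protein: bool) -> None:
        self.check_cv(f.feature_type, f"{path}/featureType")
        self.check_cv(f.feature_role, f"{path}/featureRole")
        for i, dm in enumerate(f.detection_methods):
            self.check_cv(dm, f"{path}/featureDetectionMethod[{i + 1}]")
        if not f.ranges:
            self.add("FEATURE_NO_RANGE", ERROR, path,
                     "feature has no featureRange")
        if self.depth < 1:
            return
        if f.feature_role is not None and f.feature_role.mi_accession is None:
            self.add("FEATURE_ROLE_NO_ACC", ERROR, f"{path}/featureRole",
                     "featureRole must carry an MI accession")
        for i, r in enumerate(f.ranges):
            rpath = f"{path}/featureRange[{i + 1}]"
            rs = r.resulting_sequence
            if rs is not None:
                if rs.xref is None and (rs.original is None or rs.new is None):
                    self.add("RESSEQ_EMPTY", ERROR, f"{rpath}/resultingSequence",
                             "resultingSequence needs original+new sequences "
                             "or an xref")
                for seq in (rs.original, rs.new):
                    if seq and not set(seq.upper()) <= _IUPAC:
                        self.add("RESSEQ_ALPHABET", WARNING,
                                 f"{rpath}/resultingSequence",
                                 f"sequence {seq!r} contains non-IUPAC letters")
            certain = (r.begin_status.mi_accession == "MI:0335"
                       and r.end_status.mi_accession == "MI:0335")
            if (isinstance(r.begin, m.ExactPosition)
                    and isinstance(r.end, m.ExactPosition)):
                if certain and r.begin.value > r.end.value:
                    self.add("RANGE_INVERTED", ERROR, rpath,
                             f"begin {r.begin.value} > end {r.end.value}")
            for pos in (r.begin, r.end):
                values = []
                if isinstance(pos, m.ExactPosition):
                    values = [pos.value]
                elif isinstance(pos, m.IntervalPosition):
                    values = [pos.start, pos.end]
                if any(v == 0 for v in values):
                    self.add("POSITION_ZERO", WARNING, rpath,
                             "coordinate 0 has no biological meaning in "
                             "1-based coordinates")
                if on_protein and any(v < 0 for v in values):
                    self.add("NEG_POS_ON_PROTEIN", WARNING, rpath,
                             "negative coordinates describe upstream gene "
                             "regions, not protein sequences")

    # -- participant checks ------------------------------------------------

    def check_participant(self, p: m.Participant, path: str) -> None:
        if p.entity is None:
            self.add("PARTICIPANT_NO_ENTITY", ERROR, path,
                     "participant references no interactor, interaction or "
                     "candidate set")
        self.check_xref(p.xref, f"{path}/xref")
        self.check_cv(p.biological_role, f"{path}/biologicalRole")
        for i, cv in enumerate(p.experimental_roles):
            self.check_cv(cv, f"{path}/experimentalRole[{i + 1}]")
        for i, cv in enumerate(p.identification_methods):
            self.check_cv(cv, f"{path}/participantIdentificationMethod[{i + 1}]")
        for org in p.host_organisms:
            self.check_organism(org, f"{path}/hostOrganism")
        for i, param in enumerate(p.parameters):
            self.check_parameter(param, f"{path}/parameter[{i + 1}]")
        on_protein = self._interactor_is_protein(p)
        for i, f in enumerate(p.features):
            self.check_feature(f, f"{path}/feature[{i + 1}]", on_protein)
        if isinstance(p.entity, m.CandidateSet):
            cs = p.entity
            if not cs.candidates:
                self.add("CANDIDATE_SET_EMPTY", ERROR,
                         f"{path}/interactorCandidateList",
                         "candidate set has no candidates")
            self.check_cv(cs.set_type, f"{path}/moleculeSetType")
            for i, cand in enumerate(cs.candidates):
                cpath = f"{path}/interactorCandidate[{i + 1}]"
                if cand.interactor is None:
                    self.add("PARTICIPANT_NO_ENTITY", ERROR, cpath,
                             "candidate resolves to no interactor")
                for j, f in enumerate(cand.features):
                    self.check_feature(f, f"{cpath}/feature[{j + 1}]", False)
        elif isinstance(p.entity, m.Interactor):
            self.check_interactor_shallow(p.entity, f"{path}/interactor")
        if self.depth >= 1 and isinstance(p.stoichiometry, m.StoichiometryRange):
            st = p.stoichiometry
            if st.min_value > st.max_value:
                self.add("STOICH_RANGE_INVERTED", ERROR,
                         f"{path}/stoichiometryRange",
                         f"minValue {st.min_value} > maxValue {st.max_value}")
        if self.depth >= 1 and p.stoichiometry is not None:
            vals = ([p.stoichiometry.value]
                    if isinstance(p.stoichiometry, m.MeanStoichiometry)
                    else [p.stoichiometry.min_value, p.stoichiometry.max_value])
            if any(v < 0 for v in vals):
                self.add("STOICH_NEGATIVE", ERROR, f"{path}/stoichiometry",
                         "stoichiometry values must be >= 0")

    _checked_interactors: set[int]

    def check_interactor_shallow(self, itor: m.Interactor, path: str) -> None:
        if id(itor) in self._checked_interactors:
            return
        self._checked_interactors.add(id(itor))
        self.check_cv(itor.interactor_type, f"{path}/interactorType")
        self.check_xref(itor.xref, f"{path}/xref")
        self.check_organism(itor.organism, f"{path}/organism")

    # -- experiment / interaction / entry ---------------------------------

    def check_experiment(self, exp: m.Experiment, path: str) -> None:
        self.check_bibref(exp.bibref, f"{path}/bibref")
        self.check_cv(exp.interaction_detection_method,
                      f"{path}/interactionDetectionMethod")
        self.check_cv(exp.participant_identification_method,
                      f"{path}/participantIdentificationMethod")
        self.check_cv(exp.feature_detection_method,
                      f"{path}/featureDetectionMethod")
        for org in exp.host_organisms:
            self.check_organism(org, f"{path}/hostOrganism")
        if self.depth >= 1 and (exp.bibref is None
                                or exp.interaction_detection_method is None):
            self.add("EXPERIMENT_INCOMPLETE", ERROR, path,
                     "experiment needs a bibref and an "
                     "interactionDetectionMethod")
        for i, vp in enumerate(exp.variable_parameters):
            vpath = f"{path}/variableParameter[{i + 1}]"
            if not vp.description or not vp.values:
                self.add("VARPARAM_INCOMPLETE", ERROR, vpath,
                         "variableParameter needs a description and at "
                         "least one value")
            self.check_cv(vp.unit, f"{vpath}/unit")
            if self.depth >= 1:
                orders = [v.order for v in vp.values if v.order is not None]
                dupes = sorted({o for o in orders if orders.count(o) > 1})
                for o in dupes:
                    self.add("ORDER_DUPLICATE", WARNING, vpath,
                             f"order value {o} used more than once")

    def check_interaction(self, inter: m.InteractionEvidence, path: str) -> None:
        self.check_xref(inter.xref, f"{path}/xref")
        for i, cv in enumerate(inter.interaction_types):
            self.check_cv(cv, f"{path}/interactionType[{i + 1}]")
        for i, p in enumerate(inter.participants):
            self.check_participant(p, f"{path}/participant[{i + 1}]")
        for i, param in enumerate(inter.parameters):
            self.check_parameter(param, f"{path}/parameter[{i + 1}]")

    def check_abstract(self, inter: m.AbstractInteraction, path: str) -> None:
        self.check_xref(inter.xref, f"{path}/xref")
        self.check_cv(inter.interactor_type, f"{path}/interactorType")
        self.check_cv(inter.interaction_type, f"{path}/interactionType")
        self.check_cv(inter.evidence_type, f"{path}/evidenceType")
        self.check_organism(inter.organism, f"{path}/organism")
        if self.depth >= 1 and inter.experiments:
            self.add("ABSTRACT_HAS_EXPERIMENT", ERROR, path,
                     "abstract interactions are evidence-free; experiments "
                     "belong on evidence interactions")
        for i, p in enumerate(inter.participants):
            self.check_participant(p, f"{path}/participant[{i + 1}]")
        for i, eff in enumerate(inter.cooperative_effects):
            epath = f"{path}/cooperativeEffect[{i + 1}]"
            self.check_cv(eff.outcome, f"{epath}/cooperativeEffectOutcome")
            self.check_cv(eff.response, f"{epath}/cooperativeEffectResponse")
            for ev in eff.evidence:
                self.check_bibref(ev.bibref, f"{epath}/bibref")
                for cv in ev.methods:
                    self.check_cv(cv, f"{epath}/evidenceMethod")
            if isinstance(eff, m.Allostery):
                self.check_cv(eff.allostery_type, f"{epath}/allosteryType")
                self.check_cv(eff.allosteric_mechanism,
                              f"{epath}/allostericMechanism")

    def check_entry(self, entry: m.Entry, path: str) -> None:
        self._checked_interactors = set()
        seen_ids: dict[int, str] = {}
        for obj in m.iter_identified(entry):
            kind = type(obj).__name__
            if obj.id in seen_ids:
                self.add("DUPLICATE_ID", ERROR, path,
                         f"id {obj.id} used by both {seen_ids[obj.id]} "
                         f"and {kind}")
            else:
                seen_ids[obj.id] = kind
        if entry.source is not None:
            self.check_xref(entry.source.xref, f"{path}/source/xref")
            self.check_bibref(entry.source.bibref, f"{path}/source/bibref")
        for i, exp in enumerate(entry.experiments):
            self.check_experiment(exp, f"{path}/experimentDescription[{i + 1}]")
        for i, itor in enumerate(entry.interactors):
            self.check_interactor_shallow(itor, f"{path}/interactor[{i + 1}]")
        kinds = set()
        for i, inter in enumerate(entry.interactions):
            ipath = f"{path}/interaction[{i + 1}]"
            if isinstance(inter, m.AbstractInteraction):
                kinds.add("abstract")
                self.check_abstract(inter, ipath)
            else:
                kinds.add("evidence")
                self.check_interaction(inter, ipath)
        if self.depth >= 1 and len(kinds) == 2:
            self.add("MIXED_INTERACTION_KINDS", WARNING,
                     f"{path}/interactionList",
                     "entry mixes evidence and abstract interactions in one "
                     "interactionList")


def validate(doc: m.Document, profile: str = "semantic",
             cv_store: Optional[CvStore] = None,
             suppress: Iterable[str] = ()) -> list[ValidationFinding]:
    """Validate a document at the given profile; returns ordered findings
    (never raises on document content)."""
    v = _Validator(profile, cv_store or CvStore.embedded(), frozenset(suppress))
    for i, entry in enumerate(doc.entries):
        v.check_entry(entry, f"/entrySet/entry[{i + 1}]")
    return v.findings


def errors_only(findings: Iterable[ValidationFinding]) -> list[ValidationFinding]:
    return [f for f in findings if f.severity == ERROR]
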
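"""In-memory object model for PSI-MI molecular-interaction documents.

The model mirrors the MIF (PSI-MI XML) level 3.0 element set: experiments,
interactors, evidence interactions, abstract (modelled) interactions such as
curated complexes, participants with features and stoichiometry, variable
experimental parameters for dynamic interactions, interactor candidate sets
(molecule sets) and cooperative effects (allostery / pre-assembly).

Design notes
------------
* All cross-references (participant -> interactor, cooperative effect ->
  affected interaction, ...) are held as direct Python object references.
  The integer ``id`` carried by identified objects exists only so documents
  can be serialized with id references; :func:`semantic_equal` ignores id
  *values* entirely and compares the reference graph structurally.
* Whether an interactor or experiment is written inline (extended form) or
  referenced from a list (compact form) is a serialization concern and is
  deliberately not represented here.
* Decimal quantities (stoichiometries, parameter factors) are stored as
  :class:`decimal.Decimal` built from the lexical form found in the file, so
  ``2.50`` survives a round trip as ``2.50``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields, is_dataclass
from decimal import Decimal
from typing import Optional, Union

MI_ACCESSION_RE = r"MI:\d{4}"

LEVEL_25 = "2.5"
LEVEL_30 = "3.0"


# ---------------------------------------------------------------------------
# leaf types
# ---------------------------------------------------------------------------

@dataclass
class DbReference:
    """A single database cross-reference (``primaryRef``/``secondaryRef``)."""

    db: str
    id: str
    db_ac: Optional[str] = None
    version: Optional[str] = None
    ref_type: Optional[str] = None
    ref_type_ac: Optional[str] = None


@dataclass
class Xref:
    primary: DbReference
    secondary: list[DbReference] = field(default_factory=list)


@dataclass
class Attribute:
    """Free-text annotation (``<attribute name=... nameAc=...>value``)."""

    name: str
    name_ac: Optional[str] = None
    value: Optional[str] = None


@dataclass
class Names:
    short_label: Optional[str] = None
    full_name: Optional[str] = None
    aliases: list[str] = field(default_factory=list)


@dataclass
class CvTerm:
    """A controlled-vocabulary term, normally carrying an MI:nnnn accession."""

    short_label: Optional[str] = None
    full_name: Optional[str] = None
    mi_accession: Optional[str] = None
    xref: Optional[Xref] = None


@dataclass
class BibRef:
    """A bibliographic reference.

    At level 3.0 a publication may carry *both* an identifying xref (e.g. a
    PubMed id) and descriptive attributes (title, authors, date); level 2.5
    only allowed one of the two.
    """

    xref: Optional[Xref] = None
    attributes: list[Attribute] = field(default_factory=list)


@dataclass
class Organism:
    """Host or source organism; negative taxids are conventional sentinels
    (-1 in vitro, -2 chemical synthesis, ...) and therefore permitted."""

    ncbi_tax_id: int
    names: Optional[Names] = None
    cell_type: Optional[CvTerm] = None
    compartment: Optional[CvTerm] = None
    tissue: Optional[CvTerm] = None


@dataclass
class Parameter:
    """A measured quantity: value = factor * base ** exponent [unit]."""

    term: str
    term_ac: Optional[str] = None
    unit: Optional[str] = None
    unit_ac: Optional[str] = None
    base: int = 10
    exponent: int = 0
    factor: Decimal = Decimal(0)
    uncertainty: Optional[Decimal] = None
    experiment: Optional["Experiment"] = None


@dataclass
class Confidence:
    unit: CvTerm
    value: str


# ---------------------------------------------------------------------------
# experiments and dynamic conditions
# ---------------------------------------------------------------------------

@dataclass
class VariableValue:
    """One value of a variable experimental condition; ``order`` positions it
    within a series (e.g. successive time points)."""

    id: int
    value: str
    order: Optional[int] = None


@dataclass
class VariableParameter:
    """A condition varied within one experiment (agonist concentration,
    hours post-infection, cell-cycle stage, ...)."""

    description: str
    unit: Optional[CvTerm] = None
    values: list[VariableValue] = field(default_factory=list)


@dataclass
class Experiment:
    id: int = 0
    names: Optional[Names] = None
    bibref: Optional[BibRef] = None
    xref: Optional[Xref] = None
    host_organisms: list[Organism] = field(default_factory=list)
    interaction_detection_method: Optional[CvTerm] = None
    participant_identification_method: Optional[CvTerm] = None
    feature_detection_method: Optional[CvTerm] = None
    variable_parameters: list[VariableParameter] = field(default_factory=list)
    confidences: list[Confidence] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)


# ---------------------------------------------------------------------------
# interactors and features
# ---------------------------------------------------------------------------

@dataclass
class Interactor:
    id: int = 0
    names: Optional[Names] = None
    xref: Optional[Xref] = None
    interactor_type: Optional[CvTerm] = None
    organism: Optional[Organism] = None
    sequence: Optional[str] = None
    attributes: list[Attribute] = field(default_factory=list)


@dataclass
class ExactPosition:
    """A single signed sequence coordinate; negative values are upstream
    (promoter-region) coordinates relative to the sequence start."""

    value: int


@dataclass
class IntervalPosition:
    start: int
    end: int


@dataclass
class UnstatedPosition:
    """Position carried entirely by its range status (undetermined, n-term...)."""


Position = Union[ExactPosition, IntervalPosition, UnstatedPosition]


@dataclass
class ResultingSequence:
    """Sequence change introduced by a mutation feature: the original and the
    new (mutated) stretch, and/or an external cross-reference (e.g. a SNP
    record) describing the change."""

    original: Optional[str] = None
    new: Optional[str] = None
    xref: Optional[Xref] = None


@dataclass
class FeatureRange:
    begin_status: CvTerm = field(default_factory=CvTerm)
    begin: Position = field(default_factory=UnstatedPosition)
    end_status: CvTerm = field(default_factory=CvTerm)
    end: Position = field(default_factory=UnstatedPosition)
    is_link: bool = False
    resulting_sequence: Optional[ResultingSequence] = None


@dataclass
class Feature:
    """A sequence feature on a participant (binding region, tag, mutation,
    PTM).  ``detection_methods`` is repeatable — the same PTM may have been
    seen both by a specific antibody and by mass spectrometry — and
    ``feature_role`` states the feature's causal role in the interaction
    (prerequisite-PTM, observed-PTM, ...).  Kinetic parameters tied to a
    specific mutation live here rather than on the interaction."""

    id: int = 0
    names: Optional[Names] = None
    xref: Optional[Xref] = None
    feature_type: Optional[CvTerm] = None
    feature_role: Optional[CvTerm] = None
    detection_methods: list[CvTerm] = field(default_factory=list)
    ranges: list[FeatureRange] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

@dataclass
class MeanStoichiometry:
    value: Decimal = Decimal(1)


@dataclass
class StoichiometryRange:
    min_value: Decimal = Decimal(0)
    max_value: Decimal = Decimal(0)


StoichiometryValue = Union[MeanStoichiometry, StoichiometryRange]


@dataclass
class Candidate:
    """One member of a molecule set, optionally with its own binding
    features."""

    id: int = 0
    interactor: Optional[Interactor] = None
    features: list[Feature] = field(default_factory=list)


@dataclass
class CandidateSet:
    """A molecule set: the participant is exactly one of several
    indistinguishable molecules (e.g. calmodulin, an identical protein
    produced by the CALM1, CALM2 and CALM3 genes)."""

    set_type: CvTerm = field(default_factory=CvTerm)
    candidates: list[Candidate] = field(default_factory=list)


@dataclass
class InteractionRef:
    """Participant entity pointing at another interaction in the same entry —
    the mechanism behind hierarchical complexes built from sub-complexes."""

    target: "Interaction" = None  # type: ignore[assignment]


ParticipantEntity = Union[Interactor, InteractionRef, CandidateSet]


@dataclass
class Participant:
    id: int = 0
    names: Optional[Names] = None
    xref: Optional[Xref] = None
    entity: Optional[ParticipantEntity] = None
    biological_role: Optional[CvTerm] = None
    experimental_roles: list[CvTerm] = field(default_factory=list)
    identification_methods: list[CvTerm] = field(default_factory=list)
    experimental_preparations: list[CvTerm] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)
    host_organisms: list[Organism] = field(default_factory=list)
    confidences: list[Confidence] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    stoichiometry: Optional[StoichiometryValue] = None
    attributes: list[Attribute] = field(default_factory=list)


@dataclass
class InferredInteraction:
    """A binding-site inference linking participants and/or specific features
    of participants within one interaction."""

    points: list[Union[Participant, Feature]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

@dataclass
class InteractionEvidence:
    """An interaction backed by at least one experiment.

    ``condition_sets`` lists, per observation, the variable-parameter values
    (from the owning experiments) under which this interaction was seen —
    each inner list is one combination of conditions.
    """

    id: int = 0
    names: Optional[Names] = None
    xref: Optional[Xref] = None
    experiments: list[Experiment] = field(default_factory=list)
    participants: list[Participant] = field(default_factory=list)
    inferred_interactions: list[InferredInteraction] = field(default_factory=list)
    interaction_types: list[CvTerm] = field(default_factory=list)
    negative: bool = False
    intra_molecular: bool = False
    confidences: list[Confidence] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    condition_sets: list[list[VariableValue]] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)


@dataclass
class CooperativityEvidence:
    """Publication + methods from which a cooperative effect was inferred."""

    bibref: BibRef = field(default_factory=BibRef)
    methods: list[CvTerm] = field(default_factory=list)


@dataclass
class MoleculeEffector:
    participant: Participant = None  # type: ignore[assignment]


@dataclass
class FeatureModificationEffector:
    feature: Feature = None  # type: ignore[assignment]


Effector = Union[MoleculeEffector, FeatureModificationEffector]


@dataclass
class Preassembly:
    """Cooperative effect through generation or abrogation of a binding site
    by an interaction or enzymatic modification."""

    evidence: list[CooperativityEvidence] = field(default_factory=list)
    affected: list["Interaction"] = field(default_factory=list)
    outcome: CvTerm = field(default_factory=CvTerm)
    response: Optional[CvTerm] = None


@dataclass
class Allostery:
    """Cooperative effect through a change of binding/catalytic properties at
    one site of a molecule caused by an event at a distinct site of the same
    molecule."""

    evidence: list[CooperativityEvidence] = field(default_factory=list)
    affected: list["Interaction"] = field(default_factory=list)
    outcome: CvTerm = field(default_factory=CvTerm)
    response: Optional[CvTerm] = None
    allosteric_molecule: Participant = None  # type: ignore[assignment]
    effector: Optional[Effector] = None
    allostery_type: Optional[CvTerm] = None
    allosteric_mechanism: Optional[CvTerm] = None


CooperativeEffect = Union[Preassembly, Allostery]


@dataclass
class AbstractInteraction:
    """A modelled, evidence-free interaction — typically a curated reference
    complex — assembled from multiple experiments or publications.

    ``experiments`` must stay empty on valid documents; the field exists so
    that malformed input (an abstract interaction carrying experiment
    references) can be represented and flagged by the validator rather than
    silently dropped.
    """

    id: int = 0
    names: Optional[Names] = None
    xref: Optional[Xref] = None
    interactor_type: Optional[CvTerm] = None
    interaction_type: Optional[CvTerm] = None
    organism: Optional[Organism] = None
    participants: list[Participant] = field(default_factory=list)
    binding_features: list[list[Feature]] = field(default_factory=list)
    cooperative_effects: list[CooperativeEffect] = field(default_factory=list)
    evidence_type: Optional[CvTerm] = None
    attributes: list[Attribute] = field(default_factory=list)
    experiments: list[Experiment] = field(default_factory=list)


Interaction = Union[InteractionEvidence, AbstractInteraction]


# ---------------------------------------------------------------------------
# entry / document
# ---------------------------------------------------------------------------

@dataclass
class Source:
    names: Optional[Names] = None
    bibref: Optional[BibRef] = None
    xref: Optional[Xref] = None
    release_date: Optional[str] = None
    attributes: list[Attribute] = field(default_factory=list)


@dataclass
class Availability:
    id: int = 0
    value: str = ""


@dataclass
class Entry:
    """One self-contained block of interaction data: a source database plus
    its experiment / interactor pools and the interaction list.  All ids live
    in a single integer namespace shared by every identified object in the
    entry."""

    source: Optional[Source] = None
    availabilities: list[Availability] = field(default_factory=list)
    experiments: list[Experiment] = field(default_factory=list)
    interactors: list[Interactor] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)


@dataclass
class Document:
    entries: list[Entry] = field(default_factory=list)
    level: str = LEVEL_30


@dataclass
class Diff:
    path: str
    description: str


@dataclass
class EquivalenceResult:
    equal: bool
    diffs: list[Diff] = field(default_factory=list)


# ---------------------------------------------------------------------------
# graph walking helpers
# ---------------------------------------------------------------------------

def iter_participant_features(participant: Participant):
    yield from participant.features
    if isinstance(participant.entity, CandidateSet):
        for cand in participant.entity.candidates:
            yield from cand.features


def iter_interaction_features(interaction: Interaction):
    for p in interaction.participants:
        yield from iter_participant_features(p)


def entry_experiments_in_use(entry: Entry) -> list[Experiment]:
    """Experiments reachable from interactions, in first-use document order."""
    seen: dict[int, Experiment] = {}
    for inter in entry.interactions:
        for exp in getattr(inter, "experiments", []):
            if id(exp) not in seen:
                seen[id(exp)] = exp
    return list(seen.values())


def entry_interactors_in_use(entry: Entry) -> list[Interactor]:
    seen: dict[int, Interactor] = {}

    def visit(obj: Optional[Interactor]):
        if obj is not None and id(obj) not in seen:
            seen[id(obj)] = obj

    for inter in entry.interactions:
        for p in inter.participants:
            if isinstance(p.entity, Interactor):
                visit(p.entity)
            elif isinstance(p.entity, CandidateSet):
                for cand in p.entity.candidates:
                    visit(cand.interactor)
    return list(seen.values())


def iter_identified(entry: Entry):
    """Yield every id-carrying object of an entry in canonical document
    order: availabilities, experiment pool (with variable values), interactor
    pool, then interactions with their participants, candidates and
    features."""
    for av in entry.availabilities:
        yield av
    for exp in entry.experiments:
        yield exp
        for vp in exp.variable_parameters:
            yield from vp.values
    for itor in entry.interactors:
        yield itor
    for inter in entry.interactions:
        yield inter
        for p in inter.participants:
            yield p
            if isinstance(p.entity, CandidateSet):
                for cand in p.entity.candidates:
                    yield cand
                    for f in cand.features:
                        yield f
            for f in p.features:
                yield f
        # malformed abstract interactions may carry experiments not in the pool
        for exp in getattr(inter, "experiments", []):
            if all(exp is not e for e in entry.experiments):
                yield exp


# ---------------------------------------------------------------------------
# semantic equality
# ---------------------------------------------------------------------------

#: dataclass fields never compared (identity bookkeeping, not content)
_IGNORED_FIELDS = {"id"}

#: (class, field) pairs compared as multisets — the schema treats these
#: lists as unordered collections.
_UNORDERED = {
    (Xref, "secondary"),
    (CandidateSet, "candidates"),
}


def _is_attr_list(value) -> bool:
    return isinstance(value, list) and value and all(
        isinstance(v, Attribute) for v in value
    )


class _Comparator:
    def __init__(self) -> None:
        self.diffs: list[Diff] = []
        self._in_progress: set[tuple[int, int]] = set()

    def compare(self, a, b, path: str) -> None:
        if a is None or b is None:
            if (a is None) != (b is None):
                self.diffs.append(Diff(path, f"{_describe(a)} != {_describe(b)}"))
            return
        if isinstance(a, (str, int, bool)) or isinstance(b, (str, int, bool)):
            if type(a) is not type(b) or a != b:
                self.diffs.append(Diff(path, f"{a!r} != {b!r}"))
            return
        if isinstance(a, Decimal) and isinstance(b, Decimal):
            if a != b:
                self.diffs.append(Diff(path, f"{a} != {b}"))
            return
        if isinstance(a, list) and isinstance(b, list):
            self._compare_list(a, b, path, unordered=False)
            return
        if not (is_dataclass(a) and is_dataclass(b)):
            if a != b:
                self.diffs.append(Diff(path, f"{a!r} != {b!r}"))
            return
        if type(a) is not type(b):
            self.diffs.append(
                Diff(path, f"{type(a).__name__} != {type(b).__name__}")
            )
            return
        key = (id(a), id(b))
        if key in self._in_progress:
            return  # already being compared higher up (shared object / cycle)
        self._in_progress.add(key)
        try:
            for f in fields(a):
                if f.name in _IGNORED_FIELDS:
                    continue
                va, vb = getattr(a, f.name), getattr(b, f.name)
                sub = f"{path}.{f.name}"
                if isinstance(va, list) and isinstance(vb, list):
                    unordered = (type(a), f.name) in _UNORDERED or (
                        _is_attr_list(va) or _is_attr_list(vb)
                    )
                    self._compare_list(va, vb, sub, unordered=unordered)
                else:
                    self.compare(va, vb, sub)
        finally:
            self._in_progress.discard(key)

    def _compare_list(self, a: list, b: list, path: str, unordered: bool) -> None:
        if len(a) != len(b):
            self.diffs.append(Diff(path, f"length {len(a)} != {len(b)}"))
            return
        if unordered:
            remaining = list(range(len(b)))
            for i, va in enumerate(a):
                match = None
                for j in remaining:
                    if self._equal_quiet(va, b[j]):
                        match = j
                        break
                if match is None:
                    self.diffs.append(
                        Diff(f"{path}[{i}]", "no matching element in other list")
                    )
                else:
                    remaining.remove(match)
        else:
            for i, (va, vb) in enumerate(zip(a, b)):
                self.compare(va, vb, f"{path}[{i}]")

    def _equal_quiet(self, a, b) -> bool:
        sub = _Comparator()
        sub._in_progress = set(self._in_progress)
        sub.compare(a, b, "")
        return not sub.diffs


def _describe(v) -> str:
    return "absent" if v is None else type(v).__name__


def semantic_equal(a: Document, b: Document) -> EquivalenceResult:
    """Compare two documents for semantic equality.

    Id values are ignored (only the shape of the reference graph matters);
    attribute lists, secondary xrefs and candidate lists compare as
    multisets; every other list is order-sensitive.
    """
    cmp = _Comparator()
    cmp.compare(a, b, "document")
    return EquivalenceResult(equal=not cmp.diffs, diffs=cmp.diffs)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _attr_sort_key(attr: Attribute):
    return (attr.name, attr.name_ac or "", attr.value or "")


def _dbref_sort_key(ref: DbReference):
    return (ref.db, ref.id, ref.ref_type or "", ref.version or "")


def _candidate_sort_key(cand: Candidate):
    itor = cand.interactor
    if itor is not None and itor.names is not None:
        return (itor.names.short_label or "", itor.names.full_name or "")
    return ("", "")


def _canonical_order(entry: Entry) -> None:
    def sort_attrs(obj) -> None:
        obj.attributes.sort(key=_attr_sort_key)

    def sort_xref(xref: Optional[Xref]) -> None:
        if xref is not None:
            xref.secondary.sort(key=_dbref_sort_key)

    def visit_cv(cv: Optional[CvTerm]) -> None:
        if cv is not None:
            sort_xref(cv.xref)

    def visit_feature(f: Feature) -> None:
        sort_attrs(f)
        sort_xref(f.xref)
        visit_cv(f.feature_type)
        visit_cv(f.feature_role)
        for dm in f.detection_methods:
            visit_cv(dm)
        for r in f.ranges:
            if r.resulting_sequence is not None:
                sort_xref(r.resulting_sequence.xref)

    def visit_participant(p: Participant) -> None:
        sort_attrs(p)
        sort_xref(p.xref)
        for f in p.features:
            visit_feature(f)
        if isinstance(p.entity, CandidateSet):
            for cand in p.entity.candidates:
                for f in cand.features:
                    visit_feature(f)
            p.entity.candidates.sort(key=_candidate_sort_key)

    if entry.source is not None:
        sort_attrs(entry.source)
        sort_xref(entry.source.xref)
    sort_attrs(entry)
    for exp in entry.experiments:
        sort_attrs(exp)
        sort_xref(exp.xref)
        if exp.bibref is not None:
            exp.bibref.attributes.sort(key=_attr_sort_key)
            sort_xref(exp.bibref.xref)
    for itor in entry.interactors:
        sort_attrs(itor)
        sort_xref(itor.xref)
    for inter in entry.interactions:
        sort_attrs(inter)
        sort_xref(inter.xref)
        for p in inter.participants:
            visit_participant(p)


def normalize(doc: Document) -> Document:
    """Return a normalized deep copy: dense ids from 1 in document order,
    canonical ordering of unordered lists, pools completed with every object
    the interactions reference.  Idempotent; never drops content."""
    doc = copy.deepcopy(doc)
    for entry in doc.entries:
        # canonical ordering first: it may reorder candidates, which feeds
        # into the first-use order of the pools below
        _canonical_order(entry)
        # pools in canonical order: objects in first-use order, then any
        # declared-but-unreferenced ones in their declared order
        used_exp = entry_experiments_in_use(entry)
        used_exp_ids = {id(e) for e in used_exp}
        entry.experiments = used_exp + [
            e for e in entry.experiments if id(e) not in used_exp_ids]
        used_itor = entry_interactors_in_use(entry)
        used_itor_ids = {id(i) for i in used_itor}
        entry.interactors = used_itor + [
            i for i in entry.interactors if id(i) not in used_itor_ids]
        next_id = 1
        for obj in iter_identified(entry):
            obj.id = next_id
            next_id += 1
    return doc
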
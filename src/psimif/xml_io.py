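"""Reading and writing PSI-MI XML (MIF) documents, levels 2.5 and 3.0.

Both document forms are supported:

* **compact** — experiments and interactors are defined once in entry-level
  list elements and referenced by id from the interactions (the default;
  suited to larger datasets);
* **extended** — every experiment and interactor is written inline where it
  is used, so all related data sits together.

Reading either form produces the same object graph: id references are
resolved to shared Python objects.  Writing normalizes the document first
(dense ids, canonical ordering), so ``read(write(d, f))`` is semantically
equal to ``normalize(d)`` for both forms.

Streams may be plain or gzip-compressed; compression is sniffed from the
magic bytes, never from the file name.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from . import model as m
from .findings import ERROR, INFO, WARNING, ValidationFinding

NS_30 = "http://psi.hupo.org/mi/mif300"
NS_25 = "http://psi.hupo.org/mi/mif"

_NS_TO_LEVEL = {NS_30: m.LEVEL_30, NS_25: m.LEVEL_25}

COMPACT = "compact"
EXTENDED = "extended"


class MifError(Exception):
    """Base class for reader/writer failures."""


class MifParseError(MifError):
    pass


class UnknownNamespaceError(MifError):
    def __init__(self, namespace: Optional[str]):
        self.namespace = namespace
        super().__init__(
            f"root element is in unrecognized namespace {namespace!r}; "
            f"expected {NS_25!r} (level 2.5) or {NS_30!r} (level 3.0)"
        )


class Level30ContentError(MifError):
    """Raised when a document declared at level 2.5 still carries 3.0-only
    content; run :func:`psimif.convert25.downgrade` first."""

    def __init__(self, details: list[str]):
        self.details = details
        super().__init__(
            "document is at level 2.5 but uses 3.0-only constructs "
            "(downgrade it with psimif.convert25.downgrade first): "
            + "; ".join(details)
        )


@dataclass
class ReadResult:
    document: Optional[m.Document]
    findings: list[ValidationFinding] = field(default_factory=list)
    level_detected: Optional[str] = None

    @property
    def fatal(self) -> bool:
        return self.document is None


# ---------------------------------------------------------------------------
# stream plumbing
# ---------------------------------------------------------------------------

def _open_source(source) -> bytes:
    if isinstance(source, bytes):
        data = source
    elif isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
    elif hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            data = data.encode("utf-8")
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported source type {type(source).__name__}")
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data


def _local(el) -> str:
    return etree.QName(el).localname


def detect_level(source) -> str:
    """Return ``"2.5"`` or ``"3.0"`` from the root element's namespace (or,
    failing that, its level/version attributes)."""
    data = _open_source(source)
    try:
        root = next(etree.iterparse(io.BytesIO(data), events=("start",)))[1]
    except (etree.XMLSyntaxError, StopIteration) as exc:
        raise MifParseError(f"not well-formed XML: {exc}") from exc
    ns = etree.QName(root).namespace
    if ns in _NS_TO_LEVEL:
        return _NS_TO_LEVEL[ns]
    if ns is None:
        level = root.get("level")
        version = root.get("version")
        if level == "3" and version == "0":
            return m.LEVEL_30
        if level == "2" and version == "5":
            return m.LEVEL_25
    raise UnknownNamespaceError(ns)


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------

class _Reader:
    def __init__(self, strict: bool):
        self.strict = strict
        self.findings: list[ValidationFinding] = []
        self.fatal = False
        self.ids: dict[int, object] = {}

    # -- diagnostics -------------------------------------------------------

    def finding(self, code, severity, path, message):
        self.findings.append(ValidationFinding(code, severity, path, message))
        if severity == ERROR:
            self.fatal = True

    def dangling(self, path: str, ref_id: int, what: str) -> None:
        sev = ERROR if self.strict else WARNING
        self.finding(
            "DANGLING_REF", sev, path,
            f"{what} reference to undefined id {ref_id}"
            + ("" if self.strict else "; reference dropped"),
        )

    def resolve(self, el, path: str, what: str, cls=None):
        try:
            ref_id = int((el.text or "").strip())
        except ValueError:
            self.dangling(path, -1, what)
            return None
        obj = self.ids.get(ref_id)
        if obj is None or (cls is not None and not isinstance(obj, cls)):
            self.dangling(path, ref_id, what)
            return None
        return obj

    def register(self, obj) -> None:
        self.ids[obj.id] = obj

    # -- generic helpers ---------------------------------------------------

    def child(self, el, name):
        for c in el:
            if isinstance(c.tag, str) and _local(c) == name:
                return c
        return None

    def children(self, el, name):
        return [
            c for c in el if isinstance(c.tag, str) and _local(c) == name
        ]

    def text(self, el, name) -> Optional[str]:
        c = self.child(el, name)
        return None if c is None else (c.text or "")

    def int_attr(self, el, name, default=None) -> Optional[int]:
        v = el.get(name)
        return default if v is None else int(v)

    def dec_attr(self, el, name) -> Optional[Decimal]:
        v = el.get(name)
        if v is None:
            return None
        try:
            return Decimal(v)
        except InvalidOperation:
            return None

    # -- leaf parsers ------------------------------------------------------

    def parse_names(self, el) -> m.Names:
        return m.Names(
            short_label=self.text(el, "shortLabel"),
            full_name=self.text(el, "fullName"),
            aliases=[c.text or "" for c in self.children(el, "alias")],
        )

    def parse_dbref(self, el) -> m.DbReference:
        return m.DbReference(
            db=el.get("db", ""),
            id=el.get("id", ""),
            db_ac=el.get("dbAc"),
            version=el.get("version"),
            ref_type=el.get("refType"),
            ref_type_ac=el.get("refTypeAc"),
        )

    def parse_xref(self, el) -> Optional[m.Xref]:
        primary = self.child(el, "primaryRef")
        if primary is None:
            return None
        return m.Xref(
            primary=self.parse_dbref(primary),
            secondary=[self.parse_dbref(c) for c in self.children(el, "secondaryRef")],
        )

    def parse_attributes(self, el) -> list[m.Attribute]:
        if el is None:
            return []
        return [
            m.Attribute(name=c.get("name", ""), name_ac=c.get("nameAc"),
                        value=c.text)
            for c in self.children(el, "attribute")
        ]

    def parse_bibref(self, el) -> m.BibRef:
        xref_el = self.child(el, "xref")
        return m.BibRef(
            xref=self.parse_xref(xref_el) if xref_el is not None else None,
            attributes=self.parse_attributes(self.child(el, "attributeList")),
        )

    def parse_cv(self, el) -> m.CvTerm:
        cv = m.CvTerm()
        names_el = self.child(el, "names")
        if names_el is not None:
            names = self.parse_names(names_el)
            cv.short_label = names.short_label
            cv.full_name = names.full_name
        xref_el = self.child(el, "xref")
        if xref_el is not None:
            xref = self.parse_xref(xref_el)
            if xref is not None:
                if xref.primary.db == "psi-mi" and re.fullmatch(
                    m.MI_ACCESSION_RE, xref.primary.id
                ):
                    cv.mi_accession = xref.primary.id
                    if xref.secondary:
                        cv.xref = m.Xref(
                            primary=xref.secondary[0],
                            secondary=xref.secondary[1:],
                        )
                else:
                    cv.xref = xref
        return cv

    def opt_cv(self, el, name) -> Optional[m.CvTerm]:
        c = self.child(el, name)
        return None if c is None else self.parse_cv(c)

    def parse_organism(self, el) -> m.Organism:
        names_el = self.child(el, "names")
        return m.Organism(
            ncbi_tax_id=self.int_attr(el, "ncbiTaxId", 0) or 0,
            names=self.parse_names(names_el) if names_el is not None else None,
            cell_type=self.opt_cv(el, "cellType"),
            compartment=self.opt_cv(el, "compartment"),
            tissue=self.opt_cv(el, "tissue"),
        )

    def parse_organism_list(self, el, name="hostOrganismList",
                            item="hostOrganism") -> list[m.Organism]:
        lst = self.child(el, name)
        if lst is None:
            return []
        return [self.parse_organism(c) for c in self.children(lst, item)]

    def parse_confidences(self, el) -> list[m.Confidence]:
        lst = self.child(el, "confidenceList")
        if lst is None:
            return []
        out = []
        for c in self.children(lst, "confidence"):
            unit = self.opt_cv(c, "unit") or m.CvTerm()
            out.append(m.Confidence(unit=unit, value=self.text(c, "value") or ""))
        return out

    def parse_parameter(self, el, path: str) -> m.Parameter:
        unc = self.dec_attr(el, "uncertainty")
        param = m.Parameter(
            term=el.get("term", ""),
            term_ac=el.get("termAc"),
            unit=el.get("unit"),
            unit_ac=el.get("unitAc"),
            base=self.int_attr(el, "base", 10),
            exponent=self.int_attr(el, "exponent", 0),
            factor=self.dec_attr(el, "factor") or Decimal(0),
            uncertainty=unc,
        )
        ref = self.child(el, "experimentRef")
        if ref is not None:
            param.experiment = self.resolve(ref, path, "experiment", m.Experiment)
        return param

    def parse_parameters(self, el, path: str) -> list[m.Parameter]:
        lst = self.child(el, "parameterList")
        if lst is None:
            return []
        return [
            self.parse_parameter(c, f"{path}/parameterList")
            for c in self.children(lst, "parameter")
        ]

    # -- experiments -------------------------------------------------------

    def parse_variable_parameter(self, el) -> m.VariableParameter:
        vp = m.VariableParameter(description=self.text(el, "description") or "")
        vp.unit = self.opt_cv(el, "unit")
        vvl = self.child(el, "variableValueList")
        if vvl is not None:
            for c in self.children(vvl, "variableValue"):
                vv = m.VariableValue(
                    id=self.int_attr(c, "id", 0) or 0,
                    value=c.text or "",
                    order=self.int_attr(c, "order"),
                )
                self.register(vv)
                vp.values.append(vv)
        return vp

    def parse_experiment(self, el, path: str) -> m.Experiment:
        exp = m.Experiment(id=self.int_attr(el, "id", 0) or 0)
        names_el = self.child(el, "names")
        if names_el is not None:
            exp.names = self.parse_names(names_el)
        bibref_el = self.child(el, "bibref")
        if bibref_el is not None:
            exp.bibref = self.parse_bibref(bibref_el)
        xref_el = self.child(el, "xref")
        if xref_el is not None:
            exp.xref = self.parse_xref(xref_el)
        exp.host_organisms = self.parse_organism_list(el)
        exp.interaction_detection_method = self.opt_cv(el, "interactionDetectionMethod")
        exp.participant_identification_method = self.opt_cv(
            el, "participantIdentificationMethod")
        exp.feature_detection_method = self.opt_cv(el, "featureDetectionMethod")
        vpl = self.child(el, "variableParameterList")
        if vpl is not None:
            exp.variable_parameters = [
                self.parse_variable_parameter(c)
                for c in self.children(vpl, "variableParameter")
            ]
        exp.confidences = self.parse_confidences(el)
        exp.attributes = self.parse_attributes(self.child(el, "attributeList"))
        self.register(exp)
        return exp

    # -- interactors and features -----------------------------------------

    def parse_interactor(self, el) -> m.Interactor:
        # the extended form may inline the same interactor several times;
        # unify on id so shared molecules stay one object
        existing = self.ids.get(self.int_attr(el, "id", 0) or 0)
        if isinstance(existing, m.Interactor):
            return existing
        itor = m.Interactor(id=self.int_attr(el, "id", 0) or 0)
        names_el = self.child(el, "names")
        if names_el is not None:
            itor.names = self.parse_names(names_el)
        xref_el = self.child(el, "xref")
        if xref_el is not None:
            itor.xref = self.parse_xref(xref_el)
        itor.interactor_type = self.opt_cv(el, "interactorType")
        org_el = self.child(el, "organism")
        if org_el is not None:
            itor.organism = self.parse_organism(org_el)
        itor.sequence = self.text(el, "sequence")
        itor.attributes = self.parse_attributes(self.child(el, "attributeList"))
        self.register(itor)
        return itor

    def parse_position(self, el, name, interval_name) -> m.Position:
        c = self.child(el, name)
        if c is not None:
            return m.ExactPosition(int(c.get("position", "0")))
        c = self.child(el, interval_name)
        if c is not None:
            return m.IntervalPosition(
                int(c.get("begin", "0")), int(c.get("end", "0")))
        return m.UnstatedPosition()

    def parse_feature_range(self, el) -> m.FeatureRange:
        fr = m.FeatureRange(
            begin_status=self.opt_cv(el, "startStatus") or m.CvTerm(),
            begin=self.parse_position(el, "begin", "beginInterval"),
            end_status=self.opt_cv(el, "endStatus") or m.CvTerm(),
            end=self.parse_position(el, "end", "endInterval"),
        )
        link = self.text(el, "isLink")
        fr.is_link = (link or "").strip() == "true"
        rs = self.child(el, "resultingSequence")
        if rs is not None:
            xref_el = self.child(rs, "xref")
            fr.resulting_sequence = m.ResultingSequence(
                original=self.text(rs, "originalSequence"),
                new=self.text(rs, "newSequence"),
                xref=self.parse_xref(xref_el) if xref_el is not None else None,
            )
        return fr

    def parse_feature(self, el, path: str) -> m.Feature:
        f = m.Feature(id=self.int_attr(el, "id", 0) or 0)
        names_el = self.child(el, "names")
        if names_el is not None:
            f.names = self.parse_names(names_el)
        xref_el = self.child(el, "xref")
        if xref_el is not None:
            f.xref = self.parse_xref(xref_el)
        f.feature_type = self.opt_cv(el, "featureType")
        f.feature_role = self.opt_cv(el, "featureRole")
        f.detection_methods = [
            self.parse_cv(c) for c in self.children(el, "featureDetectionMethod")
        ]
        frl = self.child(el, "featureRangeList")
        if frl is not None:
            f.ranges = [
                self.parse_feature_range(c)
                for c in self.children(frl, "featureRange")
            ]
        f.parameters = self.parse_parameters(el, path)
        f.attributes = self.parse_attributes(self.child(el, "attributeList"))
        self.register(f)
        return f

    def parse_features(self, el, path: str) -> list[m.Feature]:
        lst = self.child(el, "featureList")
        if lst is None:
            return []
        return [
            self.parse_feature(c, f"{path}/featureList")
            for c in self.children(lst, "feature")
        ]

    # -- participants ------------------------------------------------------

    def parse_candidate_set(self, el, path: str) -> m.CandidateSet:
        cs = m.CandidateSet(
            set_type=self.opt_cv(el, "moleculeSetType") or m.CvTerm())
        for c in self.children(el, "interactorCandidate"):
            cand = m.Candidate(id=self.int_attr(c, "id", 0) or 0)
            inline = self.child(c, "interactor")
            ref = self.child(c, "interactorRef")
            if inline is not None:
                cand.interactor = self.parse_interactor(inline)
            elif ref is not None:
                cand.interactor = self.resolve(
                    ref, f"{path}/interactorCandidate", "interactor", m.Interactor)
            cand.features = self.parse_features(c, f"{path}/interactorCandidate")
            self.register(cand)
            cs.candidates.append(cand)
        return cs

    def parse_participant(self, el, path: str) -> m.Participant:
        p = m.Participant(id=self.int_attr(el, "id", 0) or 0)
        self.register(p)
        names_el = self.child(el, "names")
        if names_el is not None:
            p.names = self.parse_names(names_el)
        xref_el = self.child(el, "xref")
        if xref_el is not None:
            p.xref = self.parse_xref(xref_el)
        inline = self.child(el, "interactor")
        iref = self.child(el, "interactorRef")
        nref = self.child(el, "interactionRef")
        cands = self.child(el, "interactorCandidateList")
        if inline is not None:
            p.entity = self.parse_interactor(inline)
        elif iref is not None:
            p.entity = self.resolve(iref, path, "interactor", m.Interactor)
        elif nref is not None:
            target = self.resolve(
                nref, path, "interaction",
                (m.InteractionEvidence, m.AbstractInteraction))
            if target is not None:
                p.entity = m.InteractionRef(target=target)
        elif cands is not None:
            p.entity = self.parse_candidate_set(
                cands, f"{path}/interactorCandidateList")
        piml = self.child(el, "participantIdentificationMethodList")
        if piml is not None:
            p.identification_methods = [
                self.parse_cv(c)
                for c in self.children(piml, "participantIdentificationMethod")
            ]
        p.biological_role = self.opt_cv(el, "biologicalRole")
        erl = self.child(el, "experimentalRoleList")
        if erl is not None:
            p.experimental_roles = [
                self.parse_cv(c) for c in self.children(erl, "experimentalRole")
            ]
        epl = self.child(el, "experimentalPreparationList")
        if epl is not None:
            p.experimental_preparations = [
                self.parse_cv(c)
                for c in self.children(epl, "experimentalPreparation")
            ]
        p.features = self.parse_features(el, path)
        p.host_organisms = self.parse_organism_list(el)
        p.confidences = self.parse_confidences(el)
        p.parameters = self.parse_parameters(el, path)
        st = self.child(el, "stoichiometry")
        str_el = self.child(el, "stoichiometryRange")
        if st is not None:
            p.stoichiometry = m.MeanStoichiometry(
                self.dec_attr(st, "value") or Decimal(0))
        elif str_el is not None:
            p.stoichiometry = m.StoichiometryRange(
                self.dec_attr(str_el, "minValue") or Decimal(0),
                self.dec_attr(str_el, "maxValue") or Decimal(0),
            )
        p.attributes = self.parse_attributes(self.child(el, "attributeList"))
        return p

    # -- interactions ------------------------------------------------------

    def fill_interaction(self, el, inter: m.InteractionEvidence, path: str,
                         entry: m.Entry) -> None:
        names_el = self.child(el, "names")
        if names_el is not None:
            inter.names = self.parse_names(names_el)
        xref_el = self.child(el, "xref")
        if xref_el is not None:
            inter.xref = self.parse_xref(xref_el)
        exl = self.child(el, "experimentList")
        if exl is not None:
            for c in exl:
                if not isinstance(c.tag, str):
                    continue
                tag = _local(c)
                if tag == "experimentRef":
                    exp = self.resolve(c, path, "experiment", m.Experiment)
                    if exp is not None:
                        inter.experiments.append(exp)
                elif tag == "experimentDescription":
                    exp_id = self.int_attr(c, "id", 0) or 0
                    existing = self.ids.get(exp_id)
                    if isinstance(existing, m.Experiment):
                        inter.experiments.append(existing)
                    else:
                        inter.experiments.append(
                            self.parse_experiment(c, f"{path}/experimentList"))
        pl = self.child(el, "participantList")
        if pl is not None:
            inter.participants = [
                self.parse_participant(c, f"{path}/participant")
                for c in self.children(pl, "participant")
            ]
        iil = self.child(el, "inferredInteractionList")
        if iil is not None:
            for c in self.children(iil, "inferredInteraction"):
                ii = m.InferredInteraction()
                for ref in c:
                    if not isinstance(ref.tag, str):
                        continue
                    tag = _local(ref)
                    if tag == "participantRef":
                        obj = self.resolve(ref, path, "participant", m.Participant)
                    elif tag == "participantFeatureRef":
                        obj = self.resolve(ref, path, "feature", m.Feature)
                    else:
                        continue
                    if obj is not None:
                        ii.points.append(obj)
                inter.inferred_interactions.append(ii)
        inter.interaction_types = [
            self.parse_cv(c) for c in self.children(el, "interactionType")
        ]
        inter.intra_molecular = (self.text(el, "intraMolecular") or "").strip() == "true"
        inter.negative = (self.text(el, "negative") or "").strip() == "true"
        evvl = self.child(el, "experimentalVariableValueList")
        if evvl is not None:
            for group in self.children(evvl, "experimentalVariableValues"):
                cset: list[m.VariableValue] = []
                for ref in self.children(group, "variableValueRef"):
                    vv = self.resolve(ref, path, "variable value", m.VariableValue)
                    if vv is not None:
                        cset.append(vv)
                inter.condition_sets.append(cset)
        inter.confidences = self.parse_confidences(el)
        inter.parameters = self.parse_parameters(el, path)
        inter.attributes = self.parse_attributes(self.child(el, "attributeList"))

    def parse_cooperativity_evidence(self, el) -> m.CooperativityEvidence:
        ev = m.CooperativityEvidence()
        bibref_el = self.child(el, "bibref")
        if bibref_el is not None:
            ev.bibref = self.parse_bibref(bibref_el)
        eml = self.child(el, "evidenceMethodList")
        if eml is not None:
            ev.methods = [
                self.parse_cv(c) for c in self.children(eml, "evidenceMethod")
            ]
        return ev

    def fill_effect_common(self, el, effect, path: str) -> None:
        cel = self.child(el, "cooperativityEvidenceList")
        if cel is not None:
            effect.evidence = [
                self.parse_cooperativity_evidence(c)
                for c in self.children(cel, "cooperativityEvidenceDescription")
            ]
        ail = self.child(el, "affectedInteractionList")
        if ail is not None:
            for ref in self.children(ail, "affectedInteractionRef"):
                target = self.resolve(
                    ref, path, "interaction",
                    (m.InteractionEvidence, m.AbstractInteraction))
                if target is not None:
                    effect.affected.append(target)
        outcome = self.opt_cv(el, "cooperativeEffectOutcome")
        if outcome is not None:
            effect.outcome = outcome
        effect.response = self.opt_cv(el, "cooperativeEffectResponse")

    def fill_abstract(self, el, inter: m.AbstractInteraction, path: str) -> None:
        names_el = self.child(el, "names")
        if names_el is not None:
            inter.names = self.parse_names(names_el)
        xref_el = self.child(el, "xref")
        if xref_el is not None:
            inter.xref = self.parse_xref(xref_el)
        inter.interactor_type = self.opt_cv(el, "interactorType")
        inter.interaction_type = self.opt_cv(el, "interactionType")
        org_el = self.child(el, "organism")
        if org_el is not None:
            inter.organism = self.parse_organism(org_el)
        pl = self.child(el, "participantList")
        if pl is not None:
            inter.participants = [
                self.parse_participant(c, f"{path}/participant")
                for c in self.children(pl, "participant")
            ]
        # experiment references are invalid here but representable, so that
        # the validator can flag them
        exl = self.child(el, "experimentList")
        if exl is not None:
            for c in exl:
                if not isinstance(c.tag, str):
                    continue
                if _local(c) == "experimentRef":
                    exp = self.resolve(c, path, "experiment", m.Experiment)
                    if exp is not None:
                        inter.experiments.append(exp)
                elif _local(c) == "experimentDescription":
                    inter.experiments.append(
                        self.parse_experiment(c, f"{path}/experimentList"))
        bfl = self.child(el, "bindingFeaturesList")
        if bfl is not None:
            for group in self.children(bfl, "bindingFeatures"):
                feats: list[m.Feature] = []
                for ref in self.children(group, "participantFeatureRef"):
                    feat = self.resolve(ref, path, "feature", m.Feature)
                    if feat is not None:
                        feats.append(feat)
                inter.binding_features.append(feats)
        cel = self.child(el, "cooperativeEffectList")
        if cel is not None:
            for c in cel:
                if not isinstance(c.tag, str):
                    continue
                tag = _local(c)
                if tag == "preassembly":
                    effect = m.Preassembly()
                    self.fill_effect_common(c, effect, path)
                    inter.cooperative_effects.append(effect)
                elif tag == "allostery":
                    effect = m.Allostery()
                    self.fill_effect_common(c, effect, path)
                    mol = self.child(c, "allostericMoleculeRef")
                    if mol is not None:
                        effect.allosteric_molecule = self.resolve(
                            mol, path, "participant", m.Participant)
                    eref = self.child(c, "allostericEffectorRef")
                    mref = self.child(c, "allostericModificationRef")
                    if eref is not None:
                        target = self.resolve(eref, path, "participant", m.Participant)
                        if target is not None:
                            effect.effector = m.MoleculeEffector(target)
                    elif mref is not None:
                        target = self.resolve(mref, path, "feature", m.Feature)
                        if target is not None:
                            effect.effector = m.FeatureModificationEffector(target)
                    effect.allostery_type = self.opt_cv(c, "allosteryType")
                    effect.allosteric_mechanism = self.opt_cv(c, "allostericMechanism")
                    inter.cooperative_effects.append(effect)
        inter.evidence_type = self.opt_cv(el, "evidenceType")
        inter.attributes = self.parse_attributes(self.child(el, "attributeList"))

    # -- entry / document --------------------------------------------------

    def parse_entry(self, el, index: int) -> m.Entry:
        path = f"/entrySet/entry[{index}]"
        entry = m.Entry()
        self.ids = {}
        src = self.child(el, "source")
        if src is not None:
            names_el = self.child(src, "names")
            bibref_el = self.child(src, "bibref")
            xref_el = self.child(src, "xref")
            entry.source = m.Source(
                names=self.parse_names(names_el) if names_el is not None else None,
                bibref=self.parse_bibref(bibref_el) if bibref_el is not None else None,
                xref=self.parse_xref(xref_el) if xref_el is not None else None,
                release_date=src.get("releaseDate"),
                attributes=self.parse_attributes(self.child(src, "attributeList")),
            )
        avl = self.child(el, "availabilityList")
        if avl is not None:
            for c in self.children(avl, "availability"):
                av = m.Availability(
                    id=self.int_attr(c, "id", 0) or 0, value=c.text or "")
                self.register(av)
                entry.availabilities.append(av)
        declared_exps: list[m.Experiment] = []
        exl = self.child(el, "experimentList")
        if exl is not None:
            declared_exps = [
                self.parse_experiment(c, f"{path}/experimentList")
                for c in self.children(exl, "experimentDescription")
            ]
        declared_itors: list[m.Interactor] = []
        itl = self.child(el, "interactorList")
        if itl is not None:
            declared_itors = [
                self.parse_interactor(c) for c in self.children(itl, "interactor")
            ]
        inl = self.child(el, "interactionList")
        shells: list[tuple[object, m.Interaction]] = []
        if inl is not None:
            for i, c in enumerate(inl):
                if not isinstance(c.tag, str):
                    continue
                tag = _local(c)
                if tag == "interaction":
                    inter: m.Interaction = m.InteractionEvidence(
                        id=self.int_attr(c, "id", 0) or 0)
                elif tag == "abstractInteraction":
                    inter = m.AbstractInteraction(
                        id=self.int_attr(c, "id", 0) or 0)
                else:
                    self.finding(
                        "UNKNOWN_ELEMENT", INFO,
                        f"{path}/interactionList", f"skipped element <{tag}>")
                    continue
                self.register(inter)
                shells.append((c, inter))
                entry.interactions.append(inter)
        for i, (c, inter) in enumerate(shells):
            ipath = f"{path}/interactionList/*[{i + 1}]"
            if isinstance(inter, m.InteractionEvidence):
                self.fill_interaction(c, inter, ipath, entry)
            else:
                self.fill_abstract(c, inter, ipath)
        entry.attributes = self.parse_attributes(self.child(el, "attributeList"))
        # pools in canonical order: first-use, then declared-but-unreferenced
        used = m.entry_experiments_in_use(
            entry)
        used_ids = {id(e) for e in used}
        entry.experiments = used + [e for e in declared_exps if id(e) not in used_ids]
        used_i = m.entry_interactors_in_use(entry)
        used_i_ids = {id(i) for i in used_i}
        entry.interactors = used_i + [
            i for i in declared_itors if id(i) not in used_i_ids]
        return entry


def read_mif(source, strict: bool = False) -> ReadResult:
    """Parse a MIF 2.5/3.0 stream into a :class:`~psimif.model.Document`.

    In strict mode a dangling id reference is fatal (no document returned);
    otherwise it is reported as a warning and the reference dropped.
    """
    try:
        data = _open_source(source)
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        return ReadResult(
            document=None,
            findings=[ValidationFinding(
                "PARSE_ERROR", ERROR, "/",
                f"malformed XML at line {exc.lineno}: {exc.msg}")],
        )
    ns = etree.QName(root).namespace
    if ns in _NS_TO_LEVEL:
        level = _NS_TO_LEVEL[ns]
    else:
        try:
            level = detect_level(data)
        except UnknownNamespaceError as exc:
            return ReadResult(
                document=None,
                findings=[ValidationFinding(
                    "UNKNOWN_NAMESPACE", ERROR, "/", str(exc))],
            )
    reader = _Reader(strict=strict)
    entries = []
    for i, el in enumerate(root):
        if isinstance(el.tag, str) and _local(el) == "entry":
            entries.append(reader.parse_entry(el, i + 1))
    doc = m.Document(entries=entries, level=level)
    if reader.fatal:
        return ReadResult(document=None, findings=reader.findings,
                          level_detected=level)
    return ReadResult(document=doc, findings=reader.findings,
                      level_detected=level)


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def _collect_30_only(doc: m.Document) -> list[str]:
    """Constructs a 2.5 writer cannot express (used for the refusal check)."""
    out: list[str] = []
    for ei, entry in enumerate(doc.entries):
        where = f"entry[{ei + 1}]"
        for exp in entry.experiments:
            if exp.variable_parameters:
                out.append(f"{where}: variableParameterList on experiment")
            if exp.bibref and exp.bibref.xref and exp.bibref.attributes:
                out.append(f"{where}: bibref with both xref and attributes")
        for inter in entry.interactions:
            if isinstance(inter, m.AbstractInteraction):
                out.append(f"{where}: abstractInteraction")
                continue
            if inter.condition_sets:
                out.append(f"{where}: experimental variable values on interaction")
            for exp in inter.experiments:
                if exp.bibref and exp.bibref.xref and exp.bibref.attributes:
                    out.append(f"{where}: bibref with both xref and attributes")
            for p in inter.participants:
                if isinstance(p.entity, m.CandidateSet):
                    out.append(f"{where}: interactorCandidateList")
                if p.stoichiometry is not None:
                    out.append(f"{where}: stoichiometry element")
                for f in m.iter_participant_features(p):
                    if f.feature_role is not None:
                        out.append(f"{where}: featureRole")
                    if len(f.detection_methods) > 1:
                        out.append(f"{where}: repeated featureDetectionMethod")
                    if f.parameters:
                        out.append(f"{where}: feature parameterList")
                    for r in f.ranges:
                        if r.resulting_sequence is not None:
                            out.append(f"{where}: resultingSequence")
                        for pos in (r.begin, r.end):
                            if isinstance(pos, m.ExactPosition) and pos.value < 0:
                                out.append(f"{where}: negative feature position")
                            if isinstance(pos, m.IntervalPosition) and (
                                pos.start < 0 or pos.end < 0
                            ):
                                out.append(f"{where}: negative feature position")
    return out


class _Writer:
    def __init__(self, level: str, form: str):
        self.level = level
        self.form = form
        self.ns = NS_30 if level == m.LEVEL_30 else NS_25

    def el(self, parent, tag, text=None, **attrs):
        e = etree.SubElement(parent, f"{{{self.ns}}}{tag}")
        for k, v in attrs.items():
            if v is not None:
                e.set(k, str(v))
        if text is not None:
            e.text = str(text)
        return e

    # -- leaves ------------------------------------------------------------

    def write_names(self, parent, names: Optional[m.Names]):
        if names is None:
            return
        e = self.el(parent, "names")
        if names.short_label is not None:
            self.el(e, "shortLabel", names.short_label)
        if names.full_name is not None:
            self.el(e, "fullName", names.full_name)
        for alias in names.aliases:
            self.el(e, "alias", alias)

    def write_dbref(self, parent, name, ref: m.DbReference):
        self.el(parent, name, db=ref.db, dbAc=ref.db_ac, id=ref.id,
                version=ref.version, refType=ref.ref_type,
                refTypeAc=ref.ref_type_ac)

    def write_xref(self, parent, xref: Optional[m.Xref]):
        if xref is None:
            return
        e = self.el(parent, "xref")
        self.write_dbref(e, "primaryRef", xref.primary)
        for s in xref.secondary:
            self.write_dbref(e, "secondaryRef", s)

    def write_attributes(self, parent, attributes: list[m.Attribute]):
        if not attributes:
            return
        e = self.el(parent, "attributeList")
        for a in attributes:
            self.el(e, "attribute", a.value, name=a.name, nameAc=a.name_ac)

    def write_bibref(self, parent, bibref: Optional[m.BibRef], name="bibref"):
        if bibref is None:
            return
        e = self.el(parent, name)
        self.write_xref(e, bibref.xref)
        self.write_attributes(e, bibref.attributes)

    def write_cv(self, parent, name, cv: Optional[m.CvTerm]):
        if cv is None:
            return
        e = self.el(parent, name)
        if cv.short_label is not None or cv.full_name is not None:
            self.write_names(e, m.Names(cv.short_label, cv.full_name))
        if cv.mi_accession is not None:
            x = self.el(e, "xref")
            self.write_dbref(x, "primaryRef", m.DbReference(
                db="psi-mi", id=cv.mi_accession, ref_type="identity"))
            if cv.xref is not None:
                self.write_dbref(x, "secondaryRef", cv.xref.primary)
                for s in cv.xref.secondary:
                    self.write_dbref(x, "secondaryRef", s)
        elif cv.xref is not None:
            self.write_xref(e, cv.xref)
        return e

    def write_organism(self, parent, org: Optional[m.Organism],
                       name="hostOrganism"):
        if org is None:
            return
        e = self.el(parent, name, ncbiTaxId=org.ncbi_tax_id)
        self.write_names(e, org.names)
        self.write_cv(e, "cellType", org.cell_type)
        self.write_cv(e, "compartment", org.compartment)
        self.write_cv(e, "tissue", org.tissue)

    def write_organism_list(self, parent, organisms: list[m.Organism]):
        if not organisms:
            return
        e = self.el(parent, "hostOrganismList")
        for org in organisms:
            self.write_organism(e, org)

    def write_confidences(self, parent, confidences: list[m.Confidence]):
        if not confidences:
            return
        e = self.el(parent, "confidenceList")
        for c in confidences:
            ce = self.el(e, "confidence")
            self.write_cv(ce, "unit", c.unit)
            self.el(ce, "value", c.value)

    def write_parameters(self, parent, parameters: list[m.Parameter]):
        if not parameters:
            return
        e = self.el(parent, "parameterList")
        for p in parameters:
            pe = self.el(e, "parameter", term=p.term, termAc=p.term_ac,
                         unit=p.unit, unitAc=p.unit_ac, base=p.base,
                         exponent=p.exponent, factor=p.factor,
                         uncertainty=p.uncertainty)
            if p.experiment is not None:
                self.el(pe, "experimentRef", p.experiment.id)

    # -- experiments -------------------------------------------------------

    def write_experiment(self, parent, exp: m.Experiment):
        e = self.el(parent, "experimentDescription", id=exp.id)
        self.write_names(e, exp.names)
        self.write_bibref(e, exp.bibref)
        self.write_xref(e, exp.xref)
        self.write_organism_list(e, exp.host_organisms)
        self.write_cv(e, "interactionDetectionMethod",
                      exp.interaction_detection_method)
        self.write_cv(e, "participantIdentificationMethod",
                      exp.participant_identification_method)
        self.write_cv(e, "featureDetectionMethod", exp.feature_detection_method)
        if exp.variable_parameters:
            vpl = self.el(e, "variableParameterList")
            for vp in exp.variable_parameters:
                vpe = self.el(vpl, "variableParameter")
                self.el(vpe, "description", vp.description)
                self.write_cv(vpe, "unit", vp.unit)
                vvl = self.el(vpe, "variableValueList")
                for vv in vp.values:
                    self.el(vvl, "variableValue", vv.value, id=vv.id,
                            order=vv.order)
        self.write_confidences(e, exp.confidences)
        self.write_attributes(e, exp.attributes)

    # -- interactors / features -------------------------------------------

    def write_interactor(self, parent, itor: m.Interactor):
        e = self.el(parent, "interactor", id=itor.id)
        self.write_names(e, itor.names)
        self.write_xref(e, itor.xref)
        self.write_cv(e, "interactorType", itor.interactor_type)
        self.write_organism(e, itor.organism, name="organism")
        if itor.sequence is not None:
            self.el(e, "sequence", itor.sequence)
        self.write_attributes(e, itor.attributes)

    def write_position(self, parent, pos: m.Position, name, interval_name):
        if isinstance(pos, m.ExactPosition):
            self.el(parent, name, position=pos.value)
        elif isinstance(pos, m.IntervalPosition):
            self.el(parent, interval_name, begin=pos.start, end=pos.end)

    def write_feature(self, parent, f: m.Feature):
        e = self.el(parent, "feature", id=f.id)
        self.write_names(e, f.names)
        self.write_xref(e, f.xref)
        self.write_cv(e, "featureType", f.feature_type)
        self.write_cv(e, "featureRole", f.feature_role)
        for dm in f.detection_methods:
            self.write_cv(e, "featureDetectionMethod", dm)
        frl = self.el(e, "featureRangeList")
        for r in f.ranges:
            re_ = self.el(frl, "featureRange")
            self.write_cv(re_, "startStatus", r.begin_status)
            self.write_position(re_, r.begin, "begin", "beginInterval")
            self.write_cv(re_, "endStatus", r.end_status)
            self.write_position(re_, r.end, "end", "endInterval")
            if r.resulting_sequence is not None:
                rs = self.el(re_, "resultingSequence")
                if r.resulting_sequence.original is not None:
                    self.el(rs, "originalSequence", r.resulting_sequence.original)
                if r.resulting_sequence.new is not None:
                    self.el(rs, "newSequence", r.resulting_sequence.new)
                self.write_xref(rs, r.resulting_sequence.xref)
            if r.is_link:
                self.el(re_, "isLink", "true")
        self.write_parameters(e, f.parameters)
        self.write_attributes(e, f.attributes)

    def write_features(self, parent, features: list[m.Feature]):
        if not features:
            return
        e = self.el(parent, "featureList")
        for f in features:
            self.write_feature(e, f)

    # -- participants ------------------------------------------------------

    def write_participant(self, parent, p: m.Participant):
        e = self.el(parent, "participant", id=p.id)
        self.write_names(e, p.names)
        self.write_xref(e, p.xref)
        if isinstance(p.entity, m.Interactor):
            if self.form == EXTENDED:
                self.write_interactor(e, p.entity)
            else:
                self.el(e, "interactorRef", p.entity.id)
        elif isinstance(p.entity, m.InteractionRef):
            self.el(e, "interactionRef", p.entity.target.id)
        elif isinstance(p.entity, m.CandidateSet):
            cse = self.el(e, "interactorCandidateList")
            self.write_cv(cse, "moleculeSetType", p.entity.set_type)
            for cand in p.entity.candidates:
                ce = self.el(cse, "interactorCandidate", id=cand.id)
                if cand.interactor is not None:
                    if self.form == EXTENDED:
                        self.write_interactor(ce, cand.interactor)
                    else:
                        self.el(ce, "interactorRef", cand.interactor.id)
                self.write_features(ce, cand.features)
        if p.identification_methods:
            piml = self.el(e, "participantIdentificationMethodList")
            for cv in p.identification_methods:
                self.write_cv(piml, "participantIdentificationMethod", cv)
        self.write_cv(e, "biologicalRole", p.biological_role)
        if p.experimental_roles:
            erl = self.el(e, "experimentalRoleList")
            for cv in p.experimental_roles:
                self.write_cv(erl, "experimentalRole", cv)
        if p.experimental_preparations:
            epl = self.el(e, "experimentalPreparationList")
            for cv in p.experimental_preparations:
                self.write_cv(epl, "experimentalPreparation", cv)
        self.write_features(e, p.features)
        self.write_organism_list(e, p.host_organisms)
        self.write_confidences(e, p.confidences)
        self.write_parameters(e, p.parameters)
        if isinstance(p.stoichiometry, m.MeanStoichiometry):
            self.el(e, "stoichiometry", value=p.stoichiometry.value)
        elif isinstance(p.stoichiometry, m.StoichiometryRange):
            self.el(e, "stoichiometryRange",
                    minValue=p.stoichiometry.min_value,
                    maxValue=p.stoichiometry.max_value)
        self.write_attributes(e, p.attributes)

    # -- interactions ------------------------------------------------------

    def write_interaction(self, parent, inter: m.InteractionEvidence,
                          written_exps: set[int]):
        e = self.el(parent, "interaction", id=inter.id)
        self.write_names(e, inter.names)
        self.write_xref(e, inter.xref)
        exl = self.el(e, "experimentList")
        for exp in inter.experiments:
            if self.form == EXTENDED:
                self.write_experiment(exl, exp)
            else:
                self.el(exl, "experimentRef", exp.id)
        pl = self.el(e, "participantList")
        for p in inter.participants:
            self.write_participant(pl, p)
        if inter.inferred_interactions:
            iil = self.el(e, "inferredInteractionList")
            for ii in inter.inferred_interactions:
                iie = self.el(iil, "inferredInteraction")
                for point in ii.points:
                    if isinstance(point, m.Participant):
                        self.el(iie, "participantRef", point.id)
                    else:
                        self.el(iie, "participantFeatureRef", point.id)
        for cv in inter.interaction_types:
            self.write_cv(e, "interactionType", cv)
        if inter.intra_molecular:
            self.el(e, "intraMolecular", "true")
        if inter.negative:
            self.el(e, "negative", "true")
        if inter.condition_sets:
            evvl = self.el(e, "experimentalVariableValueList")
            for cset in inter.condition_sets:
                group = self.el(evvl, "experimentalVariableValues")
                for vv in cset:
                    self.el(group, "variableValueRef", vv.id)
        self.write_confidences(e, inter.confidences)
        self.write_parameters(e, inter.parameters)
        self.write_attributes(e, inter.attributes)

    def write_abstract(self, parent, inter: m.AbstractInteraction):
        e = self.el(parent, "abstractInteraction", id=inter.id)
        self.write_names(e, inter.names)
        self.write_xref(e, inter.xref)
        self.write_cv(e, "interactorType", inter.interactor_type)
        self.write_cv(e, "interactionType", inter.interaction_type)
        self.write_organism(e, inter.organism, name="organism")
        if inter.participants:
            pl = self.el(e, "participantList")
            for p in inter.participants:
                self.write_participant(pl, p)
        if inter.binding_features:
            bfl = self.el(e, "bindingFeaturesList")
            for group in inter.binding_features:
                ge = self.el(bfl, "bindingFeatures")
                for feat in group:
                    self.el(ge, "participantFeatureRef", feat.id)
        if inter.cooperative_effects:
            cel = self.el(e, "cooperativeEffectList")
            for effect in inter.cooperative_effects:
                self.write_effect(cel, effect)
        self.write_cv(e, "evidenceType", inter.evidence_type)
        self.write_attributes(e, inter.attributes)

    def write_effect(self, parent, effect: m.CooperativeEffect):
        name = "allostery" if isinstance(effect, m.Allostery) else "preassembly"
        e = self.el(parent, name)
        if effect.evidence:
            cel = self.el(e, "cooperativityEvidenceList")
            for ev in effect.evidence:
                eve = self.el(cel, "cooperativityEvidenceDescription")
                self.write_bibref(eve, ev.bibref)
                if ev.methods:
                    eml = self.el(eve, "evidenceMethodList")
                    for cv in ev.methods:
                        self.write_cv(eml, "evidenceMethod", cv)
        ail = self.el(e, "affectedInteractionList")
        for target in effect.affected:
            self.el(ail, "affectedInteractionRef", target.id)
        self.write_cv(e, "cooperativeEffectOutcome", effect.outcome)
        self.write_cv(e, "cooperativeEffectResponse", effect.response)
        if isinstance(effect, m.Allostery):
            if effect.allosteric_molecule is not None:
                self.el(e, "allostericMoleculeRef", effect.allosteric_molecule.id)
            if isinstance(effect.effector, m.MoleculeEffector):
                self.el(e, "allostericEffectorRef", effect.effector.participant.id)
            elif isinstance(effect.effector, m.FeatureModificationEffector):
                self.el(e, "allostericModificationRef", effect.effector.feature.id)
            self.write_cv(e, "allosteryType", effect.allostery_type)
            self.write_cv(e, "allostericMechanism", effect.allosteric_mechanism)

    # -- entry / document --------------------------------------------------

    def write_entry(self, parent, entry: m.Entry):
        e = self.el(parent, "entry")
        if entry.source is not None:
            src = self.el(e, "source", releaseDate=entry.source.release_date)
            self.write_names(src, entry.source.names)
            self.write_bibref(src, entry.source.bibref)
            self.write_xref(src, entry.source.xref)
            self.write_attributes(src, entry.source.attributes)
        if entry.availabilities:
            avl = self.el(e, "availabilityList")
            for av in entry.availabilities:
                self.el(avl, "availability", av.value, id=av.id)
        if self.form == COMPACT:
            pool_exps = entry.experiments
            pool_itors = entry.interactors
        else:
            # extended form inlines used objects; entry-level lists keep only
            # the declared-but-unreferenced ones so no content is lost
            used = {id(x) for x in m.entry_experiments_in_use(entry)}
            pool_exps = [x for x in entry.experiments if id(x) not in used]
            used_i = {id(x) for x in m.entry_interactors_in_use(entry)}
            pool_itors = [x for x in entry.interactors if id(x) not in used_i]
        if pool_exps:
            exl = self.el(e, "experimentList")
            for exp in pool_exps:
                self.write_experiment(exl, exp)
        if pool_itors:
            itl = self.el(e, "interactorList")
            for itor in pool_itors:
                self.write_interactor(itl, itor)
        inl = self.el(e, "interactionList")
        written_exps: set[int] = set()
        for inter in entry.interactions:
            if isinstance(inter, m.AbstractInteraction):
                self.write_abstract(inl, inter)
            else:
                self.write_interaction(inl, inter, written_exps)
        self.write_attributes(e, entry.attributes)


def write_mif(doc: m.Document, form: str = COMPACT,
              dest=None, normalize: bool = True) -> Optional[bytes]:
    """Serialize a document; returns UTF-8 bytes unless ``dest`` (path or
    binary file object) is given.

    The document is normalized before writing so output bytes are a pure
    function of document content.  A level-2.5 document still containing
    3.0-only constructs is refused with :class:`Level30ContentError`.
    """
    if form not in (COMPACT, EXTENDED):
        raise ValueError(f"unknown form {form!r}")
    if doc.level == m.LEVEL_25:
        problems = _collect_30_only(doc)
        if problems:
            raise Level30ContentError(problems)
    if normalize:
        doc = m.normalize(doc)
    writer = _Writer(doc.level, form)
    nsmap = {None: writer.ns}
    root = etree.Element(f"{{{writer.ns}}}entrySet", nsmap=nsmap)
    if doc.level == m.LEVEL_30:
        root.set("level", "3")
        root.set("version", "0")
        root.set("minorVersion", "0")
    else:
        root.set("level", "2")
        root.set("version", "5")
        root.set("minorVersion", "4")
    for entry in doc.entries:
        writer.write_entry(root, entry)
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if dest is None:
        return data
    if isinstance(dest, (str, Path)):
        Path(dest).write_bytes(data)
    else:
        dest.write(data)
    return None


# ---------------------------------------------------------------------------
# structural schema validation
# ---------------------------------------------------------------------------

_SCHEMA_CACHE: dict[str, etree.XMLSchema] = {}


def _load_schema(level: str) -> etree.XMLSchema:
    if level not in _SCHEMA_CACHE:
        from importlib.resources import files

        name = ("mif300_structural.xsd" if level == m.LEVEL_30
                else "mif254_structural.xsd")
        data = (files("psimif") / "schemas" / name).read_bytes()
        _SCHEMA_CACHE[level] = etree.XMLSchema(etree.fromstring(data))
    return _SCHEMA_CACHE[level]


def xsd_validate(data: bytes, level: Optional[str] = None) -> list[str]:
    """Validate serialized MIF bytes against the bundled structural schema
    for the given (or sniffed) level; returns a list of violation messages,
    empty when the document conforms."""
    data = _open_source(data)
    if level is None:
        level = detect_level(data)
    schema = _load_schema(level)
    tree = etree.fromstring(data)
    if schema.validate(tree):
        return []
    return [str(err) for err in schema.error_log]
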
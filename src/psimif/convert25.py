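"""Lossy downgrade of level-3.0 documents to level 2.5, and the inverse
structural upgrade.

Every 3.0-only construct is rewritten using the annotation workarounds that
level-2.5 producers historically used — negative coordinates become
undetermined ranges, resulting sequences / feature roles / extra detection
methods become feature attributes, feature parameters move to the
interaction parameter list, dynamic-interaction conditions become
experiment/interaction attributes, abstract interactions become ordinary
interactions backed by a synthesized inferred-by-curator (MI:0364)
experiment, cooperative effects become interaction-level annotations,
candidate sets collapse to a single molecule-set interactor, stoichiometry
and split publication details become participant/experiment attributes.

Each rewritten construct is recorded once in a :class:`LossReport`.  The
annotations carry machine-parsable ``psimi3:`` payloads (JSON), so
``upgrade(..., promote=True)`` can restore the original 3.0 content; the
round trip is the identity up to :func:`~psimif.model.normalize`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

from . import _codec as codec
from . import model as m

CATEGORIES = (
    "NEGATIVE_POSITION",
    "RESULTING_SEQUENCE",
    "EXTRA_DETECTION_METHODS",
    "FEATURE_ROLE",
    "FEATURE_PARAMETERS",
    "VARIABLE_PARAMETERS",
    "ABSTRACT_INTERACTION",
    "COOPERATIVE_EFFECT",
    "CANDIDATE_SET",
    "STOICHIOMETRY_ELEMENT",
    "BIBREF_SPLIT",
)

PREFIX = "psimi3:"
A_ORIG_ID = PREFIX + "orig-id"
A_SYNTH = PREFIX + "synthesized"
A_RANGE = PREFIX + "range"
A_RESSEQ = PREFIX + "resulting-sequence"
A_DETECT = PREFIX + "feature-detection-method"
A_ROLE = PREFIX + "feature-role"
A_FPARAM = PREFIX + "feature-parameter"
A_VPARAM = PREFIX + "variable-parameter"
A_VVALUES = PREFIX + "variable-values"
A_ABSTRACT = PREFIX + "abstract-interaction"
A_EFFECT = PREFIX + "cooperative-effect"
A_CANDSET = PREFIX + "candidate-set"
A_STOICH = PREFIX + "stoichiometry"
A_BIBSPLIT = PREFIX + "bibref-split"

_UNDETERMINED = dict(short_label="undetermined", mi_accession="MI:0339")
_INFERRED_BY_CURATOR = dict(short_label="inferred by curator",
                            mi_accession="MI:0364")


@dataclass
class LossItem:
    category: str
    path: str
    detail: str


@dataclass
class LossReport:
    items: list[LossItem] = field(default_factory=list)

    def add(self, category: str, path: str, detail: str) -> None:
        assert category in CATEGORIES
        self.items.append(LossItem(category, path, detail))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for item in self.items:
            out[item.category] = out.get(item.category, 0) + 1
        return out

    @property
    def empty(self) -> bool:
        return not self.items

    def to_jsonable(self) -> dict:
        return {
            "counts": self.counts(),
            "items": [
                {"category": i.category, "path": i.path, "detail": i.detail}
                for i in self.items
            ],
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _get_payloads(obj, name: str) -> list:
    return [codec.loads(a.value) for a in obj.attributes
            if a.name == name and a.value]


def _pop_attrs(obj, name: str) -> list:
    payloads = _get_payloads(obj, name)
    obj.attributes = [a for a in obj.attributes if a.name != name]
    return payloads


def _add_payload(obj, name: str, payload) -> None:
    obj.attributes.append(m.Attribute(name=name, value=codec.dumps(payload)))


def _mark(obj) -> int:
    """Tag an object with its pre-downgrade id so annotation payloads can
    reference it across the conversion; returns that id."""
    if not any(a.name == A_ORIG_ID for a in obj.attributes):
        obj.attributes.append(m.Attribute(name=A_ORIG_ID, value=str(obj.id)))
    return obj.id


def _is_synth(obj) -> bool:
    return any(a.name == A_SYNTH for a in obj.attributes)


def _neg_or_zero(pos: m.Position) -> bool:
    if isinstance(pos, m.ExactPosition):
        return pos.value <= 0
    if isinstance(pos, m.IntervalPosition):
        return pos.start <= 0 or pos.end <= 0
    return False


def _strip_param(param: m.Parameter) -> m.Parameter:
    clone = copy.deepcopy(param)
    clone.experiment = None
    return clone


# ---------------------------------------------------------------------------
# downgrade
# ---------------------------------------------------------------------------

def downgrade(doc30: m.Document) -> tuple[m.Document, LossReport]:
    """Convert a 3.0 document to a valid 2.5 document plus a loss report
    with one item per rewritten construct.  Total on validator-clean input;
    a document using no 3.0-only construct converts with an empty report."""
    doc = m.normalize(doc30)
    report = LossReport()
    for ei, entry in enumerate(doc.entries):
        _downgrade_entry(entry, f"entry[{ei + 1}]", report)
    doc.level = m.LEVEL_25
    return doc, report


def _downgrade_entry(entry: m.Entry, where: str, report: LossReport) -> None:
    # 1. cooperative effects -> interaction annotations
    for j, inter in enumerate(entry.interactions):
        if not isinstance(inter, m.AbstractInteraction):
            continue
        path = f"{where}/interaction[{j + 1}]"
        for effect in inter.cooperative_effects:
            _add_payload(inter, A_EFFECT, _encode_effect(effect))
            report.add("COOPERATIVE_EFFECT", path,
                       f"{type(effect).__name__.lower()} effect on "
                       f"{len(effect.affected)} interaction(s)")
        inter.cooperative_effects = []

    # 2. abstract interactions -> evidence interactions with a synthesized
    #    inferred-by-curator experiment
    for j, inter in enumerate(entry.interactions):
        if isinstance(inter, m.AbstractInteraction):
            path = f"{where}/interaction[{j + 1}]"
            _abstract_to_evidence(inter, entry, report, path)

    # 3. per-interaction: observed variable-value combinations
    for j, inter in enumerate(entry.interactions):
        path = f"{where}/interaction[{j + 1}]"
        if inter.condition_sets:
            payload = {"sets": [[vv.id for vv in s] for s in inter.condition_sets]}
            _add_payload(inter, A_VVALUES, payload)
            report.add("VARIABLE_PARAMETERS", path,
                       f"{len(inter.condition_sets)} observed condition set(s)")
            inter.condition_sets = []

        # 4. per-participant: candidate sets and stoichiometry
        for k, p in enumerate(inter.participants):
            ppath = f"{path}/participant[{k + 1}]"
            if isinstance(p.entity, m.CandidateSet):
                _collapse_candidate_set(p, entry, report, ppath)
            if p.stoichiometry is not None:
                if isinstance(p.stoichiometry, m.MeanStoichiometry):
                    payload = {"kind": "mean",
                               "value": str(p.stoichiometry.value)}
                    detail = f"mean {p.stoichiometry.value}"
                else:
                    payload = {"kind": "range",
                               "min": str(p.stoichiometry.min_value),
                               "max": str(p.stoichiometry.max_value)}
                    detail = (f"range {p.stoichiometry.min_value}.."
                              f"{p.stoichiometry.max_value}")
                _add_payload(p, A_STOICH, payload)
                report.add("STOICHIOMETRY_ELEMENT", ppath, detail)
                p.stoichiometry = None

            # 5. per-feature rules
            for fi, f in enumerate(p.features):
                _downgrade_feature(f, inter, report, f"{ppath}/feature[{fi + 1}]")

    # 6. per-experiment: variable parameters and combined bibrefs
    for j, exp in enumerate(entry.experiments):
        path = f"{where}/experimentDescription[{j + 1}]"
        for vp in exp.variable_parameters:
            _add_payload(exp, A_VPARAM, {"vp": codec.to_jsonable(vp)})
            report.add("VARIABLE_PARAMETERS", path,
                       f"variable parameter {vp.description!r} with "
                       f"{len(vp.values)} value(s)")
        exp.variable_parameters = []
        _split_bibref(exp, report, path)
    if entry.source is not None:
        _split_bibref(entry.source, report, f"{where}/source")


def _split_bibref(owner, report: LossReport, path: str) -> None:
    bibref = owner.bibref
    if bibref is None or bibref.xref is None or not bibref.attributes:
        return
    _add_payload(owner, A_BIBSPLIT,
                 {"attrs": [codec.to_jsonable(a) for a in bibref.attributes]})
    owner.attributes.extend(bibref.attributes)
    report.add("BIBREF_SPLIT", f"{path}/bibref",
               f"{len(bibref.attributes)} publication attribute(s) moved "
               "out of bibref")
    bibref.attributes = []


def _encode_effect(effect: m.CooperativeEffect) -> dict:
    payload = {
        "kind": "allostery" if isinstance(effect, m.Allostery) else "preassembly",
        "evidence": [
            {"bibref": codec.to_jsonable(ev.bibref),
             "methods": [codec.to_jsonable(cv) for cv in ev.methods]}
            for ev in effect.evidence
        ],
        "affected": [_mark(t) for t in effect.affected],
        "outcome": codec.to_jsonable(effect.outcome),
        "response": codec.to_jsonable(effect.response),
    }
    if isinstance(effect, m.Allostery):
        if effect.allosteric_molecule is not None:
            payload["allosteric_molecule"] = _mark(effect.allosteric_molecule)
        if isinstance(effect.effector, m.MoleculeEffector):
            payload["effector"] = {"kind": "molecule",
                                   "ref": _mark(effect.effector.participant)}
        elif isinstance(effect.effector, m.FeatureModificationEffector):
            payload["effector"] = {"kind": "modification",
                                   "ref": _mark(effect.effector.feature)}
        payload["allostery_type"] = codec.to_jsonable(effect.allostery_type)
        payload["allosteric_mechanism"] = codec.to_jsonable(
            effect.allosteric_mechanism)
    return payload


def _abstract_to_evidence(inter: m.AbstractInteraction, entry: m.Entry,
                          report: LossReport, path: str) -> None:
    payload = {
        "interactor_type": codec.to_jsonable(inter.interactor_type),
        "evidence_type": codec.to_jsonable(inter.evidence_type),
        "organism": codec.to_jsonable(inter.organism),
        "binding_features": [
            [_mark(f) for f in group] for group in inter.binding_features
        ],
        "has_interaction_type": inter.interaction_type is not None,
    }
    _mark(inter)
    _add_payload(inter, A_ABSTRACT, payload)
    report.add("ABSTRACT_INTERACTION", path,
               "modelled interaction rewritten as an interaction with a "
               "synthesized inferred-by-curator experiment")

    synth = m.Experiment(
        names=m.Names(short_label="inferred"),
        bibref=(m.BibRef(xref=copy.deepcopy(inter.xref))
                if inter.xref is not None
                else m.BibRef(attributes=[
                    m.Attribute(name=A_SYNTH, value="bibref")])),
        interaction_detection_method=m.CvTerm(**_INFERRED_BY_CURATOR),
        attributes=[m.Attribute(name=A_SYNTH, value="experiment")],
    )
    entry.experiments.append(synth)

    interaction_type = inter.interaction_type
    d = inter.__dict__
    for name in ("interactor_type", "interaction_type", "organism",
                 "binding_features", "cooperative_effects", "evidence_type"):
        d.pop(name, None)
    # swap the instance class in place so every reference (participants of
    # other interactions, affected-interaction lists) stays valid
    inter.__class__ = m.InteractionEvidence
    inter.experiments = [synth]
    inter.inferred_interactions = []
    inter.interaction_types = (
        [interaction_type] if interaction_type is not None else [])
    inter.negative = False
    inter.intra_molecular = False
    inter.confidences = []
    inter.parameters = []
    inter.condition_sets = []


def _collapse_candidate_set(p: m.Participant, entry: m.Entry,
                            report: LossReport, path: str) -> None:
    cs = p.entity
    payload = {"set_type": codec.to_jsonable(cs.set_type), "candidates": []}
    member_refs: list[m.DbReference] = []
    member_labels: list[str] = []
    for cand in cs.candidates:
        entry_ref: Optional[int] = None
        if cand.interactor is not None:
            entry_ref = _mark(cand.interactor)
            if cand.interactor.xref is not None:
                member_refs.append(copy.deepcopy(cand.interactor.xref.primary))
            if cand.interactor.names and cand.interactor.names.short_label:
                member_labels.append(cand.interactor.names.short_label)
        payload["candidates"].append({
            "id": cand.id,
            "interactor": entry_ref,
            "features": [codec.to_jsonable(f) for f in cand.features],
        })
    _add_payload(p, A_CANDSET, payload)
    report.add("CANDIDATE_SET", path,
               f"{len(cs.candidates)} candidate(s) collapsed to one "
               "molecule-set interactor")

    label = "-".join(member_labels) if member_labels else "molecule set"
    synth = m.Interactor(
        names=m.Names(short_label=label),
        interactor_type=m.CvTerm(short_label="molecule set",
                                 mi_accession="MI:1304"),
        attributes=[m.Attribute(name=A_SYNTH, value="interactor")]
        + [m.Attribute(name="member", value=lb) for lb in member_labels],
    )
    if member_refs:
        synth.xref = m.Xref(primary=member_refs[0], secondary=member_refs[1:])
    entry.interactors.append(synth)
    p.entity = synth


def _downgrade_feature(f: m.Feature, inter: m.InteractionEvidence,
                       report: LossReport, path: str) -> None:
    if f.feature_role is not None:
        _add_payload(f, A_ROLE, {"cv": codec.to_jsonable(f.feature_role)})
        report.add("FEATURE_ROLE", path,
                   f"feature role {f.feature_role.short_label or f.feature_role.mi_accession}")
        f.feature_role = None
    if len(f.detection_methods) > 1:
        for k, dm in enumerate(f.detection_methods[1:], start=1):
            _add_payload(f, A_DETECT, {"index": k, "cv": codec.to_jsonable(dm)})
        report.add("EXTRA_DETECTION_METHODS", path,
                   f"{len(f.detection_methods) - 1} extra detection method(s) "
                   "kept as attributes; first method retained")
        f.detection_methods = f.detection_methods[:1]
    for param in f.parameters:
        payload = {"feature": _mark(f),
                   "param": codec.to_jsonable(_strip_param(param))}
        if param.experiment is not None:
            payload["experiment"] = _mark(param.experiment)
        _add_payload(inter, A_FPARAM, payload)
        inter.parameters.append(param)
        report.add("FEATURE_PARAMETERS", path,
                   f"parameter {param.term!r} moved to the interaction "
                   "parameter list")
    f.parameters = []
    for i, r in enumerate(f.ranges):
        if r.resulting_sequence is not None:
            rs = r.resulting_sequence
            _add_payload(f, A_RESSEQ, {
                "index": i,
                "rs": codec.to_jsonable(rs),
                "xref_was_none": f.xref is None,
            })
            if rs.xref is not None:
                if f.xref is None:
                    f.xref = copy.deepcopy(rs.xref)
                else:
                    f.xref.secondary.append(copy.deepcopy(rs.xref.primary))
                    f.xref.secondary.extend(copy.deepcopy(rs.xref.secondary))
            report.add("RESULTING_SEQUENCE", f"{path}/featureRange[{i + 1}]",
                       f"{rs.original or '?'}->{rs.new or '?'} kept as "
                       "attribute")
            r.resulting_sequence = None
        if _neg_or_zero(r.begin) or _neg_or_zero(r.end):
            _add_payload(f, A_RANGE, {
                "index": i,
                "begin_status": codec.to_jsonable(r.begin_status),
                "begin": codec.to_jsonable(r.begin),
                "end_status": codec.to_jsonable(r.end_status),
                "end": codec.to_jsonable(r.end),
            })
            report.add("NEGATIVE_POSITION", f"{path}/featureRange[{i + 1}]",
                       "non-positive coordinates replaced by undetermined "
                       "range statuses")
            r.begin_status = m.CvTerm(**_UNDETERMINED)
            r.end_status = m.CvTerm(**_UNDETERMINED)
            r.begin = m.UnstatedPosition()
            r.end = m.UnstatedPosition()


# ---------------------------------------------------------------------------
# upgrade
# ---------------------------------------------------------------------------

def upgrade(doc25: m.Document, promote: bool = False) -> m.Document:
    """Lift a 2.5 document to level 3.0.  No content is invented; with
    ``promote=True`` the ``psimi3:`` annotations written by
    :func:`downgrade` are recognized and promoted back to first-class
    level-3.0 elements."""
    doc = copy.deepcopy(doc25)
    doc.level = m.LEVEL_30
    if promote:
        for entry in doc.entries:
            _promote_entry(entry)
    return doc


def _attributed_objects(entry: m.Entry):
    for exp in entry.experiments:
        yield exp
    for itor in entry.interactors:
        yield itor
    for inter in entry.interactions:
        yield inter
        for p in inter.participants:
            yield p
            for f in m.iter_participant_features(p):
                yield f


def _promote_entry(entry: m.Entry) -> None:
    refs: dict[int, object] = {}
    for obj in _attributed_objects(entry):
        for a in obj.attributes:
            if a.name == A_ORIG_ID and a.value:
                refs[int(a.value)] = obj

    # experiments: variable parameters and bibref reunification
    for exp in entry.experiments:
        for payload in _pop_attrs(exp, A_VPARAM):
            vp = codec.from_jsonable(payload["vp"])
            exp.variable_parameters.append(vp)
            for vv in vp.values:
                refs[vv.id] = vv
        _unsplit_bibref(exp)
    if entry.source is not None:
        _unsplit_bibref(entry.source)

    # abstract interactions back from their annotation form
    for inter in entry.interactions:
        payloads = _get_payloads(inter, A_ABSTRACT)
        if not payloads:
            continue
        payload = payloads[0]
        _pop_attrs(inter, A_ABSTRACT)
        interaction_types = inter.interaction_types
        d = inter.__dict__
        for name in ("experiments", "inferred_interactions",
                     "interaction_types", "negative", "intra_molecular",
                     "confidences", "parameters", "condition_sets"):
            d.pop(name, None)
        inter.__class__ = m.AbstractInteraction
        inter.interactor_type = codec.from_jsonable(payload["interactor_type"])
        inter.evidence_type = codec.from_jsonable(payload["evidence_type"])
        inter.organism = codec.from_jsonable(payload["organism"])
        inter.interaction_type = (
            interaction_types[0]
            if payload["has_interaction_type"] and interaction_types else None)
        inter.binding_features = [
            [refs[fid] for fid in group if fid in refs]
            for group in payload["binding_features"]
        ]
        inter.cooperative_effects = []
        inter.experiments = []

    # cooperative effects
    for inter in entry.interactions:
        if not isinstance(inter, m.AbstractInteraction):
            continue
        for payload in _pop_attrs(inter, A_EFFECT):
            inter.cooperative_effects.append(_decode_effect(payload, refs))

    # evidence interactions: condition sets and feature parameters
    for inter in entry.interactions:
        if not isinstance(inter, m.InteractionEvidence):
            continue
        for payload in _pop_attrs(inter, A_VVALUES):
            for id_set in payload["sets"]:
                inter.condition_sets.append(
                    [refs[i] for i in id_set if i in refs])
        for payload in _pop_attrs(inter, A_FPARAM):
            feature = refs.get(payload["feature"])
            param = codec.from_jsonable(payload["param"])
            if "experiment" in payload:
                exp = refs.get(payload["experiment"])
                if isinstance(exp, m.Experiment):
                    param.experiment = exp
            target = payload["param"]
            for i, cand in enumerate(inter.parameters):
                if codec.to_jsonable(_strip_param(cand)) == target:
                    del inter.parameters[i]
                    break
            if isinstance(feature, m.Feature):
                feature.parameters.append(param)

    # participants: candidate sets and stoichiometry
    for inter in entry.interactions:
        for p in inter.participants:
            for payload in _pop_attrs(p, A_CANDSET):
                cs = m.CandidateSet(
                    set_type=codec.from_jsonable(payload["set_type"]))
                for cp in payload["candidates"]:
                    cand = m.Candidate(id=cp["id"])
                    if cp["interactor"] is not None:
                        target = refs.get(cp["interactor"])
                        if isinstance(target, m.Interactor):
                            cand.interactor = target
                    cand.features = [
                        codec.from_jsonable(fp) for fp in cp["features"]]
                    cs.candidates.append(cand)
                p.entity = cs
            for payload in _pop_attrs(p, A_STOICH):
                from decimal import Decimal

                if payload["kind"] == "mean":
                    p.stoichiometry = m.MeanStoichiometry(
                        Decimal(payload["value"]))
                else:
                    p.stoichiometry = m.StoichiometryRange(
                        Decimal(payload["min"]), Decimal(payload["max"]))
            for f in p.features:
                _promote_feature(f)

    # drop synthesized carriers, then every remaining psimi3: annotation
    entry.experiments = [e for e in entry.experiments if not _is_synth(e)]
    entry.interactors = [i for i in entry.interactors if not _is_synth(i)]
    for obj in _attributed_objects(entry):
        obj.attributes = [a for a in obj.attributes
                          if not a.name.startswith(PREFIX)]
    if entry.source is not None:
        entry.source.attributes = [a for a in entry.source.attributes
                                   if not a.name.startswith(PREFIX)]


def _unsplit_bibref(owner) -> None:
    for payload in _pop_attrs(owner, A_BIBSPLIT):
        moved = [codec.from_jsonable(a) for a in payload["attrs"]]
        for attr in moved:
            for i, cand in enumerate(owner.attributes):
                if (cand.name, cand.name_ac, cand.value) == (
                        attr.name, attr.name_ac, attr.value):
                    del owner.attributes[i]
                    break
        if owner.bibref is None:
            owner.bibref = m.BibRef()
        owner.bibref.attributes.extend(moved)


def _decode_effect(payload: dict, refs: dict[int, object]) -> m.CooperativeEffect:
    evidence = [
        m.CooperativityEvidence(
            bibref=codec.from_jsonable(ev["bibref"]) or m.BibRef(),
            methods=[codec.from_jsonable(cv) for cv in ev["methods"]],
        )
        for ev in payload["evidence"]
    ]
    affected = [refs[i] for i in payload["affected"] if i in refs]
    outcome = codec.from_jsonable(payload["outcome"]) or m.CvTerm()
    response = codec.from_jsonable(payload["response"])
    if payload["kind"] == "preassembly":
        return m.Preassembly(evidence=evidence, affected=affected,
                             outcome=outcome, response=response)
    effect = m.Allostery(evidence=evidence, affected=affected,
                         outcome=outcome, response=response)
    if "allosteric_molecule" in payload:
        target = refs.get(payload["allosteric_molecule"])
        if isinstance(target, m.Participant):
            effect.allosteric_molecule = target
    eff = payload.get("effector")
    if eff is not None:
        target = refs.get(eff["ref"])
        if eff["kind"] == "molecule" and isinstance(target, m.Participant):
            effect.effector = m.MoleculeEffector(target)
        elif eff["kind"] == "modification" and isinstance(target, m.Feature):
            effect.effector = m.FeatureModificationEffector(target)
    effect.allostery_type = codec.from_jsonable(payload["allostery_type"])
    effect.allosteric_mechanism = codec.from_jsonable(
        payload["allosteric_mechanism"])
    return effect


def _promote_feature(f: m.Feature) -> None:
    for payload in _pop_attrs(f, A_ROLE):
        f.feature_role = codec.from_jsonable(payload["cv"])
    extras = sorted(_pop_attrs(f, A_DETECT), key=lambda p: p["index"])
    for payload in extras:
        f.detection_methods.append(codec.from_jsonable(payload["cv"]))
    resseqs = sorted(_pop_attrs(f, A_RESSEQ), key=lambda p: p["index"])
    for payload in reversed(resseqs):
        rs = codec.from_jsonable(payload["rs"])
        if payload["index"] < len(f.ranges):
            f.ranges[payload["index"]].resulting_sequence = rs
        if rs.xref is not None and f.xref is not None:
            if payload["xref_was_none"]:
                f.xref = None
            else:
                copied = [rs.xref.primary, *rs.xref.secondary]
                for ref in copied:
                    for i, cand in enumerate(f.xref.secondary):
                        if cand == ref:
                            del f.xref.secondary[i]
                            break
    for payload in _pop_attrs(f, A_RANGE):
        if payload["index"] < len(f.ranges):
            r = f.ranges[payload["index"]]
            r.begin_status = codec.from_jsonable(payload["begin_status"])
            r.begin = codec.from_jsonable(payload["begin"])
            r.end_status = codec.from_jsonable(payload["end_status"])
            r.end = codec.from_jsonable(payload["end"])
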
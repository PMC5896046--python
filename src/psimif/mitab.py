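"""MITAB 2.7 export: evidence interactions as 42-column tab-delimited rows.

N-ary interactions are spoke-expanded into n−1 binary pairs hubbed on the
bait participant (or the first participant when no bait is annotated).
Abstract interactions carry no experimental evidence to tabulate and are
skipped with a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from . import model as m

log = logging.getLogger(__name__)

MI_BAIT = "MI:0496"

COLUMNS = (
    "ID(s) interactor A", "ID(s) interactor B",
    "Alt. ID(s) interactor A", "Alt. ID(s) interactor B",
    "Alias(es) interactor A", "Alias(es) interactor B",
    "Interaction detection method(s)", "Publication 1st author(s)",
    "Publication Identifier(s)", "Taxid interactor A", "Taxid interactor B",
    "Interaction type(s)", "Source database(s)",
    "Interaction identifier(s)", "Confidence value(s)", "Expansion method(s)",
    "Biological role(s) interactor A", "Biological role(s) interactor B",
    "Experimental role(s) interactor A", "Experimental role(s) interactor B",
    "Type(s) interactor A", "Type(s) interactor B",
    "Xref(s) interactor A", "Xref(s) interactor B", "Interaction Xref(s)",
    "Annotation(s) interactor A", "Annotation(s) interactor B",
    "Interaction annotation(s)", "Host organism(s)",
    "Interaction parameter(s)", "Creation date", "Update date",
    "Checksum(s) interactor A", "Checksum(s) interactor B",
    "Interaction Checksum(s)", "Negative",
    "Feature(s) interactor A", "Feature(s) interactor B",
    "Stoichiometry(s) interactor A", "Stoichiometry(s) interactor B",
    "Identification method participant A",
    "Identification method participant B",
)

assert len(COLUMNS) == 42


@dataclass
class BinaryPair:
    a: m.Participant
    b: m.Participant
    expansion: str  # "none" | "spoke"
    source_interaction: m.InteractionEvidence


def expand_binary(interaction: m.InteractionEvidence) -> list[BinaryPair]:
    """Spoke-expand an evidence interaction into binary pairs.

    Two participants give the single pair unexpanded; n > 2 gives n−1
    hub×spoke pairs with the bait (else the first participant) as hub, in
    document order; a single participant gives a self-pair (the
    intra-molecular case).
    """
    parts = interaction.participants
    if not parts:
        raise ValueError("cannot expand an interaction with no participants")
    if len(parts) == 1:
        return [BinaryPair(parts[0], parts[0], "none", interaction)]
    if len(parts) == 2:
        return [BinaryPair(parts[0], parts[1], "none", interaction)]
    hub = next(
        (p for p in parts
         if any(r.mi_accession == MI_BAIT for r in p.experimental_roles)),
        parts[0],
    )
    return [BinaryPair(hub, p, "spoke", interaction)
            for p in parts if p is not hub]


# ---------------------------------------------------------------------------
# cell formatting
# ---------------------------------------------------------------------------

def _esc(text: str) -> str:
    """No tab, newline or pipe may leak out of a free-text value."""
    for bad in "\t\n\r|":
        text = text.replace(bad, " ")
    return text


def _join(values: Iterable[str]) -> str:
    out = [v for v in values if v]
    return "|".join(out) if out else "-"


def _fmt_cv(cv: Optional[m.CvTerm]) -> str:
    if cv is None:
        return ""
    label = _esc(cv.short_label or cv.full_name or "unknown")
    if cv.mi_accession:
        return f'psi-mi:"{cv.mi_accession}"({label})'
    return f"psi-mi:{label}"


def _participant_interactor(p: m.Participant) -> Optional[m.Interactor]:
    if isinstance(p.entity, m.Interactor):
        return p.entity
    return None


def _primary_id(p: m.Participant) -> str:
    itor = _participant_interactor(p)
    if itor is not None and itor.xref is not None:
        ref = itor.xref.primary
        return f"{_esc(ref.db)}:{_esc(ref.id)}"
    if isinstance(p.entity, m.CandidateSet):
        # a molecule set has no single identifier; use the participant label
        label = (p.names.short_label if p.names else None) or "molecule set"
        return f"psimif:{_esc(label)}"
    if isinstance(p.entity, m.InteractionRef):
        return f"psimif:interaction-{p.entity.target.id}"
    if itor is not None and itor.names and itor.names.short_label:
        return f"unknown:{_esc(itor.names.short_label)}"
    return "-"


def _alt_ids(p: m.Participant) -> str:
    itor = _participant_interactor(p)
    if itor is None or itor.xref is None:
        return "-"
    return _join(f"{_esc(r.db)}:{_esc(r.id)}" for r in itor.xref.secondary)


def _aliases(p: m.Participant) -> str:
    names: list[str] = []
    itor = _participant_interactor(p)
    if itor is not None and itor.names is not None:
        if itor.names.short_label:
            names.append(
                f"psi-mi:{_esc(itor.names.short_label)}(display_short)")
        if itor.names.full_name:
            names.append(f"psi-mi:{_esc(itor.names.full_name)}(display_long)")
        names.extend(f"psi-mi:{_esc(a)}(alias)" for a in itor.names.aliases)
    if isinstance(p.entity, m.CandidateSet):
        # candidates surface in the alias column (no dedicated MITAB slot)
        for cand in p.entity.candidates:
            if cand.interactor and cand.interactor.names \
                    and cand.interactor.names.short_label:
                names.append(
                    f"psi-mi:{_esc(cand.interactor.names.short_label)}"
                    "(set member)")
    return _join(names)


def _taxid(p: m.Participant) -> str:
    itor = _participant_interactor(p)
    if itor is None or itor.organism is None:
        return "-"
    org = itor.organism
    label = (org.names.short_label if org.names else None) or "unknown"
    return f"taxid:{org.ncbi_tax_id}({_esc(label)})"


def _itor_type(p: m.Participant) -> str:
    if isinstance(p.entity, m.CandidateSet):
        return _join([_fmt_cv(p.entity.set_type)])
    itor = _participant_interactor(p)
    return _join([_fmt_cv(itor.interactor_type)]) if itor else "-"


def _xrefs(p: m.Participant) -> str:
    return "-"


def _annotations(obj) -> str:
    out = []
    for a in obj.attributes:
        value = _esc(a.value) if a.value else ""
        out.append(f"{_esc(a.name)}:{value}" if value else _esc(a.name))
    return _join(out)


def _features(p: m.Participant) -> str:
    def pos(x: m.Position) -> str:
        if isinstance(x, m.ExactPosition):
            return str(x.value)
        if isinstance(x, m.IntervalPosition):
            return f"{x.start}..{x.end}"
        return "?"

    out = []
    for f in m.iter_participant_features(p):
        ftype = (f.feature_type.short_label
                 if f.feature_type and f.feature_type.short_label
                 else "feature")
        for r in f.ranges:
            out.append(f"{_esc(ftype)}:{pos(r.begin)}-{pos(r.end)}")
    return _join(out)


def _stoichiometry(p: m.Participant) -> str:
    st = p.stoichiometry
    if isinstance(st, m.MeanStoichiometry):
        return str(st.value)
    if isinstance(st, m.StoichiometryRange):
        return f"{st.min_value}-{st.max_value}"
    return "-"


def _ident_methods(p: m.Participant, exp: Optional[m.Experiment]) -> str:
    if p.identification_methods:
        return _join(_fmt_cv(cv) for cv in p.identification_methods)
    if exp is not None and exp.participant_identification_method is not None:
        return _join([_fmt_cv(exp.participant_identification_method)])
    return "-"


def _interaction_ids(inter: m.InteractionEvidence) -> str:
    if inter.xref is not None:
        ref = inter.xref.primary
        return f"{_esc(ref.db)}:{_esc(ref.id)}"
    return f"psimif:interaction-{inter.id}"


def _parameters(inter: m.InteractionEvidence) -> str:
    out = []
    for p in inter.parameters:
        value = f"{p.factor}"
        if p.exponent:
            value = f"{p.factor}x{p.base}^{p.exponent}"
        unit = f"({_esc(p.unit)})" if p.unit else ""
        out.append(f"{_esc(p.term)}:{value}{unit}")
    return _join(out)


def _row(pair: BinaryPair, source_label: str) -> list[str]:
    inter = pair.source_interaction
    exp = inter.experiments[0] if inter.experiments else None
    a, b = pair.a, pair.b
    detection = _join([_fmt_cv(exp.interaction_detection_method)]) if exp else "-"
    pubs = "-"
    if exp is not None and exp.bibref is not None and exp.bibref.xref is not None:
        ref = exp.bibref.xref.primary
        pubs = f"{_esc(ref.db)}:{_esc(ref.id)}"
    host = "-"
    if exp is not None and exp.host_organisms:
        org = exp.host_organisms[0]
        label = (org.names.short_label if org.names else None) or "unknown"
        host = f"taxid:{org.ncbi_tax_id}({_esc(label)})"
    expansion = ('psi-mi:"MI:1060"(spoke expansion)'
                 if pair.expansion == "spoke" else "-")
    confidences = _join(
        f"{_esc(c.unit.short_label or 'score')}:{_esc(c.value)}"
        for c in inter.confidences)
    return [
        _primary_id(a), _primary_id(b),
        _alt_ids(a), _alt_ids(b),
        _aliases(a), _aliases(b),
        detection,
        "-",
        pubs,
        _taxid(a), _taxid(b),
        _join(_fmt_cv(t) for t in inter.interaction_types),
        source_label,
        _interaction_ids(inter),
        confidences,
        expansion,
        _join([_fmt_cv(a.biological_role)]),
        _join([_fmt_cv(b.biological_role)]),
        _join(_fmt_cv(r) for r in a.experimental_roles),
        _join(_fmt_cv(r) for r in b.experimental_roles),
        _itor_type(a), _itor_type(b),
        _xrefs(a), _xrefs(b),
        "-",
        _annotations(a.entity) if isinstance(a.entity, m.Interactor) else "-",
        _annotations(b.entity) if isinstance(b.entity, m.Interactor) else "-",
        _annotations(inter),
        host,
        _parameters(inter),
        "-", "-",
        "-", "-", "-",
        "true" if inter.negative else "false",
        _features(a), _features(b),
        _stoichiometry(a), _stoichiometry(b),
        _ident_methods(a, exp), _ident_methods(b, exp),
    ]


def write_mitab(doc: m.Document, version: str = "2.7",
                header: bool = True) -> str:
    """Render all evidence interactions of a document as MITAB 2.7 text."""
    if version != "2.7":
        raise ValueError(f"unsupported MITAB version {version!r}")
    doc = m.normalize(doc)
    lines: list[str] = []
    if header:
        lines.append("#" + "\t".join(COLUMNS))
    for entry in doc.entries:
        source_label = "-"
        if entry.source and entry.source.names \
                and entry.source.names.short_label:
            source_label = f"psi-mi:{_esc(entry.source.names.short_label)}"
        for inter in entry.interactions:
            if isinstance(inter, m.AbstractInteraction):
                log.info("skipping abstract interaction %s (no experimental "
                         "evidence to tabulate)",
                         (inter.names.short_label if inter.names
                          else inter.id))
                continue
            for pair in expand_binary(inter):
                lines.append("\t".join(_row(pair, source_label)))
    return "\n".join(lines) + "\n"
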
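"""JSON codec for a subset of the object model.

The 2.5 downgrade stores removed level-3.0 constructs inside ordinary MIF
attributes so they survive as machine-parsable annotations and can be
promoted back to first-class elements.  This codec turns the relevant model
dataclasses into plain JSON and back; Decimals keep their lexical form.
"""

from __future__ import annotations

import json
from dataclasses import fields, is_dataclass
from decimal import Decimal

from . import model as m

_TYPES = {
    cls.__name__: cls
    for cls in (
        m.Names, m.DbReference, m.Xref, m.Attribute, m.CvTerm, m.BibRef,
        m.Organism, m.Parameter, m.Confidence, m.ExactPosition,
        m.IntervalPosition, m.UnstatedPosition, m.ResultingSequence,
        m.FeatureRange, m.Feature, m.VariableValue, m.VariableParameter,
    )
}


def to_jsonable(obj):
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, Decimal):
        return {"~d": str(obj)}
    if isinstance(obj, list):
        return [to_jsonable(v) for v in obj]
    if is_dataclass(obj):
        name = type(obj).__name__
        if name not in _TYPES:
            raise ValueError(f"{name} is not JSON-encodable")
        out = {"~t": name}
        for f in fields(obj):
            value = getattr(obj, f.name)
            if f.name == "experiment" and isinstance(obj, m.Parameter):
                if value is not None:
                    raise ValueError(
                        "cannot encode a parameter bound to an experiment")
                continue
            out[f.name] = to_jsonable(value)
        return out
    raise ValueError(f"cannot encode {type(obj).__name__}")


def from_jsonable(data):
    if data is None or isinstance(data, (str, bool, int)):
        return data
    if isinstance(data, list):
        return [from_jsonable(v) for v in data]
    if isinstance(data, dict):
        if "~d" in data:
            return Decimal(data["~d"])
        cls = _TYPES[data["~t"]]
        kwargs = {
            k: from_jsonable(v) for k, v in data.items() if k != "~t"
        }
        return cls(**kwargs)
    raise ValueError(f"cannot decode {type(data).__name__}")


def dumps(data) -> str:
    return json.dumps(data, sort_keys=True, separators=(",", ":"))


def loads(text: str):
    return json.loads(text)
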
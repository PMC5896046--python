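"""Shared finding type used by the reader and the semantic validator."""

from __future__ import annotations

from dataclasses import dataclass
import json

ERROR = "error"
WARNING = "warning"
INFO = "info"


@dataclass
class ValidationFinding:
    """One diagnostic: a stable machine code, a severity, the element path it
    points at and a human-readable message."""

    code: str
    severity: str
    path: str
    message: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "code": self.code,
                "severity": self.severity,
                "path": self.path,
                "message": self.message,
            },
            sort_keys=True,
        )

    def __str__(self) -> str:  # human-readable one-liner
        return f"[{self.severity.upper()}] {self.code} at {self.path}: {self.message}"
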
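"""Validation messages shared by the import, datasheet and gate layers."""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Severity(enum.Enum):
    ERROR = "ERROR"      # blocks the gate
    WARNING = "WARNING"  # advisory: the originating scientist decides
    INFO = "INFO"

    def __lt__(self, other: "Severity") -> bool:
        order = {"ERROR": 0, "WARNING": 1, "INFO": 2}
        return order[self.value] < order[other.value]


@dataclass
class Finding:
    """A validation message with a stable code and a locator.

    ERROR findings block acceptance; WARNING and INFO never do.
    """

    severity: Severity
    code: str
    locator: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.value} [{self.code}] {self.locator}: {self.message}"

    def as_dict(self) -> dict:
        return {"severity": self.severity.value, "code": self.code,
                "locator": self.locator, "message": self.message}
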
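"""Structured lint findings, shared by the framework validators and the
external-scheme auditor."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"
    INFO = "info"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class LintFinding:
    """One audit outcome.

    ``witnesses`` names the offending entities; a finding without witnesses
    is only admissible when it is informational or not evaluable.
    """

    rule: str
    severity: Severity
    message: str
    witnesses: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.witnesses and self.severity == Severity.ERROR:
            raise ValueError(f"error finding {self.rule!r} must cite a witness")

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "severity": self.severity.value,
            "message": self.message,
            "witnesses": list(self.witnesses),
        }


@dataclass
class LintReport:
    """An ordered collection of findings with CI-friendly accessors."""

    findings: list[LintFinding] = field(default_factory=list)

    def add(
        self,
        rule: str,
        severity: Severity,
        message: str,
        witnesses: Sequence[str] = (),
    ) -> LintFinding:
        finding = LintFinding(rule, severity, message, tuple(witnesses))
        self.findings.append(finding)
        return finding

    def extend(self, other: "LintReport") -> None:
        self.findings.extend(other.findings)

    def by_rule(self, rule: str) -> list[LintFinding]:
        return [f for f in self.findings if f.rule == rule]

    @property
    def errors(self) -> list[LintFinding]:
        return [f for f in self.findings if f.severity == Severity.ERROR]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __iter__(self) -> Iterator[LintFinding]:
        return iter(self.findings)

    def __len__(self) -> int:
        return len(self.findings)

    def to_dict(self) -> dict:
        return {"findings": [f.to_dict() for f in self.findings]}

    def render(self) -> str:
        if not self.findings:
            return "no findings\n"
        lines = []
        for f in self.findings:
            wit = f" [{', '.join(f.witnesses)}]" if f.witnesses else ""
            lines.append(f"{f.severity.value:>13}  {f.rule}: {f.message}{wit}")
        return "\n".join(lines) + "\n"
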
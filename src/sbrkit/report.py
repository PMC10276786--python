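"""The Core Company BR position (CBR): a concise, standalone 1-2 page
summary of the structured benefit-risk assessment.

The CBR is the single authoritative statement of a product's
benefit-risk profile, from which every other BR communication derives.
Five principles govern it and are enforced here as lint rules: (1) it is
highly succinct and standalone — operationalized as a body-text ceiling
of 900 words (about two pages at standard formatting); (2) it rests on a
concise set of precisely defined, mutually exclusive benefits and risks
(cardinality checks delegated to the value-tree validator); (3) every
Key Safety Risk carries either a quantitative estimate or an explicit
uncertainty statement; (4) the methodology is one of the recognized set;
(5) the development milestone is recorded. The CBR is a living document:
re-issuing it with changed content increments the version and marks the
prior one superseded.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

from pydantic import BaseModel

from .errors import ValidationError
from .selector import METHOD_CATEGORY
from .value_tree import ValueTree, read_tree, validate_tree

__all__ = ["CBRPosition", "LintReport", "lint_cbr", "render_cbr", "PositionLog"]

WORD_CEILING = 900
RECOGNIZED_METHODS = frozenset(METHOD_CATEGORY)


class CBRPosition(BaseModel):
    product: str
    indication: str
    milestone: str | None = None
    methodology: str = "effects_table"
    tree: ValueTree
    benefit_statements: dict[str, str] = {}  # node_id -> statement
    risk_statements: dict[str, str] = {}
    # node_id -> quantitative estimate text (e.g. "NNH 93 (...)"), optional
    estimates: dict[str, str] = {}
    # node_id -> uncertainty text; mandatory for risks without an estimate
    uncertainties: dict[str, str] = {}
    conclusion: str = ""
    version: int = 1
    date: str = ""
    status: str = "current"  # draft | current | superseded

    def to_json_obj(self) -> dict[str, Any]:
        obj = self.model_dump(exclude={"tree"})
        obj["tree"] = {
            "title": self.tree.title,
            "benefits": [n.model_dump(mode="json", exclude_none=True)
                         for n in self.tree.benefits],
            "risks": [n.model_dump(mode="json", exclude_none=True)
                      for n in self.tree.risks],
        }
        return obj

    @classmethod
    def from_json_obj(cls, obj: Mapping[str, Any]) -> "CBRPosition":
        data = dict(obj)
        tree_obj = data.pop("tree")
        tree = ValueTree(
            title=tree_obj.get("title", ""),
            benefits=tree_obj["benefits"],
            risks=tree_obj["risks"],
        )
        return cls(tree=tree, **data)


class LintReport(BaseModel):
    violations: list[str] = []
    warnings: list[str] = []

    @property
    def ok(self) -> bool:
        return not self.violations


def _body_text(pos: CBRPosition) -> str:
    parts = [
        pos.conclusion,
        *pos.benefit_statements.values(),
        *pos.risk_statements.values(),
        *pos.estimates.values(),
        *pos.uncertainties.values(),
    ]
    return " ".join(p for p in parts if p)


def lint_cbr(pos: CBRPosition) -> LintReport:
    """Check a position against the five structural principles."""
    violations: list[str] = []
    warnings: list[str] = []
    word_count = len(_body_text(pos).split())
    if word_count > WORD_CEILING:
        violations.append(
            f"principle 1 (succinct standalone output): body text is "
            f"{word_count} words, ceiling is {WORD_CEILING}"
        )
    tree_report = validate_tree(pos.tree)
    for err in tree_report.errors:
        violations.append(f"principle 2 (concise, mutually exclusive set): {err}")
    for warn in tree_report.warnings:
        warnings.append(f"principle 2: {warn}")
    for node in pos.tree.risks:
        has_estimate = bool(pos.estimates.get(node.node_id, "").strip())
        has_uncertainty = bool(pos.uncertainties.get(node.node_id, "").strip())
        if not (has_estimate or has_uncertainty):
            violations.append(
                f"principle 3 (uncertainty emphasis): Key Safety Risk "
                f"{node.node_id!r} has neither a quantitative estimate nor an "
                "uncertainty statement"
            )
    if pos.methodology not in RECOGNIZED_METHODS:
        violations.append(
            f"principle 4 (recognized frameworks): methodology "
            f"{pos.methodology!r} is not one of {sorted(RECOGNIZED_METHODS)}"
        )
    if not pos.milestone:
        violations.append(
            "principle 5 (milestone-driven assessment): no development "
            "milestone recorded"
        )
    return LintReport(violations=violations, warnings=warnings)


def render_cbr(pos: CBRPosition, format: str = "markdown") -> str:
    """Render a linted position as a deterministic document.

    Section order is header, benefits, risks, uncertainties, conclusion,
    version footer. Rendering is pure: identical input yields a
    byte-identical document. Raises on lint violations.
    """
    if format not in ("markdown", "plain_text"):
        raise ValidationError(f"unknown format {format!r}")
    report = lint_cbr(pos)
    if not report.ok:
        raise ValidationError(
            "position fails lint:\n  - " + "\n  - ".join(report.violations)
        )
    md = format == "markdown"

    def h(level: int, text: str) -> str:
        return f"{'#' * level} {text}" if md else text.upper()

    lines = [
        h(1, f"Core Company BR Position — {pos.product}"),
        "",
        f"Indication: {pos.indication}",
        f"Milestone: {pos.milestone}",
        f"Methodology: {pos.methodology}",
        "",
        h(2, "Key Clinical Benefits"),
    ]
    for node in pos.tree.benefits:
        stmt = pos.benefit_statements.get(node.node_id, node.definition)
        est = pos.estimates.get(node.node_id, "")
        suffix = f" ({est})" if est else ""
        lines.append(f"- {node.label}: {stmt}{suffix}")
    lines += ["", h(2, "Key Safety Risks")]
    for node in pos.tree.risks:
        stmt = pos.risk_statements.get(node.node_id, node.definition)
        est = pos.estimates.get(node.node_id, "")
        suffix = f" ({est})" if est else ""
        lines.append(f"- {node.label}: {stmt}{suffix}")
    uncertain = [
        (pos.tree.node(nid).label, text)
        for nid, text in pos.uncertainties.items()
        if text.strip()
    ]
    if uncertain:
        lines += ["", h(2, "Uncertainties")]
        for label, text in uncertain:
            lines.append(f"- {label}: {text}")
    lines += ["", h(2, "Benefit-Risk Conclusion"), pos.conclusion or "(none stated)"]
    lines += [
        "",
        "---" if md else "-" * 40,
        f"Version {pos.version} ({pos.status}){' — ' + pos.date if pos.date else ''}",
    ]
    return "\n".join(lines) + "\n"


class PositionLog:
    """Version history for a product's CBR.

    The position is dynamic: when new important data change its content,
    issuing the update increments the version and marks the previous one
    superseded. Re-issuing identical content is a no-op.
    """

    def __init__(self) -> None:
        self.history: list[CBRPosition] = []

    @property
    def current(self) -> CBRPosition | None:
        return self.history[-1] if self.history else None

    def issue(self, pos: CBRPosition) -> CBRPosition:
        prev = self.current
        if prev is not None:
            if pos.to_json_obj() | {"version": 0, "status": "", "date": ""} == \
               prev.to_json_obj() | {"version": 0, "status": "", "date": ""}:
                return prev
            self.history[-1] = prev.model_copy(update={"status": "superseded"})
            pos = pos.model_copy(update={"version": prev.version + 1, "status": "current"})
        else:
            pos = pos.model_copy(update={"version": 1, "status": "current"})
        self.history.append(pos)
        return pos


def write_position(pos: CBRPosition, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pos.to_json_obj(), indent=2) + "\n")


def read_position(path: str | Path) -> CBRPosition:
    return CBRPosition.from_json_obj(json.loads(Path(path).read_text()))
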
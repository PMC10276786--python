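"""Builders for the milestone deliverables: the early-development context
table, the effects table, and forest-plot data.

The context table is a descriptive four-row framework (analysis of the
condition, current treatment options, potential clinical benefits,
potential safety risks), each row pairing an overview-and-evidence cell
with an uncertainties-and-implications cell. The effects table is the
semi-quantitative workhorse: one row per Key Clinical Benefit or Key
Safety Risk with per-arm values computed from trial counts and a
mandatory uncertainties/strength-of-evidence note. Forest-plot data
expresses the same outcomes as risk ratios (log scale) or risk
differences (linear scale) with confidence intervals.

Numeric cells are always recomputed from counts — printed percentages
are never trusted inputs — using one-decimal half-up percent formatting.
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
from pydantic import BaseModel

from .effect_stats import relative_risk, risk_difference
from .errors import ValidationError
from .trial_data import TrialDataset
from .value_tree import BRNode, Side, ValueTree, WeightSet

__all__ = [
    "ContextTable",
    "EffectsRow",
    "EffectsTable",
    "ForestRecord",
    "ForestPlotData",
    "format_percent",
    "build_context_table",
    "build_effects_table",
    "build_forest_data",
]

CONTEXT_ROWS = (
    "analysis_of_condition",
    "current_treatment_options",
    "potential_clinical_benefits",
    "potential_safety_risks",
)
_ROW_TITLES = {
    "analysis_of_condition": "Analysis of condition",
    "current_treatment_options": "Current treatment options",
    "potential_clinical_benefits": "Potential clinical benefits",
    "potential_safety_risks": "Potential safety risks",
}
NOT_AVAILABLE = "not yet available"


def format_percent(events: int, total: int) -> str:
    """Percent of ``events/total`` to one decimal, half-up (80.8, 66.1)."""
    pct = Decimal(events * 100) / Decimal(total)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class ContextTable(BaseModel):
    """Four framework rows x (overview_and_evidence, uncertainties_and_implications)."""

    cells: dict[str, dict[str, str]]
    completeness: float

    def to_json_obj(self) -> dict[str, Any]:
        return self.model_dump()

    def to_markdown(self) -> str:
        lines = [
            "| | Overview and evidence | Uncertainties and implications |",
            "|---|---|---|",
        ]
        for row in CONTEXT_ROWS:
            cells = self.cells[row]
            lines.append(
                f"| {_ROW_TITLES[row]} | {cells['overview_and_evidence']} "
                f"| {cells['uncertainties_and_implications']} |"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_json_obj(cls, obj: Mapping[str, Any]) -> "ContextTable":
        return cls(cells=obj["cells"], completeness=obj["completeness"])


def build_context_table(content: Mapping[str, Mapping[str, str]]) -> ContextTable:
    """Assemble a context table; empty cells become "not yet available".

    ``content`` maps row keys (see :data:`CONTEXT_ROWS`) to
    {overview_and_evidence, uncertainties_and_implications}. The
    completeness score is filled cells / 8.
    """
    unknown = sorted(set(content) - set(CONTEXT_ROWS))
    if unknown:
        raise ValidationError(f"unknown context-table row(s) {unknown}")
    cells: dict[str, dict[str, str]] = {}
    filled = 0
    for row in CONTEXT_ROWS:
        cells[row] = {}
        for col in ("overview_and_evidence", "uncertainties_and_implications"):
            text = str(content.get(row, {}).get(col, "") or "").strip()
            if text:
                filled += 1
                cells[row][col] = text
            else:
                cells[row][col] = NOT_AVAILABLE
    return ContextTable(cells=cells, completeness=filled / 8)


class EffectsRow(BaseModel):
    effect: str
    short_description: str
    unit: str
    treatment_value: str
    comparator_value: str
    uncertainties: str
    references: str
    section: str  # "favorable" | "unfavorable"


class EffectsTable(BaseModel):
    """Favorable rows first, then unfavorable; every row carries a
    non-empty uncertainties/strength-of-evidence note."""

    rows: list[EffectsRow]

    def to_json_obj(self) -> dict[str, Any]:
        return self.model_dump()

    def to_markdown(self) -> str:
        lines = [
            "| Effect | Short description | Unit | Treatment | Comparator "
            "| Uncertainties / strength of evidence | References |",
            "|---|---|---|---|---|---|---|",
        ]
        current = None
        for row in self.rows:
            if row.section != current:
                current = row.section
                title = current.capitalize()
                lines.append(f"| **{title}** | | | | | | |")
            lines.append(
                f"| {row.effect} | {row.short_description} | {row.unit} "
                f"| {row.treatment_value} | {row.comparator_value} "
                f"| {row.uncertainties} | {row.references} |"
            )
        return "\n".join(lines) + "\n"

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([r.model_dump() for r in self.rows]).to_csv(path, index=False)


class Annotation(BaseModel):
    """Free-text cells attached to an effects-table row."""

    short_description: str = ""
    unit: str = "%"
    uncertainties: str = ""
    references: str = ""
    # pass-through values for externally computed effects (e.g. hazard
    # ratios from a time-to-event analysis); never computed here
    treatment_value: str | None = None
    comparator_value: str | None = None


def _ordered(tree: ValueTree, ws: WeightSet | None, side: Side) -> list[BRNode]:
    return ws.ordered_nodes(tree, side) if ws is not None else tree.side_nodes(side)


def build_effects_table(
    tree: ValueTree,
    ds: TrialDataset,
    annotations: Mapping[str, Annotation | Mapping[str, str]] | None = None,
    ws: WeightSet | None = None,
) -> EffectsTable:
    """One row per tree node; numeric cells recomputed from trial counts.

    Linked nodes get per-arm percentages (one decimal, half-up). Nodes
    without a linked outcome appear with an em-dash value and an
    auto-generated missing-data note unless an annotation supplies the
    uncertainty text. An empty uncertainties cell on a linked node is an
    error: every effect must state its uncertainties.
    """
    annotations = annotations or {}
    rows: list[EffectsRow] = []
    for side, section in ((Side.benefit, "favorable"), (Side.risk, "unfavorable")):
        for node in _ordered(tree, ws, side):
            ann = annotations.get(node.node_id, Annotation())
            if not isinstance(ann, Annotation):
                ann = Annotation(**ann)
            if node.linked_outcome_id is not None:
                if node.linked_outcome_id not in ds:
                    raise ValidationError(
                        f"node {node.node_id!r} links to unknown outcome "
                        f"{node.linked_outcome_id!r}"
                    )
                cmp_ = ds.get(node.linked_outcome_id)
                t_val = format_percent(cmp_.treatment.events, cmp_.treatment.total)
                c_val = format_percent(cmp_.comparator.events, cmp_.comparator.total)
                uncertainties = ann.uncertainties.strip()
                if not uncertainties:
                    raise ValidationError(
                        f"node {node.node_id!r}: uncertainties text is mandatory"
                    )
            elif ann.treatment_value is not None and ann.comparator_value is not None:
                t_val, c_val = ann.treatment_value, ann.comparator_value
                uncertainties = ann.uncertainties.strip()
                if not uncertainties:
                    raise ValidationError(
                        f"node {node.node_id!r}: uncertainties text is mandatory"
                    )
            else:
                t_val = c_val = "—"
                uncertainties = ann.uncertainties.strip() or (
                    f"No trial data linked for {node.label!r}; "
                    "frequency not yet estimable"
                )
            rows.append(
                EffectsRow(
                    effect=node.label,
                    short_description=ann.short_description or node.definition,
                    unit=ann.unit,
                    treatment_value=t_val,
                    comparator_value=c_val,
                    uncertainties=uncertainties,
                    references=ann.references,
                    section=section,
                )
            )
    return EffectsTable(rows=rows)


class ForestRecord(BaseModel):
    label: str
    node_id: str
    side: str
    point: float
    lower: float
    upper: float
    flagged: str = ""  # e.g. continuity correction note


class ForestPlotData(BaseModel):
    records: list[ForestRecord]
    scale: str  # "ratio_log" | "difference_linear"
    level: float

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([r.model_dump() for r in self.records]).to_csv(path, index=False)

    def to_json_obj(self) -> dict[str, Any]:
        return self.model_dump()

    def plot(self, path: str | Path) -> None:
        """Optional static forest plot (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.records)
        fig, ax = plt.subplots(figsize=(6, 0.5 * n + 1.5))
        ys = range(n, 0, -1)
        for y, rec in zip(ys, self.records):
            ax.plot([rec.lower, rec.upper], [y, y], "-", color="black")
            ax.plot([rec.point], [y], "s",
                    color="tab:blue" if rec.side == "benefit" else "tab:red")
        ax.set_yticks(list(ys))
        ax.set_yticklabels([r.label for r in self.records])
        if self.scale == "ratio_log":
            ax.set_xscale("log")
            ax.axvline(1.0, color="grey", linestyle="--")
            ax.set_xlabel(f"Risk ratio ({self.level:.0%} CI)")
        else:
            ax.axvline(0.0, color="grey", linestyle="--")
            ax.set_xlabel(f"Risk difference ({self.level:.0%} CI)")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def build_forest_data(
    tree: ValueTree,
    ds: TrialDataset,
    scale: str = "ratio_log",
    level: float = 0.95,
    ws: WeightSet | None = None,
) -> ForestPlotData:
    """One forest record per tree node, benefits first then risks, each
    side in weighted order when a WeightSet is given.

    ``scale`` selects risk ratios (``ratio_log``) or risk differences
    (``difference_linear``, hybrid-score interval). Outcomes with zero
    cells are flagged, never dropped.
    """
    if scale not in ("ratio_log", "difference_linear"):
        raise ValidationError(f"unknown scale {scale!r}")
    records = []
    for side in (Side.benefit, Side.risk):
        for node in _ordered(tree, ws, side):
            if node.linked_outcome_id is None or node.linked_outcome_id not in ds:
                raise ValidationError(
                    f"node {node.node_id!r} has no resolvable linked outcome"
                )
            cmp_ = ds.get(node.linked_outcome_id)
            if scale == "ratio_log":
                rr = relative_risk(cmp_, level=level)
                point, lower, upper = rr.rr, rr.lower, rr.upper
                flag = "continuity-corrected (zero cell)" if rr.continuity_corrected else ""
                if math.isinf(point) or math.isnan(point):
                    flag = (flag + "; " if flag else "") + "undefined/infinite risk ratio"
            else:
                rd = risk_difference(cmp_, level=level)
                point, lower, upper = rd.rd, rd.lower, rd.upper
                flag = ""
            records.append(
                ForestRecord(
                    label=node.label,
                    node_id=node.node_id,
                    side=node.side.value,
                    point=point,
                    lower=lower,
                    upper=upper,
                    flagged=flag,
                )
            )
    return ForestPlotData(records=records, scale=scale, level=level)


def context_table_to_json(table: ContextTable, path: str | Path) -> None:
    Path(path).write_text(json.dumps(table.to_json_obj(), indent=2) + "\n")


def context_table_from_json(path: str | Path) -> ContextTable:
    return ContextTable.from_json_obj(json.loads(Path(path).read_text()))
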
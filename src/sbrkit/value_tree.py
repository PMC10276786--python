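"""Value trees of Key Clinical Benefits and Key Safety Risks, with
ordinal and anchor-100 weighting and multi-rater Delphi aggregation.

A value tree is the simplest structured benefit-risk display: two
branches, one listing the Key Clinical Benefits (favorable effects,
normally the pivotal-trial efficacy endpoints) and one the Key Safety
Risks (unfavorable effects important to patients or approvability).
Good practice keeps the tree small — around 2-3 benefits and 6-8
risks — with node definitions precise and mutually exclusive so that
no clinical event is double-counted; :func:`validate_tree` checks the
machine-checkable proxies of these rules and reports the cardinality
guidance as warnings, not errors.

Two weighting modes are supported. Ordinal ranking orders nodes within
each side by relative medical importance (frequencies deliberately play
no part). The anchor-100 mode fixes the single most important benefit at
100 and scores every other node relative to it; a panel of raters can
produce these scores over one or more Delphi rounds, aggregated by the
per-node median of the final round.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import SchemaError, ValidationError

__all__ = [
    "Side",
    "RiskCriteria",
    "BRNode",
    "ValueTree",
    "WeightSet",
    "DelphiPanel",
    "ValidationReport",
    "ConvergenceReport",
    "validate_tree",
    "ordinal_weighting",
    "delphi_aggregate",
    "normalize_weights",
    "read_tree",
    "write_tree",
    "read_delphi_csv",
    "render_tree_text",
    "render_tree_dot",
]

BENEFIT_RANGE = (2, 3)
RISK_RANGE = (6, 8)


class Side(str, Enum):
    benefit = "benefit"
    risk = "risk"


class RiskCriteria(BaseModel):
    """1-5 scores on the five criteria used to qualify a Key Safety Risk:
    signal strength/causality, seriousness, manageability, patient-centric
    burden, and differentiation from competitors or standard of care."""

    model_config = ConfigDict(frozen=True)

    signal_strength: int
    seriousness: int
    manageability: int
    patient_impact: int
    differentiation: int

    @model_validator(mode="after")
    def _check_range(self) -> "RiskCriteria":
        for name, value in self.model_dump().items():
            if not 1 <= value <= 5:
                raise ValueError(f"criterion {name} must be in 1..5, got {value}")
        return self


class BRNode(BaseModel):
    """One Key Clinical Benefit or Key Safety Risk."""

    model_config = ConfigDict(frozen=True)

    node_id: str
    label: str
    side: Side
    definition: str = ""
    risk_criteria: RiskCriteria | None = None
    linked_outcome_id: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "BRNode":
        if not self.node_id:
            raise ValueError("node_id must be non-empty")
        if self.risk_criteria is not None and self.side != Side.risk:
            raise ValueError(
                f"node {self.node_id!r}: risk_criteria only allowed on risk nodes"
            )
        return self


class ValueTree(BaseModel):
    """Ordered benefits and risks under a title."""

    title: str = ""
    benefits: list[BRNode] = []
    risks: list[BRNode] = []

    @model_validator(mode="after")
    def _check(self) -> "ValueTree":
        ids = [n.node_id for n in self.nodes()]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate node_id(s) {dupes}")
        for node in self.benefits:
            if node.side != Side.benefit:
                raise ValueError(f"node {node.node_id!r} on benefits branch has side {node.side}")
        for node in self.risks:
            if node.side != Side.risk:
                raise ValueError(f"node {node.node_id!r} on risks branch has side {node.side}")
        return self

    def nodes(self) -> list[BRNode]:
        return [*self.benefits, *self.risks]

    def node(self, node_id: str) -> BRNode:
        for n in self.nodes():
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def side_nodes(self, side: Side) -> list[BRNode]:
        return list(self.benefits if side == Side.benefit else self.risks)


class ValidationReport(BaseModel):
    errors: list[str] = []
    warnings: list[str] = []

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_tree(tree: ValueTree) -> ValidationReport:
    """Check a tree against the structural rules of a concise benefit-risk
    presentation.

    Errors: duplicate labels, an empty side. Warnings: benefit count
    outside 2-3 or risk count outside 6-8 (the recommended ceilings for
    a succinct assessment), and identical definition text on two nodes,
    which suggests double-counting of the same clinical event.
    """
    errors: list[str] = []
    warnings: list[str] = []
    labels = [n.label for n in tree.nodes()]
    for label in sorted({l for l in labels if labels.count(l) > 1}):
        errors.append(f"duplicate label {label!r}; nodes must be mutually exclusive")
    if not tree.benefits:
        errors.append("no Key Clinical Benefits defined")
    if not tree.risks:
        errors.append("no Key Safety Risks defined")
    nb, nr = len(tree.benefits), len(tree.risks)
    if tree.benefits and not BENEFIT_RANGE[0] <= nb <= BENEFIT_RANGE[1]:
        warnings.append(
            f"{nb} Key Clinical Benefits; guidance is no more than "
            f"{BENEFIT_RANGE[0]}-{BENEFIT_RANGE[1]}"
        )
    if tree.risks and not RISK_RANGE[0] <= nr <= RISK_RANGE[1]:
        warnings.append(
            f"{nr} Key Safety Risks; guidance is no more than "
            f"{RISK_RANGE[0]}-{RISK_RANGE[1]}"
        )
    seen_defs: dict[str, str] = {}
    for node in tree.nodes():
        text = node.definition.strip().lower()
        if not text:
            continue
        if text in seen_defs:
            warnings.append(
                f"nodes {seen_defs[text]!r} and {node.node_id!r} share identical "
                "definition text: possible double-counting"
            )
        else:
            seen_defs[text] = node.node_id
    return ValidationReport(errors=errors, warnings=warnings)


class WeightSet(BaseModel):
    """Node weights, either ordinal ranks or anchor-100 cardinal scores.

    Ordinal ranks are a permutation of 1..k within each side. Anchor-100
    weights lie in (0, 100] with exactly one node — a benefit, the single
    most important one — at 100.
    """

    mode: str  # "ordinal" | "anchor100"
    weights: dict[str, float]

    def validate_against(self, tree: ValueTree) -> None:
        tree_ids = {n.node_id for n in tree.nodes()}
        unknown = sorted(set(self.weights) - tree_ids)
        if unknown:
            raise ValidationError(f"weights reference unknown node(s) {unknown}")
        if self.mode == "ordinal":
            for side in Side:
                ranks = sorted(
                    int(self.weights[n.node_id])
                    for n in tree.side_nodes(side)
                    if n.node_id in self.weights
                )
                expected = list(range(1, len(ranks) + 1))
                if ranks != expected:
                    raise ValidationError(
                        f"{side.value} ranks {ranks} are not a permutation of 1..{len(ranks)}"
                    )
        elif self.mode == "anchor100":
            anchors = [nid for nid, w in self.weights.items() if w == 100.0]
            if len(anchors) != 1:
                raise ValidationError(
                    f"anchor-100 weights need exactly one node at 100, got {sorted(anchors)}"
                )
            if tree.node(anchors[0]).side != Side.benefit:
                raise ValidationError(
                    f"anchor node {anchors[0]!r} must be a Key Clinical Benefit"
                )
            bad = sorted(nid for nid, w in self.weights.items() if not 0 < w <= 100)
            if bad:
                raise ValidationError(f"weights outside (0, 100] for node(s) {bad}")
        else:
            raise ValidationError(f"unknown weight mode {self.mode!r}")

    def ordered_nodes(self, tree: ValueTree, side: Side) -> list[BRNode]:
        """Side nodes rearranged by weight: rank ascending, or cardinal
        weight non-increasing. Unweighted nodes keep tree order at the end."""
        nodes = tree.side_nodes(side)
        weighted = [n for n in nodes if n.node_id in self.weights]
        rest = [n for n in nodes if n.node_id not in self.weights]
        if self.mode == "ordinal":
            weighted.sort(key=lambda n: self.weights[n.node_id])
        else:
            weighted.sort(key=lambda n: -self.weights[n.node_id])
        return weighted + rest

    def to_json_obj(self) -> dict[str, Any]:
        return {"mode": self.mode, "weights": dict(self.weights)}


def ordinal_weighting(tree: ValueTree, ranks: Mapping[str, int]) -> WeightSet:
    """Build an ordinal WeightSet (1 = most important, within each side)."""
    ws = WeightSet(mode="ordinal", weights={k: float(v) for k, v in ranks.items()})
    for side in Side:
        missing = [n.node_id for n in tree.side_nodes(side) if n.node_id not in ranks]
        if missing:
            raise ValidationError(f"missing rank(s) for {side.value} node(s) {missing}")
    ws.validate_against(tree)
    return ws


class DelphiPanel(BaseModel):
    """Raw multi-rater anchor-100 elicitation data.

    ``rounds`` is a list (round 1 first) of {rater_id: {node_id: weight}}.
    ``anchor_id`` names the benefit every rater must hold at exactly 100.
    ``convergence_threshold`` is the maximum acceptable inter-rater range
    (max - min) per node, in anchor-100 points.
    """

    rounds: list[dict[str, dict[str, float]]]
    anchor_id: str
    convergence_threshold: float = 20.0


class ConvergenceReport(BaseModel):
    per_node_range: dict[str, float]
    threshold: float
    converged: dict[str, bool]

    @property
    def all_converged(self) -> bool:
        return all(self.converged.values())


def delphi_aggregate(panel: DelphiPanel) -> tuple[WeightSet, ConvergenceReport]:
    """Aggregate the final Delphi round into a consensus anchor-100 WeightSet.

    The consensus weight for each node is the median across raters of the
    final round; the anchor is checked to be exactly 100 for every rater
    and is exactly 100 in the output. Convergence (inter-rater range at
    or below the panel threshold) is reported per node, never enforced:
    whether to run another round is the facilitator's call.
    """
    if not panel.rounds:
        raise ValidationError("Delphi panel has no rounds")
    final = panel.rounds[-1]
    if not final:
        raise ValidationError("final Delphi round has no raters")
    node_ids: set[str] | None = None
    for rater, scores in final.items():
        if node_ids is None:
            node_ids = set(scores)
        elif set(scores) != node_ids:
            raise ValidationError(
                f"rater {rater!r} scored a different node set than the panel"
            )
        if panel.anchor_id not in scores:
            raise ValidationError(f"rater {rater!r} did not score anchor {panel.anchor_id!r}")
        if scores[panel.anchor_id] != 100.0:
            raise ValidationError(
                f"rater {rater!r} scored anchor {panel.anchor_id!r} as "
                f"{scores[panel.anchor_id]}, must be exactly 100"
            )
        bad = sorted(nid for nid, w in scores.items() if not 0 < w <= 100)
        if bad:
            raise ValidationError(f"rater {rater!r}: weights outside (0, 100] for {bad}")
    assert node_ids is not None
    frame = pd.DataFrame({rater: scores for rater, scores in final.items()})
    consensus = frame.median(axis=1)
    spread = frame.max(axis=1) - frame.min(axis=1)
    weights = {nid: float(consensus[nid]) for nid in sorted(node_ids)}
    weights[panel.anchor_id] = 100.0
    report = ConvergenceReport(
        per_node_range={nid: float(spread[nid]) for nid in sorted(node_ids)},
        threshold=panel.convergence_threshold,
        converged={
            nid: bool(spread[nid] <= panel.convergence_threshold) for nid in sorted(node_ids)
        },
    )
    return WeightSet(mode="anchor100", weights=weights), report


def normalize_weights(ws: WeightSet) -> dict[str, float]:
    """Anchor-100 weights rescaled to sum to 1 (the MCDA input scale)."""
    if ws.mode != "anchor100":
        raise ValidationError("ordinal weights are not cardinal; cannot normalize")
    total = sum(ws.weights.values())
    if total <= 0:
        raise ValidationError("weights sum to zero")
    return {nid: w / total for nid, w in ws.weights.items()}


# ---------------------------------------------------------------------------
# serialization & rendering

def _node_to_obj(node: BRNode) -> dict[str, Any]:
    obj: dict[str, Any] = {
        "node_id": node.node_id,
        "label": node.label,
        "definition": node.definition,
        "linked_outcome_id": node.linked_outcome_id,
    }
    if node.risk_criteria is not None:
        obj["risk_criteria"] = node.risk_criteria.model_dump()
    return obj


def write_tree(tree: ValueTree, path: str | Path) -> None:
    obj = {
        "title": tree.title,
        "benefits": [_node_to_obj(n) for n in tree.benefits],
        "risks": [_node_to_obj(n) for n in tree.risks],
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_tree(path: str | Path) -> ValueTree:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("benefits", "risks"):
        if key not in obj:
            raise SchemaError(f"{path}: missing key {key!r}")
    try:
        benefits = [BRNode(side=Side.benefit, **n) for n in obj["benefits"]]
        risks = [
            BRNode(
                side=Side.risk,
                risk_criteria=(RiskCriteria(**n["risk_criteria"])
                               if n.get("risk_criteria") else None),
                **{k: v for k, v in n.items() if k != "risk_criteria"},
            )
            for n in obj["risks"]
        ]
        return ValueTree(title=obj.get("title", ""), benefits=benefits, risks=risks)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_delphi_csv(path: str | Path, anchor_id: str,
                    convergence_threshold: float = 20.0) -> DelphiPanel:
    """Read elicitation data with columns round,rater_id,node_id,weight."""
    try:
        frame = pd.read_csv(path, dtype={"rater_id": str, "node_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in ("round", "rater_id", "node_id", "weight") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    rounds = []
    for _, sub in frame.groupby("round", sort=True):
        rnd: dict[str, dict[str, float]] = {}
        for _, row in sub.iterrows():
            rnd.setdefault(row["rater_id"], {})[row["node_id"]] = float(row["weight"])
        rounds.append(rnd)
    return DelphiPanel(rounds=rounds, anchor_id=anchor_id,
                       convergence_threshold=convergence_threshold)


def _ordered_sides(tree: ValueTree, ws: WeightSet | None) -> list[tuple[str, list[BRNode]]]:
    if ws is None:
        return [("Key Clinical Benefits", tree.benefits),
                ("Key Safety Risks", tree.risks)]
    return [("Key Clinical Benefits", ws.ordered_nodes(tree, Side.benefit)),
            ("Key Safety Risks", ws.ordered_nodes(tree, Side.risk))]


def _weight_tag(node: BRNode, ws: WeightSet | None) -> str:
    if ws is None or node.node_id not in ws.weights:
        return ""
    w = ws.weights[node.node_id]
    return f" [rank {int(w)}]" if ws.mode == "ordinal" else f" [{w:g}]"


def render_tree_text(tree: ValueTree, ws: WeightSet | None = None) -> str:
    """Indented-text rendering; with a WeightSet the tree is rearranged by
    weight (the weighted value tree display)."""
    lines = [tree.title or "Value tree"]
    for heading, nodes in _ordered_sides(tree, ws):
        lines.append(f"  {heading}")
        for node in nodes:
            lines.append(f"    - {node.label}{_weight_tag(node, ws)}")
    return "\n".join(lines) + "\n"


def render_tree_dot(tree: ValueTree, ws: WeightSet | None = None) -> str:
    """Graphviz dot source for the (optionally weighted) value tree."""
    def q(s: str) -> str:
        return '"' + s.replace('"', r'\"') + '"'

    lines = ["digraph value_tree {", "  rankdir=LR;", f"  root [label={q(tree.title or 'BR')}];"]
    for heading, nodes in _ordered_sides(tree, ws):
        hid = "benefits" if "Benefit" in heading else "risks"
        lines.append(f"  {hid} [label={q(heading)}];")
        lines.append(f"  root -> {hid};")
        for node in nodes:
            label = f"{node.label}{_weight_tag(node, ws)}"
            lines.append(f"  {q(node.node_id)} [label={q(label)}, shape=box];")
            lines.append(f"  {hid} -> {q(node.node_id)};")
    lines.append("}")
    return "\n".join(lines) + "\n"
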
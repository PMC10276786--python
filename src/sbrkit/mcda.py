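"""Fully quantitative net clinical benefit by multi-criteria decision
analysis (MCDA).

Each Key Clinical Benefit and Key Safety Risk contributes
``value = normalized weight x frequency`` per arm, where the weight is
the node's relative medical importance on the anchor-100 scale
(normalized to sum to one across all scored nodes) and the frequency is
the observed or estimated event proportion in that arm. Benefits add,
risks subtract: an arm's net clinical benefit is the benefit total minus
the risk total, and the decision quantity is the between-arm difference
of nets. The treatment is favorable when that difference is positive.

Weights are preference judgments, not data, so the sensitivity analysis
perturbs them: each draw multiplies every non-anchor weight by an
independent uniform factor in [1-h, 1+h], re-normalizes and re-scores.
The fraction of draws whose favorability verdict matches the baseline
(``sign_stability``) summarizes how robust the conclusion is to the
weighting exercise.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .errors import SchemaError, ValidationError
from .value_tree import Side, ValueTree, WeightSet, normalize_weights

__all__ = [
    "ArmFrequency",
    "FrequencyTable",
    "MCDAResult",
    "SensitivityReport",
    "mcda_score",
    "mcda_sensitivity",
    "mcda_chart_data",
    "read_frequency_csv",
    "write_frequency_csv",
]

ARMS = ("treatment", "comparator")


class ArmFrequency(BaseModel):
    """Event proportion for one node in both arms, flagged by provenance."""

    treatment: float
    comparator: float
    provenance: str = "observed"  # "observed" | "estimated"


class FrequencyTable(BaseModel):
    """node_id -> per-arm frequencies in [0, 1]."""

    entries: dict[str, ArmFrequency]

    def validate_against(self, tree: ValueTree) -> None:
        for node in tree.nodes():
            if node.node_id not in self.entries:
                raise ValidationError(f"no frequency entry for node {node.node_id!r}")
        for nid, entry in self.entries.items():
            for arm in ARMS:
                f = getattr(entry, arm)
                if not 0.0 <= f <= 1.0:
                    raise ValidationError(
                        f"frequency for node {nid!r}, arm {arm}: {f} outside [0, 1]"
                    )
            if entry.provenance not in ("observed", "estimated"):
                raise ValidationError(
                    f"node {nid!r}: provenance must be 'observed' or 'estimated'"
                )


class MCDAResult(BaseModel):
    """Per-node contributions, per-arm totals and the net difference."""

    contributions: dict[str, dict[str, float]]  # node_id -> arm -> weight*freq
    benefit_total: dict[str, float]
    risk_total: dict[str, float]
    net: dict[str, float]
    net_difference: float
    favorable: bool
    normalized_weights: dict[str, float]
    node_sides: dict[str, str]

    def to_json_obj(self) -> dict[str, Any]:
        return self.model_dump()


def mcda_score(tree: ValueTree, ws: WeightSet, freq: FrequencyTable) -> MCDAResult:
    """Score the tree: contribution(node, arm) = normalized weight x frequency.

    Deterministic; additive by construction (totals are exact sums of
    contributions). Raises if any tree node lacks a frequency entry or
    the weight set is not anchor-100.
    """
    ws.validate_against(tree)
    freq.validate_against(tree)
    norm = normalize_weights(ws)
    missing = [n.node_id for n in tree.nodes() if n.node_id not in norm]
    if missing:
        raise ValidationError(f"no weight for node(s) {missing}")
    contributions: dict[str, dict[str, float]] = {}
    benefit_total = {arm: 0.0 for arm in ARMS}
    risk_total = {arm: 0.0 for arm in ARMS}
    for node in tree.nodes():
        entry = freq.entries[node.node_id]
        contributions[node.node_id] = {
            arm: norm[node.node_id] * getattr(entry, arm) for arm in ARMS
        }
        bucket = benefit_total if node.side == Side.benefit else risk_total
        for arm in ARMS:
            bucket[arm] += contributions[node.node_id][arm]
    net = {arm: benefit_total[arm] - risk_total[arm] for arm in ARMS}
    net_difference = net["treatment"] - net["comparator"]
    return MCDAResult(
        contributions=contributions,
        benefit_total=benefit_total,
        risk_total=risk_total,
        net=net,
        net_difference=net_difference,
        favorable=net_difference > 0,
        normalized_weights=norm,
        node_sides={n.node_id: n.side.value for n in tree.nodes()},
    )


class SensitivityReport(BaseModel):
    n_draws: int
    perturbation: float
    scheme: str
    sign_stability: float
    baseline_favorable: bool
    net_difference_range: tuple[float, float]
    weight_range_explored: dict[str, tuple[float, float]]

    def to_json_obj(self) -> dict[str, Any]:
        return self.model_dump()


def mcda_sensitivity(
    tree: ValueTree,
    ws: WeightSet,
    freq: FrequencyTable,
    perturbation: float = 0.2,
    n_draws: int = 1000,
    seed: int = 0,
) -> SensitivityReport:
    """Weight-perturbation sensitivity of the favorability verdict.

    Each draw multiplies each non-anchor raw weight by an independent
    uniform factor in [1-h, 1+h] (h = ``perturbation``), clips into
    (0, 100] to preserve the anchor-100 semantics, re-normalizes and
    re-scores. ``sign_stability`` is the fraction of draws whose
    favorability equals the baseline verdict. Reproducible for a fixed
    seed.
    """
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    if perturbation < 0:
        raise ValidationError(f"perturbation must be >= 0, got {perturbation}")
    baseline = mcda_score(tree, ws, freq)
    anchor = [nid for nid, w in ws.weights.items() if w == 100.0][0]
    others = [nid for nid in ws.weights if nid != anchor]
    rng = np.random.default_rng(seed)
    stable = 0
    nets = np.empty(n_draws)
    explored = {nid: [ws.weights[nid], ws.weights[nid]] for nid in ws.weights}
    for i in range(n_draws):
        factors = rng.uniform(1 - perturbation, 1 + perturbation, size=len(others))
        weights = dict(ws.weights)
        for nid, f in zip(others, factors):
            weights[nid] = float(np.clip(ws.weights[nid] * f, 1e-9, 100.0))
            explored[nid][0] = min(explored[nid][0], weights[nid])
            explored[nid][1] = max(explored[nid][1], weights[nid])
        drawn = WeightSet(mode="anchor100", weights=weights)
        result = mcda_score(tree, drawn, freq)
        nets[i] = result.net_difference
        stable += result.favorable == baseline.favorable
    return SensitivityReport(
        n_draws=n_draws,
        perturbation=perturbation,
        scheme="multiplicative uniform [1-h, 1+h] on non-anchor weights, re-normalized",
        sign_stability=stable / n_draws,
        baseline_favorable=baseline.favorable,
        net_difference_range=(float(nets.min()), float(nets.max())),
        weight_range_explored={nid: (lo, hi) for nid, (lo, hi) in explored.items()},
    )


def mcda_chart_data(result: MCDAResult) -> list[dict[str, Any]]:
    """Bar/waterfall records: signed between-arm contribution differences.

    One record per node, value +w(f_t - f_c) for benefits and
    -w(f_t - f_c) for risks, so the records sum exactly to the net
    difference. Ordered benefits first then risks, each side by
    descending magnitude (ties broken by node_id for a canonical order).
    """
    records = []
    for nid, contrib in result.contributions.items():
        side = result.node_sides[nid]
        sign = 1.0 if side == "benefit" else -1.0
        value = sign * (contrib["treatment"] - contrib["comparator"])
        records.append({"node_id": nid, "side": side, "value": value})
    records.sort(key=lambda r: (r["side"] != "benefit", -abs(r["value"]), r["node_id"]))
    return records


def read_frequency_csv(path: str | Path) -> FrequencyTable:
    """Read a frequency table with columns node_id,arm,frequency,provenance."""
    try:
        frame = pd.read_csv(path, dtype={"node_id": str, "arm": str, "provenance": str},
                            float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in ("node_id", "arm", "frequency") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if "provenance" not in frame.columns:
        frame["provenance"] = "observed"
    entries: dict[str, dict[str, Any]] = {}
    for _, row in frame.iterrows():
        if row["arm"] not in ARMS:
            raise ValidationError(f"unknown arm {row['arm']!r} for node {row['node_id']!r}")
        slot = entries.setdefault(row["node_id"], {"provenance": row["provenance"]})
        slot[row["arm"]] = float(row["frequency"])
    table = {}
    for nid, slot in entries.items():
        for arm in ARMS:
            if arm not in slot:
                raise ValidationError(f"node {nid!r}: missing {arm} frequency")
        table[nid] = ArmFrequency(**slot)
    ft = FrequencyTable(entries=table)
    for nid, entry in ft.entries.items():
        for arm in ARMS:
            if not 0.0 <= getattr(entry, arm) <= 1.0:
                raise ValidationError(
                    f"frequency for node {nid!r}, arm {arm} outside [0, 1]"
                )
    return ft


def write_frequency_csv(freq: FrequencyTable, path: str | Path) -> None:
    rows = []
    for nid, entry in freq.entries.items():
        for arm in ARMS:
            rows.append(
                {
                    "node_id": nid,
                    "arm": arm,
                    "frequency": getattr(entry, arm),
                    "provenance": entry.provenance,
                }
            )
    pd.DataFrame(rows, columns=["node_id", "arm", "frequency", "provenance"]).to_csv(
        path, index=False
    )


def chart_data_to_csv(records: list[dict[str, Any]], path: str | Path) -> None:
    pd.DataFrame(records, columns=["node_id", "side", "value"]).to_csv(path, index=False)


def result_to_json(result: MCDAResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_json_obj(), indent=2) + "\n")
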
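"""Two-arm binary outcome data: types, file I/O and a trial simulator.

The statistical atom of the toolkit is a two-arm comparison for one
outcome: event counts ``n`` of ``N`` in a treatment arm and a comparator
arm, tagged with the outcome's direction (favorable for clinical
benefits, unfavorable for safety risks). Datasets are read and written
as CSV (long format, one row per arm) or JSON (one object per
comparison), and a seeded binomial simulator produces synthetic trials
of the same shape for testing and calibration work.

Designs with more than two arms are rejected: every downstream statistic
(risk difference, NNT/NNH, risk ratio, MCDA frequency contrast) is
pairwise, treatment versus comparator.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import SchemaError, ValidationError

__all__ = [
    "Direction",
    "OutcomeCount",
    "TwoArmComparison",
    "TrialDataset",
    "read_counts",
    "write_counts",
    "simulate_trial",
]

CSV_COLUMNS = ["outcome_id", "direction", "arm", "events", "total"]
ARM_LABELS = ("treatment", "comparator")


class Direction(str, Enum):
    """Whether more events are good (favorable) or bad (unfavorable)."""

    favorable = "favorable"
    unfavorable = "unfavorable"


class OutcomeCount(BaseModel):
    """Event count for one outcome in one arm: ``events`` of ``total``."""

    model_config = ConfigDict(frozen=True)

    events: int
    total: int
    arm_label: str = ""

    @model_validator(mode="after")
    def _check_counts(self) -> "OutcomeCount":
        if self.total < 1:
            raise ValueError(f"total must be >= 1, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise ValueError(
                f"events must satisfy 0 <= events <= total, "
                f"got events={self.events}, total={self.total}"
            )
        return self

    @property
    def proportion(self) -> float:
        """Observed event proportion; always derived from counts."""
        return self.events / self.total


class TwoArmComparison(BaseModel):
    """One outcome contrasted between a treatment and a comparator arm."""

    model_config = ConfigDict(frozen=True)

    outcome_id: str
    treatment: OutcomeCount
    comparator: OutcomeCount
    direction: Direction

    @model_validator(mode="after")
    def _check_id(self) -> "TwoArmComparison":
        if not self.outcome_id:
            raise ValueError("outcome_id must be non-empty")
        return self

    def swapped(self) -> "TwoArmComparison":
        """Return the comparison with the arms exchanged."""
        return TwoArmComparison(
            outcome_id=self.outcome_id,
            treatment=self.comparator,
            comparator=self.treatment,
            direction=self.direction,
        )


class TrialDataset(BaseModel):
    """Ordered collection of comparisons with free-form study metadata."""

    comparisons: list[TwoArmComparison] = []
    metadata: dict[str, str] = {}

    @model_validator(mode="after")
    def _check_unique_ids(self) -> "TrialDataset":
        seen: set[str] = set()
        for cmp_ in self.comparisons:
            if cmp_.outcome_id in seen:
                raise ValueError(f"duplicate outcome_id {cmp_.outcome_id!r}")
            seen.add(cmp_.outcome_id)
        return self

    def __iter__(self) -> Iterator[TwoArmComparison]:  # type: ignore[override]
        return iter(self.comparisons)

    def __len__(self) -> int:
        return len(self.comparisons)

    def get(self, outcome_id: str) -> TwoArmComparison:
        for cmp_ in self.comparisons:
            if cmp_.outcome_id == outcome_id:
                return cmp_
        raise KeyError(outcome_id)

    def __contains__(self, outcome_id: object) -> bool:
        return any(c.outcome_id == outcome_id for c in self.comparisons)


def _comparison_from_arm_rows(outcome_id: str, rows: pd.DataFrame) -> TwoArmComparison:
    if len(rows) != 2 or set(rows["arm"]) != set(ARM_LABELS):
        raise ValidationError(
            f"outcome {outcome_id!r} must have exactly one 'treatment' and one "
            f"'comparator' row, got arms {sorted(rows['arm'])}"
        )
    directions = set(rows["direction"])
    if len(directions) != 1:
        raise ValidationError(
            f"outcome {outcome_id!r} has inconsistent directions {sorted(directions)}"
        )
    by_arm = {}
    for _, row in rows.iterrows():
        try:
            by_arm[row["arm"]] = OutcomeCount(
                events=int(row["events"]), total=int(row["total"]), arm_label=row["arm"]
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"invalid counts for outcome {outcome_id!r}, arm {row['arm']!r}: {exc}"
            ) from exc
    try:
        direction = Direction(directions.pop())
    except ValueError as exc:
        raise ValidationError(f"outcome {outcome_id!r}: {exc}") from exc
    return TwoArmComparison(
        outcome_id=outcome_id,
        treatment=by_arm["treatment"],
        comparator=by_arm["comparator"],
        direction=direction,
    )


def _dataset_from_json_obj(obj: object) -> TrialDataset:
    if isinstance(obj, Mapping):
        records = obj.get("comparisons")
        metadata = {str(k): str(v) for k, v in obj.get("metadata", {}).items()}
    else:
        records, metadata = obj, {}
    if not isinstance(records, Sequence):
        raise SchemaError("counts JSON must be a list of comparisons or "
                          "an object with a 'comparisons' list")
    comparisons = []
    for i, rec in enumerate(records):
        for key in ("outcome_id", "direction", "treatment", "comparator"):
            if key not in rec:
                raise SchemaError(f"comparison #{i}: missing key {key!r}")
        try:
            comparisons.append(
                TwoArmComparison(
                    outcome_id=rec["outcome_id"],
                    direction=rec["direction"],
                    treatment=OutcomeCount(**rec["treatment"], arm_label="treatment"),
                    comparator=OutcomeCount(**rec["comparator"], arm_label="comparator"),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"comparison #{i} ({rec.get('outcome_id')!r}): {exc}") from exc
    try:
        return TrialDataset(comparisons=comparisons, metadata=metadata)
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def read_counts(path: str | Path, format: str | None = None) -> TrialDataset:
    """Read a two-arm counts dataset from CSV or JSON.

    CSV schema: ``outcome_id,direction,arm,events,total`` with
    ``arm`` in {treatment, comparator} and exactly two rows per outcome.
    JSON schema: list of ``{outcome_id, direction, treatment:{events,total},
    comparator:{events,total}}``, optionally wrapped with metadata.
    Row/record order is preserved. ``format`` defaults from the file suffix.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
        return _dataset_from_json_obj(obj)
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    try:
        frame = pd.read_csv(path, dtype={"outcome_id": str, "direction": str, "arm": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header row") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    comparisons = []
    # groupby would reorder; iterate in first-appearance order instead
    for outcome_id in frame["outcome_id"].drop_duplicates():
        rows = frame[frame["outcome_id"] == outcome_id]
        comparisons.append(_comparison_from_arm_rows(str(outcome_id), rows))
    try:
        return TrialDataset(comparisons=comparisons)
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def write_counts(ds: TrialDataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset so that :func:`read_counts` round-trips it exactly."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = {
            "comparisons": [
                {
                    "outcome_id": c.outcome_id,
                    "direction": c.direction.value,
                    "treatment": {"events": c.treatment.events, "total": c.treatment.total},
                    "comparator": {"events": c.comparator.events, "total": c.comparator.total},
                }
                for c in ds.comparisons
            ],
            "metadata": ds.metadata,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    rows = []
    for c in ds.comparisons:
        for arm, count in (("treatment", c.treatment), ("comparator", c.comparator)):
            rows.append(
                {
                    "outcome_id": c.outcome_id,
                    "direction": c.direction.value,
                    "arm": arm,
                    "events": count.events,
                    "total": count.total,
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def simulate_trial(
    spec: Mapping[str, tuple[float, float]] | Mapping[str, Mapping[str, float]],
    n_treatment: int,
    n_comparator: int,
    seed: int,
    directions: Mapping[str, Direction | str] | None = None,
) -> TrialDataset:
    """Simulate a two-arm trial with independent binomial outcome counts.

    ``spec`` maps each outcome id to its true event rates
    ``(rate_treatment, rate_comparator)``. Events are drawn independently
    per arm and outcome from ``Binomial(N, rate)`` using one seeded
    generator per call, so identical ``seed`` + ``spec`` reproduce the
    dataset exactly. ``directions`` defaults every outcome to favorable.
    """
    if n_treatment < 1 or n_comparator < 1:
        raise ValidationError("per-arm sample sizes must be >= 1")
    directions = directions or {}
    rng = np.random.default_rng(seed)
    comparisons = []
    for outcome_id, rates in spec.items():
        p_t, p_c = (float(r) for r in rates)
        for p in (p_t, p_c):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"outcome {outcome_id!r}: rate {p} outside [0, 1]"
                )
        events_t = int(rng.binomial(n_treatment, p_t))
        events_c = int(rng.binomial(n_comparator, p_c))
        comparisons.append(
            TwoArmComparison(
                outcome_id=outcome_id,
                treatment=OutcomeCount(events=events_t, total=n_treatment,
                                       arm_label="treatment"),
                comparator=OutcomeCount(events=events_c, total=n_comparator,
                                        arm_label="comparator"),
                direction=Direction(directions.get(outcome_id, Direction.favorable)),
            )
        )
    return TrialDataset(comparisons=comparisons, metadata={"simulated": "true", "seed": str(seed)})
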
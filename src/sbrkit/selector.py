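"""Milestone- and complexity-driven recommendation of the sBR methodology.

The framework progresses from descriptive displays early in development
to semi-quantitative and, where warranted, fully quantitative analyses
at submission: a context table at first-time-in-human, value trees with
weighting at Phase IIb, an effects table (or weighted value tree
fallback) at Phase III, and at submission either the semi-quantitative
base case (effects table / forest plot) or NNT/MCDA for complex or
borderline profiles. The rule table lives in an editable YAML file so
organizations can refine the mapping; the shipped file encodes only the
textually stated recommendations.
"""

from __future__ import annotations

from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict

from .errors import SchemaError, ValidationError

__all__ = [
    "Milestone",
    "DataMaturity",
    "BRComplexity",
    "ProjectState",
    "BRCategory",
    "MethodRecommendation",
    "METHOD_CATEGORY",
    "load_rules",
    "recommend",
]


class Milestone(str, Enum):
    ftih = "ftih"
    phase2b = "phase2b"
    phase3 = "phase3"
    submission = "submission"


class DataMaturity(str, Enum):
    minimal = "minimal"
    emerging = "emerging"
    pivotal = "pivotal"


class BRComplexity(str, Enum):
    straightforward = "straightforward"
    complex_or_borderline = "complex_or_borderline"


class BRCategory(str, Enum):
    descriptive = "descriptive"
    semi_quantitative = "semi_quantitative"
    fully_quantitative = "fully_quantitative"


#: Methodology -> the analysis category it belongs to.
METHOD_CATEGORY: dict[str, BRCategory] = {
    "context_table": BRCategory.descriptive,
    "value_tree": BRCategory.descriptive,
    "weighted_value_tree": BRCategory.descriptive,
    "effects_table": BRCategory.semi_quantitative,
    "forest_plot": BRCategory.semi_quantitative,
    "nnt_nnh": BRCategory.fully_quantitative,
    "mcda": BRCategory.fully_quantitative,
}


class ProjectState(BaseModel):
    model_config = ConfigDict(frozen=True)

    milestone: Milestone
    data_maturity: DataMaturity
    br_complexity: BRComplexity
    accelerated: bool = False


class MethodRecommendation(BaseModel):
    primary_methods: list[str]
    br_category: BRCategory
    rationale: str


def load_rules(path: str | Path | None = None) -> list[dict[str, Any]]:
    """Load the rule table (shipped default, or a user-supplied YAML)."""
    if path is None:
        text = (resources.files("sbrkit") / "data" / "selector_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    obj = yaml.safe_load(text)
    if not isinstance(obj, Mapping) or "rules" not in obj:
        raise SchemaError("rules YAML must contain a top-level 'rules' list")
    rules = obj["rules"]
    for i, rule in enumerate(rules):
        for key in ("when", "recommend", "category", "rationale"):
            if key not in rule:
                raise SchemaError(f"rule #{i}: missing key {key!r}")
        for method in rule["recommend"]:
            if method not in METHOD_CATEGORY:
                raise SchemaError(f"rule #{i}: unknown methodology {method!r}")
        categories = {METHOD_CATEGORY[m] for m in rule["recommend"]}
        if categories != {BRCategory(rule["category"])}:
            raise SchemaError(
                f"rule #{i}: category {rule['category']!r} inconsistent with "
                f"methods {rule['recommend']}"
            )
    return list(rules)


def _matches(when: Mapping[str, str], state: ProjectState) -> bool:
    for key, value in when.items():
        if getattr(state, key).value != value:
            return False
    return True


def recommend(
    state: ProjectState, rules: list[dict[str, Any]] | None = None
) -> MethodRecommendation:
    """Deterministic first-match lookup in the rule table.

    Every project state maps to a recommendation (the shipped rule file
    is total over the state space). For accelerated programs a note is
    appended: milestone boundaries blur on accelerated timelines, so the
    milestone mapping is advisory rather than prescriptive.
    """
    rules = rules if rules is not None else load_rules()
    for rule in rules:
        if _matches(rule["when"], state):
            rationale = str(rule["rationale"]).strip()
            if state.accelerated:
                rationale += (
                    " Note: accelerated development timeline — phase-milestone "
                    "distinctions may be blurred, so this milestone-based "
                    "recommendation is advisory."
                )
            return MethodRecommendation(
                primary_methods=list(rule["recommend"]),
                br_category=BRCategory(rule["category"]),
                rationale=rationale,
            )
    raise ValidationError(f"no rule matches project state {state}")
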
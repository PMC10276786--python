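import pytest

from sbrkit.trial_data import (
    Direction,
    OutcomeCount,
    TrialDataset,
    TwoArmComparison,
)
from sbrkit.value_tree import BRNode, Side, ValueTree, WeightSet


def make_comparison(x_t, n_t, x_c, n_c, direction="favorable", outcome_id="outcome"):
    return TwoArmComparison(
        outcome_id=outcome_id,
        direction=Direction(direction),
        treatment=OutcomeCount(events=x_t, total=n_t, arm_label="treatment"),
        comparator=OutcomeCount(events=x_c, total=n_c, arm_label="comparator"),
    )


@pytest.fixture
def response_cmp():
    """Published worked example, efficacy row: 143/177 vs 226/342."""
    return make_comparison(143, 177, 226, 342, "favorable", "response_rate")


@pytest.fixture
def discontinuation_cmp():
    """Published worked example, safety row: 7/206 vs 10/432."""
    return make_comparison(7, 206, 10, 432, "unfavorable", "discontinuation_ae")


@pytest.fixture
def worked_dataset(response_cmp, discontinuation_cmp):
    return TrialDataset(
        comparisons=[response_cmp, discontinuation_cmp],
        metadata={"study": "drug X vs placebo"},
    )


@pytest.fixture
def small_tree():
    """2 benefits / 6 risks: within the recommended cardinality bands."""
    benefits = [
        BRNode(node_id="resp", label="Response rate", side=Side.benefit,
               definition="Proportion achieving clinical response",
               linked_outcome_id="response_rate"),
        BRNode(node_id="qol", label="Quality of life", side=Side.benefit,
               definition="Patient-reported quality of life improvement"),
    ]
    risks = [
        BRNode(node_id="disc", label="Discontinuation due to AEs", side=Side.risk,
               definition="Treatment discontinuation attributed to adverse events",
               linked_outcome_id="discontinuation_ae"),
    ] + [
        BRNode(node_id=f"risk{i}", label=f"Safety risk {i}", side=Side.risk,
               definition=f"Definition of safety risk {i}")
        for i in range(1, 6)
    ]
    return ValueTree(title="Drug X benefit-risk", benefits=benefits, risks=risks)


@pytest.fixture
def anchor_weights(small_tree):
    weights = {"resp": 100.0, "qol": 60.0, "disc": 40.0}
    weights.update({f"risk{i}": 10.0 * i for i in range(1, 6)})
    return WeightSet(mode="anchor100", weights=weights)
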
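import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

# fixtures used inside @given are frozen pydantic models, never mutated,
# so sharing them across generated examples is safe
FIXTURE_SETTINGS = dict(
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)

from sbrkit.errors import ValidationError
from sbrkit.mcda import (
    ArmFrequency,
    FrequencyTable,
    mcda_chart_data,
    mcda_score,
    mcda_sensitivity,
    read_frequency_csv,
    write_frequency_csv,
)
from sbrkit.value_tree import BRNode, Side, ValueTree, WeightSet


@pytest.fixture
def two_node_tree():
    return ValueTree(
        title="minimal",
        benefits=[BRNode(node_id="b", label="Benefit", side=Side.benefit)],
        risks=[BRNode(node_id="r", label="Risk", side=Side.risk)],
    )


@pytest.fixture
def two_node_weights():
    return WeightSet(mode="anchor100", weights={"b": 100.0, "r": 20.0})


@pytest.fixture
def two_node_freq():
    return FrequencyTable(entries={
        "b": ArmFrequency(treatment=0.5, comparator=0.0),
        "r": ArmFrequency(treatment=0.1, comparator=0.0),
    })


def freq_for(tree, treatment, comparator):
    return FrequencyTable(entries={
        n.node_id: ArmFrequency(treatment=treatment[n.node_id],
                                comparator=comparator[n.node_id])
        for n in tree.nodes()
    })


class TestScore:
    def test_hand_arithmetic_example(self, two_node_tree, two_node_weights, two_node_freq):
        """weights (100, 20) normalize to (5/6, 1/6); with treatment freqs
        (0.5, 0.1) and a zero comparator, net(treatment) = 5/6*0.5 - 1/6*0.1."""
        res = mcda_score(two_node_tree, two_node_weights, two_node_freq)
        assert res.normalized_weights == pytest.approx({"b": 5 / 6, "r": 1 / 6})
        assert res.net["treatment"] == pytest.approx(5 / 6 * 0.5 - 1 / 6 * 0.1, abs=1e-15)
        assert res.net["comparator"] == 0.0
        assert res.net_difference == pytest.approx(0.4, abs=1e-12)
        assert res.favorable

    def test_equal_arms_not_favorable(self, two_node_tree, two_node_weights):
        freq = freq_for(two_node_tree, {"b": 0.3, "r": 0.1}, {"b": 0.3, "r": 0.1})
        res = mcda_score(two_node_tree, two_node_weights, freq)
        assert res.net_difference == 0.0
        assert not res.favorable

    @settings(max_examples=25, **FIXTURE_SETTINGS)
    @given(c=st.floats(0.01, 10.0))
    def test_weight_scale_invariance(self, two_node_tree, two_node_freq, c):
        """Scaling every raw weight by a common factor leaves the normalized
        weights — and hence every contribution — unchanged: only relative
        importance enters the score."""
        from sbrkit.value_tree import normalize_weights

        raw = {"b": 100.0, "r": 20.0}
        scaled = WeightSet(mode="anchor100", weights={k: c * v for k, v in raw.items()})
        base = WeightSet(mode="anchor100", weights=raw)
        n_base, n_scaled = normalize_weights(base), normalize_weights(scaled)
        for nid in raw:
            assert n_scaled[nid] == pytest.approx(n_base[nid], rel=1e-12)
        res = mcda_score(two_node_tree, base, two_node_freq)
        for nid in raw:
            for arm in ("treatment", "comparator"):
                assert res.contributions[nid][arm] == pytest.approx(
                    n_base[nid] * getattr(two_node_freq.entries[nid], arm), abs=1e-15
                )

    def test_missing_frequency_names_node(self, two_node_tree, two_node_weights):
        freq = FrequencyTable(entries={"b": ArmFrequency(treatment=0.5, comparator=0.0)})
        with pytest.raises(ValidationError, match="'r'"):
            mcda_score(two_node_tree, two_node_weights, freq)

    def test_additivity_of_totals(self, small_tree, anchor_weights):
        freq = freq_for(
            small_tree,
            {n.node_id: 0.1 * (i + 1) for i, n in enumerate(small_tree.nodes())},
            {n.node_id: 0.05 * (i + 1) for i, n in enumerate(small_tree.nodes())},
        )
        res = mcda_score(small_tree, anchor_weights, freq)
        for arm in ("treatment", "comparator"):
            b_sum = sum(res.contributions[n.node_id][arm] for n in small_tree.benefits)
            r_sum = sum(res.contributions[n.node_id][arm] for n in small_tree.risks)
            assert res.benefit_total[arm] == pytest.approx(b_sum, abs=1e-15)
            assert res.risk_total[arm] == pytest.approx(r_sum, abs=1e-15)
            assert res.net[arm] == pytest.approx(b_sum - r_sum, abs=1e-15)

    @settings(max_examples=30, **FIXTURE_SETTINGS)
    @given(c=st.floats(0.1, 1.0))
    def test_linearity_in_frequency(self, small_tree, anchor_weights, c):
        base_t = {n.node_id: 0.4 for n in small_tree.nodes()}
        base_c = {n.node_id: 0.2 for n in small_tree.nodes()}
        res1 = mcda_score(small_tree, anchor_weights, freq_for(small_tree, base_t, base_c))
        res2 = mcda_score(
            small_tree, anchor_weights,
            freq_for(small_tree, {k: c * v for k, v in base_t.items()},
                     {k: c * v for k, v in base_c.items()}),
        )
        assert res2.net_difference == pytest.approx(c * res1.net_difference, rel=1e-12)

    def test_dominant_treatment_always_favorable(self, small_tree):
        """If treatment beats comparator on every node (higher benefit
        frequencies, lower risk frequencies), every weight set agrees."""
        treatment = {n.node_id: 0.6 for n in small_tree.benefits}
        treatment |= {n.node_id: 0.05 for n in small_tree.risks}
        comparator = {n.node_id: 0.3 for n in small_tree.benefits}
        comparator |= {n.node_id: 0.2 for n in small_tree.risks}
        freq = freq_for(small_tree, treatment, comparator)
        for seed in range(20):
            import numpy as np

            rng = np.random.default_rng(seed)
            weights = {"resp": 100.0}
            for n in small_tree.nodes():
                if n.node_id != "resp":
                    weights[n.node_id] = float(rng.uniform(1, 100))
            ws = WeightSet(mode="anchor100", weights=weights)
            assert mcda_score(small_tree, ws, freq).favorable


class TestSensitivity:
    def test_zero_perturbation_fully_stable(self, two_node_tree, two_node_weights, two_node_freq):
        rep = mcda_sensitivity(two_node_tree, two_node_weights, two_node_freq,
                               perturbation=0.0, n_draws=200, seed=5)
        assert rep.sign_stability == 1.0

    def test_clear_margin_stable_under_small_h(self, two_node_tree, two_node_weights,
                                               two_node_freq):
        rep = mcda_sensitivity(two_node_tree, two_node_weights, two_node_freq,
                               perturbation=0.1, n_draws=500, seed=5)
        assert rep.sign_stability == 1.0

    def test_reproducible_and_validated(self, two_node_tree, two_node_weights, two_node_freq):
        a = mcda_sensitivity(two_node_tree, two_node_weights, two_node_freq,
                             perturbation=0.3, n_draws=100, seed=11)
        b = mcda_sensitivity(two_node_tree, two_node_weights, two_node_freq,
                             perturbation=0.3, n_draws=100, seed=11)
        assert a == b
        with pytest.raises(ValidationError):
            mcda_sensitivity(two_node_tree, two_node_weights, two_node_freq, n_draws=0)

    def test_knife_edge_matches_direct_resimulation(self, two_node_tree):
        """Baseline net difference exactly 0: stability must equal the
        fraction of draws on the baseline (non-favorable) side, recomputed
        independently with the same generator stream."""
        import numpy as np

        ws = WeightSet(mode="anchor100", weights={"b": 100.0, "r": 50.0})
        freq = FrequencyTable(entries={
            "b": ArmFrequency(treatment=0.3, comparator=0.1),
            "r": ArmFrequency(treatment=0.5, comparator=0.1),  # 100*0.2 = 50*0.4
        })
        baseline = mcda_score(two_node_tree, ws, freq)
        assert baseline.net_difference == pytest.approx(0.0, abs=1e-15)
        h, n_draws, seed = 0.5, 2000, 77
        rep = mcda_sensitivity(two_node_tree, ws, freq, perturbation=h,
                               n_draws=n_draws, seed=seed)
        rng = np.random.default_rng(seed)
        stable = 0
        for _ in range(n_draws):
            f = rng.uniform(1 - h, 1 + h, size=1)[0]
            w_r = np.clip(50.0 * f, 1e-9, 100.0)
            net_diff = (100 * 0.2 - w_r * 0.4) / (100 + w_r)
            stable += (net_diff > 0) == baseline.favorable
        assert rep.sign_stability == pytest.approx(stable / n_draws, abs=1e-12)


class TestChartData:
    def test_records_sum_to_net_difference(self, two_node_tree, two_node_weights,
                                           two_node_freq):
        res = mcda_score(two_node_tree, two_node_weights, two_node_freq)
        records = mcda_chart_data(res)
        assert sum(r["value"] for r in records) == pytest.approx(res.net_difference, abs=1e-12)
        assert [r["side"] for r in records] == ["benefit", "risk"]

    def test_canonical_ordering(self, small_tree, anchor_weights):
        freq = freq_for(
            small_tree,
            {n.node_id: 0.3 for n in small_tree.nodes()},
            {n.node_id: 0.1 for n in small_tree.nodes()},
        )
        res = mcda_score(small_tree, anchor_weights, freq)
        records = mcda_chart_data(res)
        sides = [r["side"] for r in records]
        assert sides == sorted(sides, key=lambda s: s != "benefit")
        for side in ("benefit", "risk"):
            mags = [abs(r["value"]) for r in records if r["side"] == side]
            assert mags == sorted(mags, reverse=True)

    def test_benefit_only_tree(self):
        tree = ValueTree(title="b-only",
                         benefits=[BRNode(node_id="b", label="B", side=Side.benefit)],
                         risks=[])
        ws = WeightSet(mode="anchor100", weights={"b": 100.0})
        freq = FrequencyTable(entries={"b": ArmFrequency(treatment=0.4, comparator=0.1)})
        records = mcda_chart_data(mcda_score(tree, ws, freq))
        assert len(records) == 1 and records[0]["side"] == "benefit"


def test_frequency_csv_round_trip(tmp_path, two_node_freq):
    path = tmp_path / "freq.csv"
    write_frequency_csv(two_node_freq, path)
    back = read_frequency_csv(path)
    assert back == two_node_freq
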
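"""Mamdani engine: memberships, rule activation, aggregation, centroid."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from camfuse import (
    Antecedent,
    FuzzyRule,
    Gaussian,
    LinguisticVariable,
    NoRuleFiredError,
    RuleBase,
    Trapezoidal,
    Triangular,
    aggregate,
    defuzzify_centroid,
    evaluate_rule,
    membership_degree,
)
from camfuse.fuzzy import AggregatedOutput
from oracles import membership_reference


class TestMembershipFunctions:
    def test_triangular_peak_and_feet(self):
        mf = Triangular(100, 150, 200)
        assert membership_degree(mf, 150) == 1.0
        assert membership_degree(mf, 100) == 0.0
        assert membership_degree(mf, 175) == pytest.approx(0.5)

    def test_gaussian_closed_form(self):
        mf = Gaussian(mean=15, sigma=5)
        assert membership_degree(mf, 15) == 1.0
        assert membership_degree(mf, 20) == pytest.approx(math.exp(-0.5))

    def test_trapezoid_flat_top(self):
        mf = Trapezoidal(0, 0, 150, 300)
        assert membership_degree(mf, 0) == 1.0
        assert membership_degree(mf, 150) == 1.0
        assert membership_degree(mf, 225) == pytest.approx(0.5)
        assert membership_degree(mf, 300) == 0.0

    @pytest.mark.parametrize(
        "bad",
        [
            lambda: Triangular(3, 2, 1),
            lambda: Triangular(1, 1, 1),
            lambda: Gaussian(0, 0),
            lambda: Gaussian(0, -1),
            lambda: Trapezoidal(0, 2, 1, 3),
        ],
    )
    def test_invalid_parameters_fail_at_construction(self, bad):
        with pytest.raises(ValueError):
            bad()

    @given(
        st.sampled_from(
            [
                Triangular(0, 0, 30),
                Triangular(30, 50, 70),
                Triangular(70, 100, 100),
                Gaussian(15, 5),
                Trapezoidal(0, 0, 150, 300),
                Trapezoidal(450, 600, 720, 720),
            ]
        ),
        st.floats(-1e6, 1e6, allow_nan=False),
    )
    def test_degree_always_in_unit_interval(self, mf, x):
        assert 0.0 <= membership_degree(mf, x) <= 1.0

    @given(
        st.sampled_from(
            [Triangular(10, 40, 90), Gaussian(50, 12), Trapezoidal(0, 20, 60, 100)]
        ),
        st.floats(0, 100, allow_nan=False),
    )
    def test_matches_interpolation_oracle(self, mf, x):
        assert membership_degree(mf, x) == pytest.approx(
            float(membership_reference(mf, np.array([x]))[0]), abs=1e-12
        )


def tiny_rulebase():
    """Two inputs on [0, 10], one output on [0, 100] with three sets."""
    a = LinguisticVariable("a", (0, 10), {"lo": Triangular(0, 0, 5), "hi": Triangular(5, 10, 10)})
    b = LinguisticVariable("b", (0, 10), {"lo": Triangular(0, 0, 5), "hi": Triangular(5, 10, 10)})
    out = LinguisticVariable(
        "out",
        (0, 100),
        {
            "small": Triangular(0, 0, 30),
            "mid": Triangular(30, 50, 70),
            "big": Triangular(70, 100, 100),
        },
    )
    rules = (
        FuzzyRule("r1", (Antecedent("a", "hi"),), "big"),
        FuzzyRule("r2", (Antecedent("a", "hi"), Antecedent("b", "hi", negated=True)), "mid"),
        FuzzyRule("r3", (Antecedent("b", "lo"),), "small"),
    )
    return RuleBase(rules=rules, inputs=(a, b), output=out)


class TestEvaluateRule:
    def test_min_of_degrees(self):
        rb = tiny_rulebase()
        # r2: a=10 -> hi degree 1; b=7.5 -> Not hi contributes 0.5; min = 0.5
        assert evaluate_rule(rb.rules[1], {"a": 10, "b": 7.5}, rb) == pytest.approx(0.5)
        assert evaluate_rule(rb.rules[1], {"a": 10, "b": 0}, rb) == 1.0

    def test_negated_antecedent_complements(self):
        rb = tiny_rulebase()
        # b=8.5 -> mu_hi = 0.7, Not hi contributes 0.3
        assert evaluate_rule(rb.rules[1], {"a": 10, "b": 8.5}, rb) == pytest.approx(0.3)

    def test_missing_input_named_in_error(self):
        rb = tiny_rulebase()
        with pytest.raises(KeyError, match="'b'"):
            evaluate_rule(rb.rules[1], {"a": 10}, rb)

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            FuzzyRule("bad", (), "big")
        with pytest.raises(ValueError):
            FuzzyRule("bad", (Antecedent("a", "hi"),), "big", weight=0.5)


class TestAggregate:
    def test_full_activation_reproduces_consequent(self):
        rb = tiny_rulebase()
        agg = aggregate(rb, {"a": 10, "b": 10})
        xs = np.linspace(0, 100, 501)
        want = rb.output.sets["big"].degree(xs)
        assert np.allclose(agg(xs), want)

    def test_partial_activation_clips_flat_top(self):
        rb = tiny_rulebase()
        # only r3 fires: b lo degree at b=3 is 1 - 3/5 = 0.4
        agg = aggregate(rb, {"a": 0, "b": 3})
        xs = np.linspace(0, 100, 1001)
        vals = agg(xs)
        assert vals.max() == pytest.approx(0.4)  # triangle flat-topped at 0.4
        assert np.all(vals[xs > 30] == 0.0)  # nothing else fired

    def test_disjoint_supports_pointwise_max_matches_grid_oracle(self):
        rb = tiny_rulebase()
        # r1 clips 'big' at hi(7) = 0.4 while r3 clips 'small' at lo(1.5) = 0.7:
        # two disjoint consequent supports aggregated by pointwise max
        agg = aggregate(rb, {"a": 7, "b": 1.5})
        assert agg.activations["r1"] == pytest.approx(0.4)
        assert agg.activations["r3"] == pytest.approx(0.7)
        xs = np.arange(0, 100.0001, 0.01)
        acts = agg.activations
        expect = np.zeros_like(xs)
        for name, cons in (("r1", "big"), ("r2", "mid"), ("r3", "small")):
            if acts[name] > 0:
                expect = np.maximum(
                    expect, np.minimum(membership_reference(rb.output.sets[cons], xs), acts[name])
                )
        assert np.allclose(agg(xs), expect, atol=1e-12)

    def test_zero_activation_contributes_nothing(self):
        rb = tiny_rulebase()
        agg = aggregate(rb, {"a": 10, "b": 10})
        assert agg.activations["r2"] == 0.0  # Not hi = 0
        assert agg.activations["r3"] == 0.0
        xs = np.linspace(0, 69.9, 100)
        assert np.all(agg(xs) == np.minimum(rb.output.sets["big"].degree(xs), 1.0))


class TestDefuzzifyCentroid:
    @pytest.mark.parametrize("alpha", [1.0, 0.7, 0.4, 0.05])
    def test_clipped_symmetric_triangle_keeps_its_center(self, alpha):
        mf = Triangular(30, 50, 70)
        agg = AggregatedOutput((0, 100), lambda x: np.minimum(mf.degree(x), alpha))
        assert defuzzify_centroid(agg, 0.1) == pytest.approx(50.0, abs=1e-9)

    def test_rectangular_membership_centers_at_midpoint(self):
        mf = Trapezoidal(20, 20, 40, 40)
        agg = AggregatedOutput((0, 100), mf.degree)
        assert defuzzify_centroid(agg, 0.1) == pytest.approx(30.0, abs=1e-9)

    def test_clipped_asymmetric_triangle_matches_fine_grid_quadrature(self):
        mf = Triangular(10, 20, 90)
        clipped = lambda x: np.minimum(mf.degree(x), 0.6)
        agg = AggregatedOutput((0, 100), clipped)
        got = defuzzify_centroid(agg, 0.1)
        xs = np.arange(0, 100.00001, 0.01)  # 10x finer independent quadrature
        mu = membership_reference(mf, xs)
        mu = np.minimum(mu, 0.6)
        want = float((xs * mu).sum() / mu.sum())
        assert got == pytest.approx(want, abs=0.1)

    def test_zero_aggregate_raises_no_rule_fired(self):
        agg = AggregatedOutput((0, 100), lambda x: np.zeros_like(np.asarray(x, float)))
        with pytest.raises(NoRuleFiredError):
            defuzzify_centroid(agg, 0.1)

    def test_output_inside_universe_for_random_inputs(self):
        rb = tiny_rulebase()
        rng = np.random.default_rng(5)
        for _ in range(100):
            inputs = {"a": rng.uniform(-2, 12), "b": rng.uniform(-2, 12)}
            agg = aggregate(rb, inputs)
            try:
                v = defuzzify_centroid(agg, 0.1)
            except NoRuleFiredError:
                continue
            assert 0.0 <= v <= 100.0

    def test_grid_resolution_convergence(self):
        rb = tiny_rulebase()
        agg = aggregate(rb, {"a": 8.2, "b": 6.3})
        assert abs(defuzzify_centroid(agg, 0.1) - defuzzify_centroid(agg, 0.05)) < 0.05

    def test_monotone_response_of_highest_output_set(self):
        # raising the activation of the top set never lowers the centroid
        rb = tiny_rulebase()
        big = rb.output.sets["big"]
        mid = rb.output.sets["mid"]
        prev = -np.inf
        for act in np.linspace(0.05, 1.0, 12):
            agg = AggregatedOutput(
                (0, 100),
                lambda x, act=act: np.maximum(
                    np.minimum(mid.degree(x), 0.5), np.minimum(big.degree(x), act)
                ),
            )
            v = defuzzify_centroid(agg, 0.1)
            assert v >= prev - 1e-9
            prev = v


class TestLinguisticVariable:
    def test_out_of_universe_inputs_clamp_with_warning(self, caplog):
        var = LinguisticVariable("v", (0, 10), {"s": Triangular(0, 5, 10)})
        import logging

        with caplog.at_level(logging.WARNING, logger="camfuse.fuzzy"):
            degs = var.degrees(25.0)
        assert degs["s"] == membership_degree(var.sets["s"], 10.0)
        assert "clamped" in caplog.text

    def test_rulebase_rejects_unknown_references(self):
        rb = tiny_rulebase()
        with pytest.raises(ValueError):
            RuleBase(
                rules=(FuzzyRule("r", (Antecedent("nope", "hi"),), "big"),),
                inputs=rb.inputs,
                output=rb.output,
            )
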
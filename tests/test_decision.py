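"""Boolean rule engine, occluder sizing, and the decision contract."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dks.decision import (
    BooleanNode,
    Condition,
    OccluderCatalogue,
    RuleError,
    RuleParseError,
    RuleSet,
    SizeUnavailableError,
    decide,
    default_catalogue,
    default_ruleset,
    evaluate,
    parse_ruleset,
    suggest_size,
    write_ruleset,
)

FULL_MEASUREMENTS = {
    "defect_pssax_mm": 12.0,
    "defect_sxlax_mm": 11.0,
    "defect_a4c_mm": 10.0,
    "rim_wall_mm": 10.0,
    "rim_svc_mm": 10.0,
    "rim_ivc_mm": 10.0,
    "rim_roof_mm": 10.0,
    "rim_mitral_mm": 10.0,
    "septum_length_mm": 40.0,
    "max_defect_diameter_mm": 12.0,
}


class TestEvaluate:
    def test_and_of_rim_conditions(self):
        rules = RuleSet(
            BooleanNode(
                "AND",
                (
                    Condition("rim_svc_mm", ">=", 5),
                    Condition("rim_ivc_mm", ">=", 5),
                ),
            )
        )
        ok, trace = evaluate(rules, {"rim_svc_mm": 6, "rim_ivc_mm": 8})
        assert ok and all(t["result"] for t in trace)
        ok, _ = evaluate(rules, {"rim_svc_mm": 4, "rim_ivc_mm": 8})
        assert not ok

    def test_not_inverts(self):
        rules = RuleSet(BooleanNode("NOT", (Condition("x", ">", 1),)))
        assert evaluate(rules, {"x": 2})[0] is False
        assert evaluate(rules, {"x": 0})[0] is True

    def test_unknown_measurement_raises(self):
        rules = RuleSet(Condition("nope_mm", ">", 1))
        with pytest.raises(RuleError):
            evaluate(rules, {"x": 1})

    def test_trace_covers_every_leaf_without_short_circuit(self):
        rules = RuleSet(
            BooleanNode(
                "AND",
                (
                    Condition("a", ">", 1),
                    Condition("b", ">", 1),
                    Condition("c", ">", 1),
                ),
            )
        )
        ok, trace = evaluate(rules, {"a": 0, "b": 5, "c": 5})
        assert not ok and len(trace) == 3

    # exhaustive oracle: random trees of <= 4 leaves over all assignments
    @given(data=st.data())
    def test_agrees_with_truth_table_enumeration(self, data):
        n_leaves = data.draw(st.integers(1, 4))
        names = [f"m{i}" for i in range(n_leaves)]

        def tree(depth, leaves):
            if depth >= 3 or data.draw(st.booleans()):
                name = leaves[data.draw(st.integers(0, len(leaves) - 1))]
                return Condition(name, ">", 0.0), lambda env, n=name: env[n] > 0
            op = data.draw(st.sampled_from(["AND", "OR", "NOT"]))
            if op == "NOT":
                child, f = tree(depth + 1, leaves)
                return BooleanNode("NOT", (child,)), lambda env, f=f: not f(env)
            left, lf = tree(depth + 1, leaves)
            right, rf = tree(depth + 1, leaves)
            comb = all if op == "AND" else any
            return (
                BooleanNode(op, (left, right)),
                lambda env, lf=lf, rf=rf, comb=comb: comb([lf(env), rf(env)]),
            )

        root, oracle = tree(0, names)
        rules = RuleSet(root)
        for bits in range(2**n_leaves):
            env = {n: (1.0 if bits >> i & 1 else -1.0) for i, n in enumerate(names)}
            assert evaluate(rules, env)[0] == oracle(env)


class TestSuggestSize:
    def test_margin_and_catalogue_rounding(self):
        cat = default_catalogue()
        assert suggest_size({"max_defect_diameter_mm": 12.0}, cat) == 16
        # 3.5 + 4 = 7.5 -> smallest catalogue device is 8
        assert suggest_size({"max_defect_diameter_mm": 3.5}, cat) == 8

    def test_size_unavailable(self):
        with pytest.raises(SizeUnavailableError):
            suggest_size({"max_defect_diameter_mm": 29.0}, default_catalogue())

    def test_monotone_in_diameter(self):
        cat = default_catalogue()
        sizes = [
            suggest_size({"max_defect_diameter_mm": d}, cat)
            for d in np.linspace(0, 28, 57)
        ]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_catalogue_validation(self):
        with pytest.raises(ValueError):
            OccluderCatalogue(sizes_mm=(10, 10))
        with pytest.raises(ValueError):
            OccluderCatalogue(sizes_mm=())


class TestDecide:
    def test_transcatheter_with_size(self):
        res = decide(FULL_MEASUREMENTS)
        assert res.plan == "transcatheter"
        assert res.suggested_size_mm == 16
        assert res.rules_satisfied and res.size_available
        assert len(res.rule_trace) == len(default_ruleset().leaves())

    def test_deficient_rim_goes_surgical(self):
        m = dict(FULL_MEASUREMENTS, rim_wall_mm=2.0)
        res = decide(m)
        assert res.plan == "surgical" and res.suggested_size_mm is None
        failed = [t for t in res.rule_trace if not t["result"]]
        assert failed and failed[0]["measure"] == "rim_wall_mm"

    def test_oversize_defect_goes_surgical_even_with_good_rims(self):
        m = dict(FULL_MEASUREMENTS, max_defect_diameter_mm=30.0)
        res = decide(m)
        assert res.plan == "surgical"
        assert not res.size_available
        assert len(res.rule_trace) == len(default_ruleset().leaves())

    def test_trace_table_renders(self):
        table = decide(FULL_MEASUREMENTS).trace_table()
        assert "rim_svc_mm" in table and "PASS" in table


class TestParseRuleset:
    def test_default_ruleset_shape(self):
        rules = default_ruleset()
        leaves = rules.leaves()
        rim_leaves = [l for l in leaves if l.measure.startswith("rim_")]
        assert len(rim_leaves) == 5
        assert all(l.cmp == ">=" and l.threshold == 5.0 for l in rim_leaves)
        septum = [l for l in leaves if l.measure == "septum_length_mm"]
        assert len(septum) == 1 and septum[0].threshold == "suggested_size_mm"

    def test_serialize_parse_identity(self, tmp_path):
        rules = default_ruleset()
        assert parse_ruleset(rules.to_yaml()).to_dict() == rules.to_dict()
        for name in ("r.yaml", "r.json"):
            path = tmp_path / name
            write_ruleset(path, rules)
            assert parse_ruleset(path).to_dict() == rules.to_dict()

    def test_empty_and_malformed_configs_rejected(self):
        with pytest.raises(RuleParseError):
            parse_ruleset("")
        with pytest.raises(RuleParseError):
            parse_ruleset({"op": "AND"})  # no children
        with pytest.raises(RuleParseError):
            parse_ruleset({"op": "XOR", "children": [{"measure": "x", "cmp": ">", "threshold": 1}]})
        with pytest.raises(RuleParseError):
            parse_ruleset({"measure": "x", "cmp": "!!", "threshold": 1})


class TestLabelConsistency:
    def test_generator_labels_reproduced_from_measurements(self, small_cases):
        from dks.stadiometry import measure_case

        for case in small_cases:
            m = measure_case(case.keypoints, case.scales)
            res = decide(m.to_dict())
            assert res.plan == case.label_plan
            assert res.suggested_size_mm == case.label_size_mm
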
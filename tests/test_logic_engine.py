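import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synlogic as sl
from synlogic.expr import ExprError, parse_expr
from synlogic.model import (AND_NOT, OR_NOT, ExprRule, IdentityRule, LinkRule,
                            ModelError, evaluate, read_rules, write_rules)
from conftest import random_model
from oracles import brute_force_async_attractors, brute_force_stable_states


# ---------------------------------------------------------------------------
# expressions


class TestExpressions:
    @pytest.mark.parametrize("text,env,value", [
        ("MAP2K3 | MAP2K4 | !DUSP1", {"MAP2K3": 0, "MAP2K4": 0, "DUSP1": 0}, 1),
        ("MAP2K3 | MAP2K4 | !DUSP1", {"MAP2K3": 1, "MAP2K4": 0, "DUSP1": 1}, 1),
        ("MAP2K3 | MAP2K4 | !DUSP1", {"MAP2K3": 0, "MAP2K4": 0, "DUSP1": 1}, 0),
        ("(A | B) & !C", {"A": 0, "B": 0, "C": 0}, 0),
        ("[(m | I) & P] & !Q", {"m": 1, "I": 0, "P": 1, "Q": 0}, 1),
        ("!(A & B)", {"A": 1, "B": 0}, 1),
    ])
    def test_evaluation(self, text, env, value):
        e = parse_expr(text)
        assert int(e.evaluate(lambda n: env[n] >= 1)) == value

    def test_parse_round_trip_preserves_semantics(self):
        text = "[(mTORC2_c | ILK) & PIP3] & !PPP1CA"
        e = parse_expr(text)
        again = parse_expr(str(e))
        for bits in range(16):
            env = {n: (bits >> i) & 1 for i, n in
                   enumerate(["mTORC2_c", "ILK", "PIP3", "PPP1CA"])}
            assert e.evaluate(lambda n: env[n] >= 1) == again.evaluate(lambda n: env[n] >= 1)

    @pytest.mark.parametrize("bad", ["", "A &", "A | | B", "(A", "A + B"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ExprError):
            parse_expr(bad)

    def test_polarities(self):
        e = parse_expr("(A | !B) & !(C | A)")
        pol = e.polarities()
        assert pol["A"] == {1, -1} and pol["B"] == {-1} and pol["C"] == {-1}


# ---------------------------------------------------------------------------
# default rules


class TestDefaultRules:
    def test_and_not_convention(self):
        net = sl.make_network([("A", 1, "X"), ("B", 1, "X"), ("C", -1, "X")])
        model = sl.default_rules(net)
        rule = model.rules["X"]
        assert isinstance(rule, LinkRule)
        assert rule.activators == ("A", "B") and rule.inhibitors == ("C",)
        assert rule.operator == AND_NOT
        assert str(rule.expr()) == "(A | B) & !C"

    def test_or_not_override_matches_stress_kinase_exception(self):
        net = sl.make_network([("MAP2K3", 1, "MAPK14"), ("MAP2K4", 1, "MAPK14"),
                               ("DUSP1", -1, "MAPK14")])
        model = sl.default_rules(net, link_overrides={"MAPK14": OR_NOT})
        rule = model.rules["MAPK14"]
        # all regulators silent -> active; active despite active inhibitor
        assert rule.next_value({"MAP2K3": 0, "MAP2K4": 0, "DUSP1": 0}) == 1
        assert rule.next_value({"MAP2K3": 1, "MAP2K4": 0, "DUSP1": 1}) == 1
        assert rule.next_value({"MAP2K3": 0, "MAP2K4": 0, "DUSP1": 1}) == 0

    def test_input_node_identity_rule_admits_both_values(self):
        net = sl.make_network([("X", 1, "Y")])
        model = sl.default_rules(net)
        assert isinstance(model.rules["X"], IdentityRule)
        states = sl.stable_states(model)
        assert [{s["X"], s["Y"]} for s in states] == [{0}, {1}]

    def test_inhibitor_only_node(self):
        net = sl.make_network([("I", -1, "X")])
        model = sl.default_rules(net)
        assert model.rules["X"].next_value({"I": 0, "X": 0}) == 1
        assert model.rules["X"].next_value({"I": 1, "X": 0}) == 0

    def test_output_counting_rule_clips(self):
        edges = [(f"P{i}", 1, "Prosurvival") for i in range(5)]
        edges += [("N0", -1, "Prosurvival"), ("P0", 1, "Antisurvival"),
                  ("P1", 1, "Antisurvival"), ("P2", 1, "Antisurvival")]
        net = sl.make_network(edges, output_nodes=("Prosurvival", "Antisurvival"))
        model = sl.default_rules(net)
        state = {f"P{i}": 1 for i in range(5)}
        state.update({"N0": 0, "Prosurvival": 0, "Antisurvival": 0})
        assert model.rules["Prosurvival"].next_value(state) == 3  # clipped at max
        state["N0"] = 1
        assert model.rules["Prosurvival"].next_value(state) == 3  # 5 - 1 = 4 -> 3
        state.update({f"P{i}": 0 for i in range(3, 5)})
        assert model.rules["Prosurvival"].next_value(state) == 2  # 3 - 1

    def test_evaluate_rejects_incomplete_state(self):
        net = sl.make_network([("A", 1, "B")])
        model = sl.default_rules(net)
        with pytest.raises(ModelError, match="missing"):
            evaluate(model, {"A": 1})


# ---------------------------------------------------------------------------
# stable states


class TestStableStates:
    def test_negative_self_loop_has_no_fixed_point(self):
        model = sl.default_rules(sl.make_network([("X", -1, "X")]))
        assert sl.stable_states(model) == []

    def test_identity_node_has_two_fixed_points(self):
        net = sl.make_network([], extra_nodes=["X"])
        model = sl.default_rules(net)
        assert sl.stable_states(model) == [{"X": 0}, {"X": 1}]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        model = random_model(seed, n_nodes=8 + seed % 5, n_cycles=seed % 4)
        assert sl.stable_states(model) == brute_force_stable_states(model)

    @pytest.mark.parametrize("seed", range(6))
    def test_clamps_equal_constant_rule_rewrite(self, seed):
        model = random_model(seed, n_nodes=9, n_cycles=seed % 3)
        node = sorted(model.network.nodes)[3]
        clamped = sl.stable_states(model, {node: 0})
        rewritten = sl.stable_states(model.clamped({node: 0}))
        assert clamped == rewritten == brute_force_stable_states(model, {node: 0})

    def test_deterministic_order(self):
        model = random_model(5, n_nodes=10, n_cycles=2)
        assert sl.stable_states(model) == sl.stable_states(model)


# ---------------------------------------------------------------------------
# asynchronous attractors


class TestAsyncAttractors:
    def test_negative_self_loop_is_complex_attractor(self):
        model = sl.default_rules(sl.make_network([("X", -1, "X")]))
        analysis = sl.async_attractors(model)
        assert len(analysis.attractors) == 1
        att = analysis.attractors[0]
        assert att.kind == "complex" and len(att.states) == 2

    def test_unique_fixed_point_model(self):
        net = sl.make_network([("A", 1, "B"), ("B", 1, "C")])
        model = sl.default_rules(net).clamped({"A": 1})
        analysis = sl.async_attractors(model)
        assert [a.kind for a in analysis.attractors] == ["stable_state"]
        assert analysis.attractors[0].states[0] == {"A": 1, "B": 1, "C": 1}

    def test_state_cap_yields_undecided(self):
        model = random_model(0, n_nodes=12)
        analysis = sl.async_attractors(model, max_states=8)
        assert analysis.undecided and analysis.attractors == ()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_transition_graph_oracle(self, seed):
        model = random_model(seed, n_nodes=6 + seed % 4, n_cycles=1 + seed % 3)
        got = [(a.kind, a.states) for a in sl.async_attractors(model).attractors]
        assert got == brute_force_async_attractors(model)

    @pytest.mark.parametrize("seed", range(8))
    def test_fixed_points_equal_singleton_attractors(self, seed):
        model = random_model(seed + 50, n_nodes=7, n_cycles=seed % 3)
        singles = [a.states[0] for a in sl.async_attractors(model).attractors
                   if a.kind == "stable_state"]
        assert singles == sl.stable_states(model)


# ---------------------------------------------------------------------------
# reduction


class TestReduction:
    def test_chain_substitution(self):
        net = sl.make_network([("A", 1, "B"), ("B", 1, "C")])
        model = sl.default_rules(net)
        red = sl.reduce_model(model, {"A", "C"})
        assert set(red.network.nodes) == {"A", "C"}
        assert red.rules["C"].regulators == {"A"}
        full = sl.project_states(sl.stable_states(model), ["A", "C"])
        assert sl.project_states(sl.stable_states(red), ["A", "C"]) == full

    def test_two_cycle_elimination_reports_irreducible_loop(self):
        # A <-> B with an external input driving A; retaining only B makes
        # B self-regulated after substituting A's rule
        net = sl.make_network([("I", 1, "A"), ("B", 1, "A"), ("A", 1, "B")])
        model = sl.default_rules(net)
        red = sl.reduce_model(model, {"I", "B"})
        assert "A" not in red.network.node_set
        assert "B" in red.rules["B"].regulators
        full = sl.project_states(sl.stable_states(model), ["B", "I"])
        assert sl.project_states(sl.stable_states(red), ["B", "I"]) == full

    def test_self_loop_node_kept_and_reported(self):
        net = sl.make_network([("X", 1, "X"), ("X", 1, "Y"), ("Y", 1, "Z")])
        model = sl.default_rules(net)
        red = sl.reduce_model(model, {"Z"})
        assert "X" in red.irreducible_nodes

    def test_unknown_retain_node_rejected(self):
        model = sl.default_rules(sl.make_network([("A", 1, "B")]))
        with pytest.raises(ModelError, match="unknown"):
            sl.reduce_model(model, {"Q"})

    @pytest.mark.parametrize("seed", range(15))
    def test_projected_fixed_points_preserved(self, seed):
        model = random_model(seed, n_nodes=9 + seed % 6, n_cycles=seed % 4)
        net = model.network
        retain = set(net.drug_target_nodes) | set(net.output_nodes)
        red = sl.reduce_model(model, retain)
        kept = sorted(red.network.nodes)
        assert (sl.project_states(brute_force_stable_states(model), kept)
                == sl.project_states(sl.stable_states(red), kept))


# ---------------------------------------------------------------------------
# edits


class TestEdits:
    @pytest.fixture()
    def akt_model(self):
        edges = [("mTORC2_c", 1, "AKT_f"), ("PIK3CA", 1, "AKT_f"),
                 ("PPP1CA", -1, "AKT_f"), ("ILK", 1, "X"), ("PIP3", 1, "X")]
        return sl.default_rules(sl.make_network(edges))

    def test_set_rule_verbatim(self, akt_model):
        edit = sl.ModelEdit.set_rule("AKT_f", "[(mTORC2_c | ILK) & PIP3] & !PPP1CA")
        model = sl.apply_edits(akt_model, [edit])
        rule = model.rules["AKT_f"]
        assert isinstance(rule, ExprRule)
        assert rule.regulators == {"mTORC2_c", "ILK", "PIP3", "PPP1CA"}
        # network in-edges resynced to the new rule
        assert set(model.network.regulators("AKT_f")) == rule.regulators

    def test_remove_edge_drops_regulator(self):
        net = sl.make_network([("CK1_f", -1, "FOXO_f"), ("NLK", 1, "FOXO_f")])
        model = sl.default_rules(net)
        model = sl.apply_edits(model, [sl.ModelEdit.remove_edge("CK1_f", "FOXO_f")])
        assert model.rules["FOXO_f"].regulators == {"NLK"}
        assert all(e[2] != "FOXO_f" or e[0] != "CK1_f" for e in model.network.edges)

    def test_add_node_with_rule(self, akt_model):
        model = sl.apply_edits(akt_model, [
            sl.ModelEdit.add_node("MXD1", expression="!PIK3CA & !ILK")])
        assert model.rules["MXD1"].regulators == {"PIK3CA", "ILK"}

    def test_empty_edit_list_is_identity(self, akt_model):
        assert sl.apply_edits(akt_model, []).rules == akt_model.rules

    def test_error_reports_edit_index(self, akt_model):
        edits = [sl.ModelEdit.set_rule("AKT_f", "PIK3CA"),
                 sl.ModelEdit.remove_edge("NOPE", "AKT_f")]
        with pytest.raises(ModelError, match="edit 1"):
            sl.apply_edits(akt_model, edits)

    def test_edit_log_retained(self, akt_model):
        edits = [sl.ModelEdit.set_max_level("AKT_f", 2)]
        model = sl.apply_edits(akt_model, edits)
        assert model.edit_log == tuple(edits)

    def test_edits_from_yaml(self, akt_model):
        text = """
- kind: set_rule
  node: AKT_f
  expression: PIK3CA & !PPP1CA
- kind: set_max_level
  node: AKT_f
  max_level: 2
"""
        edits = sl.edits_from_yaml(text)
        model = sl.apply_edits(akt_model, edits)
        assert model.max_level("AKT_f") == 2
        assert model.rules["AKT_f"].regulators == {"PIK3CA", "PPP1CA"}


# ---------------------------------------------------------------------------
# serialization


class TestRuleSerialization:
    @pytest.mark.parametrize("seed", [0, 4])
    def test_round_trip_preserves_dynamics(self, seed):
        model = random_model(seed, n_nodes=10, n_cycles=seed % 2)
        back = read_rules(write_rules(model))
        assert sl.stable_states(back) == sl.stable_states(model)
        assert {n: back.max_level(n) for n in back.network.nodes} \
            == {n: model.max_level(n) for n in model.network.nodes}


# ---------------------------------------------------------------------------
# property: synchronous image determinism


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_evaluate_total_and_deterministic(seed):
    model = random_model(seed % 100, n_nodes=8)
    states = sl.stable_states(model)
    for s in states:
        assert evaluate(model, s) == s  # fixed points map to themselves
    some = {n: 0 for n in model.network.nodes}
    assert evaluate(model, some) == evaluate(model, some)
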
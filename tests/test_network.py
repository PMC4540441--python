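"""Network: CPT construction, validation, exact inference."""

import itertools

import numpy as np
import pytest

from conftest import enumerate_outcome_posterior, random_small_network
from reefrisk.elicitation import Parameterization, build_parameterization
from reefrisk.network import (
    CPT,
    EndpointElicitation,
    NetworkModel,
    NodeSpec,
    build_model,
    composite_cpt,
    default_orientation_map,
    default_structure,
    infer,
    infer_decline,
    interpolate_cpt,
    ordinal_score,
    read_cpts,
    required_quantities,
    structure_from_yaml,
    structure_to_yaml,
    validate_network,
    write_cpts,
)

S3 = ("low", "medium", "high")


def _parents(n=2, states=S3):
    return [NodeSpec(f"p{i}", "input", states) for i in range(n)]


class TestOrdinalScore:
    def test_extremes(self):
        ps = _parents(3)
        assert ordinal_score(("low",) * 3, ps) == 0.0
        assert ordinal_score(("high",) * 3, ps) == 1.0

    def test_mixed_assignment(self):
        ps = _parents(2)
        assert ordinal_score(("medium", "high"), ps) == pytest.approx(0.75)

    def test_single_state_parent_contributes_zero_with_warning(self):
        ps = [NodeSpec("p0", "input", ("only",)), NodeSpec("p1", "input", S3)]
        with pytest.warns(UserWarning, match="single state"):
            assert ordinal_score(("only", "high"), ps) == pytest.approx(0.5)


class TestInterpolateCpt:
    def test_endpoints_reproduced_bit_for_bit(self):
        ps = _parents(2)
        low = np.array([0.8, 0.15, 0.05])
        high = np.array([0.07, 0.23, 0.7])
        cpt = interpolate_cpt(EndpointElicitation("n", low, high), ps, S3)
        assert np.array_equal(cpt.table[("low", "low")], low)
        assert np.array_equal(cpt.table[("high", "high")], high)

    def test_midpoint_is_arithmetic_mean(self):
        ps = _parents(1, states=("a", "b", "c"))
        cpt = interpolate_cpt(
            EndpointElicitation("n", np.array([0.8, 0.2]), np.array([0.2, 0.8])),
            ps, ("x", "y"))
        assert cpt.table[("b",)] == pytest.approx([0.5, 0.5])

    def test_all_rows_normalized(self):
        ps = _parents(3)
        cpt = interpolate_cpt(
            EndpointElicitation("n", np.array([0.6, 0.4]), np.array([0.1, 0.9])),
            ps, ("x", "y"))
        assert not cpt.validate()

    def test_monotone_in_score_under_dominance(self):
        """If the high endpoint stochastically dominates, interpolated rows
        are ordered in the interpolation coordinate."""
        ps = _parents(2)
        low, high = np.array([0.7, 0.2, 0.1]), np.array([0.1, 0.2, 0.7])
        cpt = interpolate_cpt(EndpointElicitation("n", low, high), ps, S3)
        rows = sorted(
            ((ordinal_score(c, ps), r) for c, r in cpt.table.items()),
            key=lambda t: t[0])
        upper_tails = [r[2] + r[1] for _, r in rows]  # P(state >= medium)
        assert all(b >= a - 1e-12 for a, b in zip(upper_tails, upper_tails[1:]))


class TestCompositeCpt:
    def test_all_parents_highest_maps_to_highest(self):
        node = NodeSpec("c", "composite", S3, ("p0", "p1"))
        cpt = composite_cpt(node, _parents(2), {"p0": 1, "p1": 1})
        assert cpt.table[("high", "high")] == pytest.approx([0, 0, 1])

    def test_degenerate_weight_follows_single_parent(self):
        node = NodeSpec("c", "composite", S3, ("p0", "p1"))
        cpt = composite_cpt(node, _parents(2), {"p0": 1, "p1": 0})
        for s1 in S3:
            for i, s0 in enumerate(S3):
                expected = np.zeros(3)
                expected[i] = 1
                assert cpt.table[(s0, s1)] == pytest.approx(expected)

    def test_threshold_rule_midpoint(self):
        node = NodeSpec("c", "composite", S3, ("p0", "p1"))
        cpt = composite_cpt(node, _parents(2), {"p0": 1, "p1": 1})
        # (lowest, highest) -> index 0.5 -> middle state
        assert cpt.table[("low", "high")] == pytest.approx([0, 1, 0])

    def test_zero_weights_rejected(self):
        node = NodeSpec("c", "composite", S3, ("p0", "p1"))
        with pytest.raises(ValueError, match="zero"):
            composite_cpt(node, _parents(2), {"p0": 0, "p1": 0})


class TestValidation:
    def test_default_model_passes(self, default_model):
        assert validate_network(default_model)

    def test_missing_row_named(self, default_model):
        broken = NetworkModel(
            nodes=dict(default_model.nodes),
            cpts={k: CPT(v.node, v.states, v.parents, v.parent_states,
                         dict(v.table))
                  for k, v in default_model.cpts.items()},
            composite_weights=default_model.composite_weights)
        combo = next(iter(broken.cpts["disease"].table))
        del broken.cpts["disease"].table[combo]
        report = validate_network(broken)
        assert not report
        assert any("disease" in p and "missing row" in p for p in report.problems)

    def test_cycle_named(self):
        states = ("a", "b")
        nodes = {
            "x": NodeSpec("x", "event", states, ("y",)),
            "y": NodeSpec("y", "event", states, ("x",)),
        }
        cpts = {
            n: CPT(n, states, nodes[n].parents, (states,),
                   {(s,): np.array([0.5, 0.5]) for s in states})
            for n in nodes
        }
        report = validate_network(NetworkModel(nodes=nodes, cpts=cpts))
        assert not report
        assert any("cycle" in p for p in report.problems)


class TestInference:
    def test_deterministic_chain(self):
        states = ("a", "b", "c")
        identity = {(s,): np.eye(3)[i] for i, s in enumerate(states)}
        nodes = {
            "in": NodeSpec("in", "input", states),
            "ev": NodeSpec("ev", "event", states, ("in",)),
            "out": NodeSpec("out", "outcome", states, ("ev",)),
        }
        cpts = {
            "ev": CPT("ev", states, ("in",), (states,), dict(identity)),
            "out": CPT("out", states, ("ev",), (states,), dict(identity)),
        }
        model = NetworkModel(nodes=nodes, cpts=cpts)
        post = infer(model, {"in": "b"}, "out")
        assert post == pytest.approx([0, 1, 0])

    def test_constant_leaf_ignores_evidence(self):
        states = ("x", "y")
        nodes = {
            "in": NodeSpec("in", "input", ("a", "b")),
            "out": NodeSpec("out", "outcome", states, ("in",)),
        }
        cpts = {"out": CPT("out", states, ("in",), (("a", "b"),),
                           {("a",): np.array([0.4, 0.6]),
                            ("b",): np.array([0.4, 0.6])})}
        model = NetworkModel(nodes=nodes, cpts=cpts)
        for s in ("a", "b"):
            assert infer_decline(model, {"in": s}) == pytest.approx(0.6)

    def test_incomplete_evidence_lists_missing_inputs(self, default_model):
        with pytest.raises(ValueError, match="temperature"):
            infer_decline(default_model, {"cyclones": "average"})

    def test_matches_enumeration_on_seeded_networks(self):
        """Variable elimination equals full-joint enumeration to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            model, evidence = random_small_network(rng)
            outcome = model.outcome_node
            got = infer(model, evidence, outcome, validate=False)
            want = enumerate_outcome_posterior(model, evidence, outcome)
            np.testing.assert_allclose(got, want, atol=1e-12, rtol=0)

    def test_single_input_adversity_increase_never_decreases_decline(
            self, default_model):
        """More adverse evidence on any one input cannot lower decline risk."""
        rng = np.random.default_rng(5)
        inputs = default_model.input_nodes
        states = ("below", "average", "above")
        for _ in range(150):
            base = {n: states[rng.integers(3)] for n in inputs}
            p0 = infer_decline(default_model, base, validate=False)
            for n in inputs:
                i = states.index(base[n])
                if i == 2:
                    continue
                bumped = dict(base, **{n: states[i + 1]})
                p1 = infer_decline(default_model, bumped, validate=False)
                assert p1 >= p0 - 1e-12, (n, base)

    def test_pessimistic_dominates_optimistic_exhaustively(self, expert_responses):
        """Pessimistic decline >= optimistic decline on the whole input space."""
        nodes, weights = default_structure()
        orientation = default_orientation_map(nodes)
        required = required_quantities(nodes)
        models = {}
        for label in ("pessimistic", "optimistic"):
            param = build_parameterization(
                expert_responses, label, orientation, required=required)
            models[label] = build_model(param, nodes, weights)
        inputs = models["pessimistic"].input_nodes
        states = ("below", "average", "above")
        for combo in itertools.product(states, repeat=len(inputs)):
            ev = dict(zip(inputs, combo))
            p_pess = infer_decline(models["pessimistic"], ev, validate=False)
            p_opt = infer_decline(models["optimistic"], ev, validate=False)
            assert p_pess >= p_opt - 1e-12, ev


class TestEventShifts:
    def test_shift_moves_mass_up_and_clamps(self, default_model):
        shifted = default_model.with_event_shifts({"bleaching": 1})
        for combo, row in default_model.cpts["bleaching"].table.items():
            new = shifted.cpts["bleaching"].table[combo]
            assert new[0] == 0.0
            assert new[2] == pytest.approx(row[1] + row[2])
            assert new.sum() == pytest.approx(1.0)

    def test_non_event_rejected(self, default_model):
        with pytest.raises(ValueError, match="not an event node"):
            default_model.with_event_shifts({"coral_decline": 1})


class TestModelAssembly:
    def test_missing_quantities_rejected(self):
        with pytest.raises(KeyError, match="bleaching"):
            build_model(Parameterization("mean", {}))

    def test_endpoint_distributions_flow_into_cpts(self, fitted):
        """The all-low/all-high outcome rows equal the pooled, renormalized
        endpoint probabilities."""
        model, param = fitted.model_, fitted.parameterization_
        cpt = model.cpts["coral_decline"]
        spec = model.nodes["coral_decline"]
        for endpoint, combo_state in (("low", 0), ("high", -1)):
            combo = tuple(model.nodes[p].states[combo_state] for p in spec.parents)
            raw = np.array([param[f"coral_decline:{endpoint}:{s}"]
                            for s in spec.states])
            assert cpt.table[combo] == pytest.approx(raw / raw.sum())


class TestFiles:
    def test_structure_yaml_round_trip(self, tmp_path):
        nodes, weights = default_structure()
        path = tmp_path / "structure.yaml"
        structure_to_yaml(nodes, weights, path)
        nodes2, weights2 = structure_from_yaml(path)
        assert nodes2 == nodes
        assert weights2 == weights

    def test_cpt_csv_round_trip_bit_exact(self, default_model, tmp_path):
        path = tmp_path / "cpts.csv"
        write_cpts(default_model.cpts, path)
        nodes = default_model.nodes
        back = read_cpts(path, nodes)
        for name, cpt in default_model.cpts.items():
            for combo, row in cpt.table.items():
                assert np.array_equal(back[name].table[combo], row), (name, combo)
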
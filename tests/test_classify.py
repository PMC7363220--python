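"""Behaviour classification, bifurcation function, witnesses."""

import pytest

from bnbif import analyse, generate_fixture
from bnbif.attractors import (
    brute_force_attractors,
    brute_force_behaviour,
    find_attractors,
)
from bnbif.classify import (
    BehaviourClass,
    ClassificationError,
    build_bifurcation,
    class_cardinalities,
    classify,
    witness,
)
from bnbif.expr import parse_expression
from bnbif.graph import ColouredGraph
from bnbif.network import ParametrisedNetwork, Regulation, instantiate
from tests.conftest import P_AND, P_OR, per_colour_oracle


class TestBehaviourClass:
    def test_canonical_string_orders_s_before_o_before_d(self):
        cls = BehaviourClass.from_behaviours(
            ["disordered", "stable", "oscillating", "stable"]
        )
        assert str(cls) == "SSOD"
        assert BehaviourClass.from_string("SSOD") == cls
        assert BehaviourClass.from_string("DOSS") == cls  # multiset semantics

    def test_bad_letters_rejected(self):
        with pytest.raises(ClassificationError):
            BehaviourClass.from_string("SX")


class TestWorkedExampleClassification:
    def test_singleton_attractor_is_stable(self, worked_example):
        g = ColouredGraph(worked_example)
        result = find_attractors(g)
        stable = next(a for a in result.attractors if len(a.states) == 1)
        behaviours = classify(g, stable)
        assert set(behaviours) == {"stable"}
        assert behaviours["stable"].contains(g.encoder.encode(P_OR))

    def test_four_state_attractor_is_oscillating(self, worked_example):
        g = ColouredGraph(worked_example)
        result = find_attractors(g)
        cycle = next(a for a in result.attractors if len(a.states) == 4)
        behaviours = classify(g, cycle)
        assert set(behaviours) == {"oscillating"}
        assert behaviours["oscillating"].contains(g.encoder.encode(P_AND))

    def test_bifurcation_function_partitions_the_two_colours(self, worked_example):
        result = analyse(worked_example)
        cards = {str(k): v for k, v in result.bifurcation.cardinalities().items()}
        assert cards == {"S": 1, "O": 1}


def _disordered_network():
    # F_a = !a, F_b = a ^ b: the whole 4-state space is one terminal SCC and
    # state a=1,b=0 has two enabled flips, so no colour oscillates.
    names = ("a", "b")
    regs = [
        Regulation("a", "a", observable="required", monotonicity="inhibition"),
        Regulation("a", "b", observable="required", monotonicity="unknown"),
        Regulation("b", "b", observable="required", monotonicity="unknown"),
    ]
    update = {
        "a": parse_expression("!a", frozenset(names), {}),
        "b": parse_expression("a ^ b", frozenset(names), {}),
    }
    return ParametrisedNetwork(names, regs, [], update)


class TestDisordered:
    def test_multi_successor_attractor_is_disordered(self):
        n = _disordered_network()
        g = ColouredGraph(n)
        result = find_attractors(g)
        (attractor,) = result.attractors
        assert len(attractor.states) == 4
        behaviours = classify(g, attractor)
        assert set(behaviours) == {"disordered"}
        # the explicit oracle agrees
        assert brute_force_behaviour(n, attractor.states) == "disordered"

    def test_single_colour_cardinality(self):
        result = analyse(_disordered_network())
        cards = {str(k): v for k, v in result.bifurcation.cardinalities().items()}
        assert cards == {"D": 1}


class TestBifurcationInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_partition_of_valid_colours(self, seed):
        doc = generate_fixture(5, seed=seed, max_parameters=2, max_colours=64)
        result = analyse(doc.network)
        bf = result.bifurcation
        total = 0
        colour_sets = list(bf.classes.values())
        for i, a in enumerate(colour_sets):
            total += a.count()
            for b in colour_sets[i + 1 :]:
                assert (a & b).is_empty, "class colour sets must be disjoint"
        assert total == result.graph.valid.count()

    @pytest.mark.parametrize("seed", range(10))
    def test_per_colour_class_matches_the_oracle(self, seed):
        doc = generate_fixture(5, seed=seed, max_parameters=2, max_colours=64)
        result = analyse(doc.network)
        for assignment, _, expected_cls in per_colour_oracle(doc.network, result):
            assert result.bifurcation.class_of(assignment) == expected_cls

    def test_incomplete_classification_is_an_error(self, worked_example):
        result = analyse(worked_example)
        g = result.graph
        with pytest.raises(ClassificationError, match="no classified attractor"):
            build_bifurcation([], g.valid)

    def test_stable_count_equals_fixed_point_count_per_colour(self):
        for seed in range(6):
            doc = generate_fixture(5, seed=seed, max_parameters=2, max_colours=64)
            n = doc.network
            result = analyse(n)
            for p in result.graph.encoder.iter_colours(result.graph.valid):
                a = result.graph.encoder.encode(p)
                bn = instantiate(n, p)
                from bnbif.attractors import build_explicit_stg

                stg = build_explicit_stg(bn)
                fixed_points = sum(1 for s in range(n.num_states) if stg.out_degree(s) == 0)
                n_stable = result.bifurcation.class_of(a).counts[0]
                assert n_stable == fixed_points


class TestWitness:
    def test_stable_witness_is_the_or_instantiation(self, worked_example):
        result = analyse(worked_example)
        colours = result.bifurcation.classes[BehaviourClass.from_string("S")]
        bn = witness(worked_example, result.graph.encoder, colours)
        for state in range(8):
            a = bn.state_bit(state, "A")
            c = bn.state_bit(state, "C")
            from bnbif.network import evaluate

            assert evaluate(bn.update["B"], state, bn) == a | c

    def test_oscillating_witness_is_the_and_instantiation(self, worked_example):
        result = analyse(worked_example)
        colours = result.bifurcation.classes[BehaviourClass.from_string("O")]
        bn = witness(worked_example, result.graph.encoder, colours)
        from bnbif.network import evaluate

        for state in range(8):
            a = bn.state_bit(state, "A")
            c = bn.state_bit(state, "C")
            assert evaluate(bn.update["B"], state, bn) == a & c

    def test_empty_colour_set_has_no_witness(self, worked_example):
        result = analyse(worked_example)
        g = result.graph
        with pytest.raises(ClassificationError):
            witness(worked_example, g.encoder, g.valid - g.valid)

    @pytest.mark.parametrize("seed", range(6))
    def test_witness_reanalysis_reproduces_its_class(self, seed):
        doc = generate_fixture(5, seed=seed, max_parameters=2, max_colours=64)
        result = analyse(doc.network)
        for cls, colours in result.bifurcation.classes.items():
            bn = witness(doc.network, result.graph.encoder, colours)
            bottoms = brute_force_attractors(bn)
            observed = BehaviourClass.from_behaviours(
                brute_force_behaviour(bn, b) for b in bottoms
            )
            assert observed == cls
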
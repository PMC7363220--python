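"""Parameter encoder and regulation-property constraints."""

from itertools import product

import pytest

from bnbif.bdd import Assignment
from bnbif.encoding import (
    EncodingError,
    build_encoder,
    monotonicity_constraint,
    observability_constraint,
    symbolic_row,
    valid_colours,
)
from bnbif.expr import Const, parse_expression
from bnbif.network import (
    ParameterDecl,
    ParametrisedNetwork,
    Regulation,
    all_parametrisations,
    evaluate,
)
from bnbif import generate_fixture
from tests.conftest import P_AND, P_OR


class TestLayout:
    def test_worked_example_has_four_bits(self, worked_example):
        encoder = build_encoder(worked_example)
        assert encoder.num_bits == 4
        assert encoder.bits == (("P", 0), ("P", 1), ("P", 2), ("P", 3))

    def test_parameter_free_network_has_one_colour(self):
        n = ParametrisedNetwork(("X",), [], [], {"X": Const(True)})
        encoder = build_encoder(n)
        assert encoder.num_bits == 0
        assert encoder.universe().count() == 1

    def test_bits_sum_over_arities(self):
        n = ParametrisedNetwork(
            ("X",),
            [Regulation("X", "X", observable="unknown")],
            [ParameterDecl("P", 1), ParameterDecl("Q", 3)],
            {"X": parse_expression("P(X)", {"X"}, {"P": 1})},
        )
        assert build_encoder(n).num_bits == 2 + 8

    def test_arity_over_cap_refused(self):
        n = ParametrisedNetwork(
            ("X",), [], [ParameterDecl("P", 9)], {"X": Const(True)}
        )
        with pytest.raises(EncodingError, match="arity 9"):
            build_encoder(n)


class TestSymbolicRow:
    def test_parameter_application_yields_the_row_bit(self, worked_example):
        encoder = build_encoder(worked_example)
        row = symbolic_row(worked_example, encoder, "B", {"A": 1, "C": 0})
        # row 10 of P, i.e. bit 2; verify by enumerating all 16 parametrisations
        assert row.bdd == encoder.bit("P", 2)
        for p in all_parametrisations(worked_example.parameters):
            expected = p.table("P")[2]
            assert row.contains(encoder.encode(p)) == bool(expected)

    def test_parameter_free_rows_are_constant(self, worked_example):
        encoder = build_encoder(worked_example)
        assert symbolic_row(worked_example, encoder, "C", {"B": 1}).is_empty
        full = symbolic_row(worked_example, encoder, "A", {"A": 1, "B": 1, "C": 1})
        assert full.bdd.is_true


class TestConstraints:
    def test_observability_of_a_parametrised_regulation(self, worked_example):
        encoder = build_encoder(worked_example)
        reg = next(
            r for r in worked_example.regulations if (r.source, r.target) == ("A", "B")
        )
        obs = observability_constraint(worked_example, encoder, reg)
        # brute force: tables differing between rows (0,y) and (1,y) for some y
        expected = sum(
            1
            for t in product((0, 1), repeat=4)
            if t[0] != t[2] or t[1] != t[3]
        )
        # complement (t00==t10 and t01==t11) has 2*2*... = 4 tables, so 12 differ
        assert expected == 12
        assert obs.count() == expected

    def test_activation_of_a_parametrised_regulation(self, worked_example):
        encoder = build_encoder(worked_example)
        reg = next(
            r for r in worked_example.regulations if (r.source, r.target) == ("A", "B")
        )
        mono = monotonicity_constraint(worked_example, encoder, reg)
        expected = sum(
            1
            for t in product((0, 1), repeat=4)
            if t[0] <= t[2] and t[1] <= t[3]
        )
        assert expected == 9
        assert mono.count() == expected

    def test_parameter_free_monotone_regulation_is_unconstraining(self, worked_example):
        encoder = build_encoder(worked_example)
        reg = next(
            r for r in worked_example.regulations if (r.source, r.target) == ("B", "A")
        )
        assert monotonicity_constraint(worked_example, encoder, reg).bdd.is_true
        assert observability_constraint(worked_example, encoder, reg).bdd.is_true

    def test_valid_colours_of_worked_example_are_or_and_and(self, worked_example):
        encoder = build_encoder(worked_example)
        valid = valid_colours(worked_example, encoder)
        assert valid.count() == 2
        tables = {p.table("P") for p in encoder.iter_colours(valid)}
        assert tables == {(0, 1, 1, 1), (0, 0, 0, 1)}

    def test_dropping_observability_grows_the_colour_set(self, worked_example):
        relaxed_regs = [
            Regulation(r.source, r.target, "unknown", r.monotonicity)
            if r.target == "B"
            else r
            for r in worked_example.regulations
        ]
        relaxed = ParametrisedNetwork(
            worked_example.variables,
            relaxed_regs,
            worked_example.parameters,
            worked_example.update,
        )
        encoder = build_encoder(relaxed)
        valid = valid_colours(relaxed, encoder)
        # tables monotone non-decreasing in both arguments: 0000, 1111, x, y, AND, OR
        assert valid.count() == 6


class TestDecode:
    @pytest.mark.parametrize(
        "bits, table",
        [((0, 1, 1, 1), (0, 1, 1, 1)), ((0, 0, 0, 1), (0, 0, 0, 1))],
    )
    def test_decode_reads_rows_in_ascending_order(self, worked_example, bits, table):
        encoder = build_encoder(worked_example)
        assert encoder.decode(Assignment(bits)).table("P") == table

    def test_encode_decode_bijection(self, worked_example):
        encoder = build_encoder(worked_example)
        for p in all_parametrisations(worked_example.parameters):
            assert encoder.decode(encoder.encode(p)) == p


def _semantically_valid(network, p):
    """Definition-level check of every regulation property (oracle)."""
    for reg in network.regulations:
        flips = []
        i = network.variable_index(reg.source)
        expr = network.update[reg.target]
        for state in range(network.num_states):
            if (state >> i) & 1:
                continue
            lo = evaluate(expr, state, network, p)
            hi = evaluate(expr, state | (1 << i), network, p)
            flips.append((lo, hi))
        if reg.observable == "required" and not any(lo != hi for lo, hi in flips):
            return False
        if reg.monotonicity == "activation" and any(lo > hi for lo, hi in flips):
            return False
        if reg.monotonicity == "inhibition" and any(hi > lo for lo, hi in flips):
            return False
    return True


def test_valid_colours_match_the_semantic_definition_exactly():
    for seed in range(12):
        doc = generate_fixture(4, seed=seed, max_parameters=3, max_colours=None)
        n = doc.network
        encoder = build_encoder(n)
        valid = valid_colours(n, encoder)
        for p in all_parametrisations(n.parameters):
            assert valid.contains(encoder.encode(p)) == _semantically_valid(n, p)
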
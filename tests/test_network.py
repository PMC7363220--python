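"""Expression language and network model: parsing, evaluation, instantiation."""

import pytest
from hypothesis import given, settings, strategies as st

from bnbif.expr import (
    App,
    BinOp,
    Const,
    ExprError,
    Not,
    Var,
    parse_expression,
    to_text,
)
from bnbif.network import (
    BooleanNetwork,
    NetworkError,
    ParameterDecl,
    ParametrisedNetwork,
    Parametrisation,
    Regulation,
    all_parametrisations,
    evaluate,
    instantiate,
    validate_network,
)
from tests.conftest import P_AND, P_OR


VARS = frozenset({"A", "B", "C", "D"})
PARAMS = {"P": 2, "Q": 0}


class TestParsing:
    def test_disjunction_of_literals_matches_reference_shape(self):
        e = parse_expression("A | !B | !C", VARS, PARAMS)
        assert e == BinOp("or", Var("A"), BinOp("or", Not(Var("B")), Not(Var("C"))))

    def test_parameter_application(self):
        e = parse_expression("P(A, C)", VARS, PARAMS)
        assert e == App("P", (Var("A"), Var("C")))
        assert parse_expression("Q()", VARS, PARAMS) == App("Q", ())

    def test_arity_mismatch_is_an_error(self):
        with pytest.raises(ExprError, match="arity"):
            parse_expression("P(A)", VARS, PARAMS)

    def test_unknown_identifiers_are_rejected_with_position(self):
        with pytest.raises(ExprError, match="unknown variable"):
            parse_expression("A | X", VARS, PARAMS)
        with pytest.raises(ExprError, match="unknown parameter"):
            parse_expression("R(A)", VARS, PARAMS)

    def test_precedence_not_and_or_xor_imp_iff(self):
        e = parse_expression("!A & B | C ^ D => A <=> B", VARS, PARAMS)
        # iff is weakest, then imp, xor, or, and, not
        assert e == BinOp(
            "iff",
            BinOp(
                "imp",
                BinOp(
                    "xor",
                    BinOp("or", BinOp("and", Not(Var("A")), Var("B")), Var("C")),
                    Var("D"),
                ),
                Var("A"),
            ),
            Var("B"),
        )

    def test_constants_and_parentheses(self):
        assert parse_expression("true & 1", VARS, PARAMS) == BinOp(
            "and", Const(True), Const(True)
        )
        assert parse_expression("(A | B) & C", VARS, PARAMS) == BinOp(
            "and", BinOp("or", Var("A"), Var("B")), Var("C")
        )

    def test_syntax_errors_carry_location(self):
        with pytest.raises(ExprError, match="line 1"):
            parse_expression("A | ", VARS, PARAMS)
        with pytest.raises(ExprError):
            parse_expression("", VARS, PARAMS)


def exprs(max_depth=4):
    leaves = st.one_of(
        st.sampled_from([Var("A"), Var("B"), Var("C")]),
        st.builds(Const, st.booleans()),
        st.builds(lambda a: App("P", (a, Var("C"))), st.sampled_from([Var("A"), Var("B")])),
    )
    return st.recursive(
        leaves,
        lambda children: st.one_of(
            st.builds(Not, children),
            st.builds(
                BinOp,
                st.sampled_from(["and", "or", "xor", "imp", "iff"]),
                children,
                children,
            ),
        ),
        max_leaves=12,
    )


@settings(derandomize=True, max_examples=150)
@given(exprs())
def test_print_parse_round_trip(e):
    assert parse_expression(to_text(e), VARS, PARAMS) == e


class TestEvaluation:
    def setup_method(self):
        self.network = _example_shell()

    def test_concrete_disjunction(self):
        # state "110": A=1, B=1, C=0
        s = self.network.state_from_string("110")
        e = parse_expression("A | !B | !C", VARS, {})
        assert evaluate(e, s, self.network) == 1

    @pytest.mark.parametrize("p, expected", [(P_OR, 1), (P_AND, 0)])
    def test_parameter_application_row_lookup(self, p, expected):
        # P(A, C) at A=1, C=0 looks up row 10 (first argument most significant)
        s = self.network.state_from_string("110")
        e = parse_expression("P(A, C)", VARS, {"P": 2})
        assert evaluate(e, s, self.network, p) == expected

    def test_missing_parameter_interpretation(self):
        e = parse_expression("P(A, C)", VARS, {"P": 2})
        with pytest.raises(NetworkError, match="missing interpretation"):
            evaluate(e, 0, self.network)


def _example_shell():
    names = ("A", "B", "C")
    return ParametrisedNetwork(
        names,
        [Regulation(v, "A", observable="unknown") for v in names],
        [ParameterDecl("P", 2)],
        {
            "A": parse_expression("A | B | C", frozenset(names), {}),
            "B": Const(False),
            "C": Const(False),
        },
    )


class TestInstantiation:
    def test_or_and_tables_give_the_two_reference_networks(self, worked_example):
        bn_or = instantiate(worked_example, P_OR)
        bn_and = instantiate(worked_example, P_AND)
        assert isinstance(bn_or, BooleanNetwork)
        for state in range(8):
            a = worked_example.state_bit(state, "A")
            c = worked_example.state_bit(state, "C")
            assert evaluate(bn_or.update["B"], state, bn_or) == a | c
            assert evaluate(bn_and.update["B"], state, bn_and) == a & c

    def test_instantiating_a_parameter_free_network_is_identity(self, worked_example):
        bn = instantiate(worked_example, P_OR)
        again = instantiate(bn, Parametrisation({}))
        assert again.update == bn.update

    def test_instantiation_commutes_with_evaluation(self):
        """evaluate(instantiate(n, p), s) == evaluate(n, s, p), exhaustively."""
        from bnbif import generate_fixture

        for seed in range(5):
            doc = generate_fixture(4, seed=seed, max_parameters=2, max_colours=256)
            n = doc.network
            for p in all_parametrisations(n.parameters):
                bn = instantiate(n, p)
                for state in range(n.num_states):
                    for name in n.variables:
                        assert evaluate(bn.update[name], state, bn) == evaluate(
                            n.update[name], state, n, p
                        )


class TestValidation:
    def test_worked_example_is_clean(self, worked_example):
        assert validate_network(worked_example) == []

    def test_reference_outside_context_is_reported(self, worked_example):
        n = worked_example
        bad = ParametrisedNetwork(
            n.variables + ("D",),
            n.regulations,
            n.parameters,
            {**n.update, "A": parse_expression("A | !B | !C | D", VARS, {}), "D": Const(False)},
        )
        issues = validate_network(bad)
        assert any(i.kind == "missing-regulation" for i in issues)

    def test_unused_regulation_source_is_reported(self):
        names = ("X", "Y")
        n = ParametrisedNetwork(
            names,
            [Regulation("X", "Y"), Regulation("Y", "Y")],
            [],
            {
                "X": Const(False),
                "Y": parse_expression("Y", frozenset(names), {}),
            },
        )
        issues = validate_network(n)
        assert any(i.kind == "unused-regulation" for i in issues)

    def test_duplicate_regulation_and_undeclared_parameter(self):
        names = ("X",)
        n = ParametrisedNetwork(
            names,
            [Regulation("X", "X"), Regulation("X", "X", observable="unknown")],
            [],
            {"X": App("P", (Var("X"),))},
        )
        kinds = {i.kind for i in validate_network(n)}
        assert "duplicate-regulation" in kinds
        assert "unknown-parameter" in kinds

    def test_source_variable_without_regulators_must_be_constant(self):
        n = ParametrisedNetwork(("X",), [], [], {"X": Const(True)})
        assert validate_network(n) == []


class TestStates:
    def test_printed_state_strings_list_first_variable_first(self, worked_example):
        mask = worked_example.state_from_string("110")
        assert worked_example.state_bit(mask, "A") == 1
        assert worked_example.state_bit(mask, "B") == 1
        assert worked_example.state_bit(mask, "C") == 0
        assert worked_example.state_to_string(mask) == "110"
        assert mask == 0b011  # variable 0 is the least significant bit
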
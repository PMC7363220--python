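"""Built-in example networks used in documentation and tests."""

from __future__ import annotations

from .expr import parse_expression
from .network import ParametrisedNetwork, ParameterDecl, Regulation


def three_variable_example(parametrised: bool = True) -> ParametrisedNetwork:
    """A three-gene toy circuit with one uncertain update function.

    Variables A, B, C with A activating itself and B, B inhibiting A and C,
    and C inhibiting A while activating B.  The concrete update functions
    are ``F_A = A | !B | !C``, ``F_B = A | C`` and ``F_C = !B``.  In the
    parametrised variant the update of B is left as an uninterpreted binary
    function ``P(A, C)``; the activation and observability annotations on
    (A, B) and (C, B) then admit exactly two interpretations of P — OR and
    AND — which bifurcate into a stable fixed point (state 110) and a
    four-state oscillation {100, 101, 111, 110}, respectively.
    """
    variables = ("A", "B", "C")
    regulations = (
        Regulation("A", "A", observable="required", monotonicity="activation"),
        Regulation("B", "A", observable="required", monotonicity="inhibition"),
        Regulation("C", "A", observable="required", monotonicity="inhibition"),
        Regulation("A", "B", observable="required", monotonicity="activation"),
        Regulation("C", "B", observable="required", monotonicity="activation"),
        Regulation("B", "C", observable="required", monotonicity="inhibition"),
    )
    names = frozenset(variables)
    if parametrised:
        parameters = (ParameterDecl("P", 2),)
        update_b = parse_expression("P(A, C)", names, {"P": 2})
    else:
        parameters = ()
        update_b = parse_expression("A | C", names, {})
    update = {
        "A": parse_expression("A | !B | !C", names, {}),
        "B": update_b,
        "C": parse_expression("!B", names, {}),
    }
    return ParametrisedNetwork(variables, regulations, parameters, update)
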
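"""Data model for (parametrised) Boolean networks.

A parametrised Boolean network consists of an ordered list of variables, a
set of regulations with optional observability / monotonicity annotations,
declarations of uninterpreted Boolean functions ("parameters") with fixed
arities, and one update expression per variable.  A plain Boolean network is
the special case with no parameters.

States are integer bit masks in declaration order: bit ``i`` holds the value
of the ``i``-th declared variable.  Printed state strings list the first
declared variable first, so with variables ``A, B, C`` the string ``"110"``
means A=1, B=1, C=0 (mask ``0b011``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator, Mapping, Sequence

from .expr import App, BinOp, Const, Expr, Not, Var, parameters_of, variables_of

OBS_REQUIRED = "required"
OBS_UNKNOWN = "unknown"
ACTIVATION = "activation"
INHIBITION = "inhibition"
MONO_UNKNOWN = "unknown"


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class Regulation:
    """A directed influence ``source -> target``.

    ``observable`` is ``"required"`` (toggling the source must be able to
    toggle the target's update function) or ``"unknown"`` (no constraint).
    ``monotonicity`` is ``"activation"``, ``"inhibition"`` or ``"unknown"``.
    """

    source: str
    target: str
    observable: str = OBS_REQUIRED
    monotonicity: str = MONO_UNKNOWN

    def __post_init__(self) -> None:
        if self.observable not in (OBS_REQUIRED, OBS_UNKNOWN):
            raise NetworkError(f"bad observability flag {self.observable!r}")
        if self.monotonicity not in (ACTIVATION, INHIBITION, MONO_UNKNOWN):
            raise NetworkError(f"bad monotonicity flag {self.monotonicity!r}")


@dataclass(frozen=True)
class ParameterDecl:
    """An uninterpreted Boolean function name with its arity."""

    name: str
    arity: int

    def __post_init__(self) -> None:
        if self.arity < 0:
            raise NetworkError(f"parameter {self.name!r} has negative arity")


@dataclass(frozen=True)
class Parametrisation:
    """An interpretation of every parameter as a concrete truth table.

    Each table is a bit tuple of length ``2**arity``.  Row order is
    lexicographic over the argument values with the *first* argument most
    significant: ``P(a1, ..., ak)`` looks up row ``a1*2^(k-1) + ... + ak``.
    """

    tables: Mapping[str, tuple[int, ...]]

    def table(self, name: str) -> tuple[int, ...]:
        try:
            return self.tables[name]
        except KeyError:
            raise NetworkError(f"missing interpretation for parameter {name!r}") from None


EMPTY_PARAMETRISATION = Parametrisation({})


class ParametrisedNetwork:
    """Variables, regulations, parameter declarations and update expressions."""

    def __init__(
        self,
        variables: Sequence[str],
        regulations: Iterable[Regulation],
        parameters: Iterable[ParameterDecl],
        update: Mapping[str, Expr],
    ):
        self.variables: tuple[str, ...] = tuple(variables)
        if len(set(self.variables)) != len(self.variables):
            raise NetworkError("duplicate variable declaration")
        self.regulations: tuple[Regulation, ...] = tuple(regulations)
        self.parameters: tuple[ParameterDecl, ...] = tuple(parameters)
        if len({p.name for p in self.parameters}) != len(self.parameters):
            raise NetworkError("duplicate parameter declaration")
        self.update: dict[str, Expr] = dict(update)
        self._index = {name: i for i, name in enumerate(self.variables)}
        self._arity = {p.name: p.arity for p in self.parameters}

    # -- simple accessors -----------------------------------------------

    @property
    def num_variables(self) -> int:
        return len(self.variables)

    @property
    def num_states(self) -> int:
        return 1 << len(self.variables)

    def variable_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise NetworkError(f"unknown variable {name!r}") from None

    def parameter_arity(self, name: str) -> int:
        try:
            return self._arity[name]
        except KeyError:
            raise NetworkError(f"unknown parameter {name!r}") from None

    def context(self, variable: str) -> tuple[str, ...]:
        """Regulators of ``variable`` in declaration order."""
        regs = {r.source for r in self.regulations if r.target == variable}
        return tuple(v for v in self.variables if v in regs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParametrisedNetwork):
            return NotImplemented
        return (
            self.variables == other.variables
            and frozenset(self.regulations) == frozenset(other.regulations)
            and frozenset(self.parameters) == frozenset(other.parameters)
            and self.update == other.update
        )

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}(|V|={len(self.variables)}, "
            f"|R|={len(self.regulations)}, |P|={len(self.parameters)})"
        )

    # -- states ----------------------------------------------------------

    def state_bit(self, state: int, variable: str) -> int:
        return (state >> self._index[variable]) & 1

    def state_to_string(self, state: int) -> str:
        return "".join(str((state >> i) & 1) for i in range(len(self.variables)))

    def state_from_string(self, text: str) -> int:
        if len(text) != len(self.variables) or set(text) - {"0", "1"}:
            raise NetworkError(f"bad state string {text!r}")
        return sum(1 << i for i, ch in enumerate(text) if ch == "1")


class BooleanNetwork(ParametrisedNetwork):
    """A fully instantiated network: no parameters anywhere."""

    def __init__(self, variables, regulations, update):
        super().__init__(variables, regulations, (), update)
        for name, expr in self.update.items():
            if parameters_of(expr):
                raise NetworkError(
                    f"update of {name!r} still contains uninterpreted functions"
                )


def evaluate(
    e: Expr,
    state: int,
    network: ParametrisedNetwork,
    parametrisation: Parametrisation = EMPTY_PARAMETRISATION,
) -> int:
    """Evaluate an update expression at a state under a parametrisation."""
    if isinstance(e, Const):
        return int(e.value)
    if isinstance(e, Var):
        return network.state_bit(state, e.name)
    if isinstance(e, Not):
        return 1 - evaluate(e.operand, state, network, parametrisation)
    if isinstance(e, BinOp):
        left = evaluate(e.left, state, network, parametrisation)
        right = evaluate(e.right, state, network, parametrisation)
        if e.op == "and":
            return left & right
        if e.op == "or":
            return left | right
        if e.op == "xor":
            return left ^ right
        if e.op == "imp":
            return (1 - left) | right
        if e.op == "iff":
            return 1 - (left ^ right)
        raise NetworkError(f"unknown operator {e.op!r}")
    if isinstance(e, App):
        row = 0
        for arg in e.args:
            row = (row << 1) | evaluate(arg, state, network, parametrisation)
        table = parametrisation.table(e.param)
        if len(table) != 1 << len(e.args):
            raise NetworkError(
                f"table for {e.param!r} has {len(table)} rows, expected {1 << len(e.args)}"
            )
        return table[row]
    raise NetworkError(f"not an expression node: {e!r}")


def _minterm_expansion(app: App, table: tuple[int, ...]) -> Expr:
    """DNF over the rows of the table where the function is 1.

    The first argument is the most significant row bit.  An all-zero table
    yields constant false.
    """
    k = len(app.args)
    terms: list[Expr] = []
    for row, value in enumerate(table):
        if not value:
            continue
        literals: list[Expr] = []
        for i, arg in enumerate(app.args):
            bit = (row >> (k - 1 - i)) & 1
            literals.append(arg if bit else Not(arg))
        if not literals:
            term: Expr = Const(True)
        else:
            term = literals[-1]
            for lit in reversed(literals[:-1]):
                term = BinOp("and", lit, term)
        terms.append(term)
    if not terms:
        return Const(False)
    out = terms[-1]
    for term in reversed(terms[:-1]):
        out = BinOp("or", term, out)
    return out


def _substitute(e: Expr, p: Parametrisation) -> Expr:
    if isinstance(e, (Const, Var)):
        return e
    if isinstance(e, Not):
        return Not(_substitute(e.operand, p))
    if isinstance(e, BinOp):
        return BinOp(e.op, _substitute(e.left, p), _substitute(e.right, p))
    if isinstance(e, App):
        inner = App(e.param, tuple(_substitute(a, p) for a in e.args))
        return _minterm_expansion(inner, p.table(e.param))
    raise NetworkError(f"not an expression node: {e!r}")


def instantiate(n: ParametrisedNetwork, p: Parametrisation) -> BooleanNetwork:
    """The p-instantiation: replace every parameter application by the
    minterm expansion of its truth table."""
    for decl in n.parameters:
        table = p.table(decl.name)
        if len(table) != 1 << decl.arity:
            raise NetworkError(
                f"table for {decl.name!r} has {len(table)} rows, expected {1 << decl.arity}"
            )
    update = {name: _substitute(expr, p) for name, expr in n.update.items()}
    return BooleanNetwork(n.variables, n.regulations, update)


@dataclass(frozen=True)
class Issue:
    """One finding of :func:`validate_network` (all findings are errors)."""

    kind: str
    message: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.message}"


def validate_network(n: ParametrisedNetwork) -> list[Issue]:
    """Static integrity checks; an empty list means the network is well-formed.

    Checks that every variable has exactly one update expression, that the
    regulators of each variable are exactly the variables its update
    expression references, that regulations are unique, that every applied
    parameter is declared with a consistent arity, and that variables with
    an empty context have constant update expressions.
    """
    issues: list[Issue] = []
    declared = set(n.variables)

    seen_pairs: set[tuple[str, str]] = set()
    for reg in n.regulations:
        pair = (reg.source, reg.target)
        if pair in seen_pairs:
            issues.append(Issue("duplicate-regulation", f"regulation {reg.source} -> {reg.target} declared twice"))
        seen_pairs.add(pair)
        for endpoint in pair:
            if endpoint not in declared:
                issues.append(Issue("unknown-variable", f"regulation endpoint {endpoint!r} is not a declared variable"))

    missing = declared - set(n.update)
    for name in sorted(missing):
        issues.append(Issue("missing-update", f"variable {name!r} has no update expression"))
    for name in sorted(set(n.update) - declared):
        issues.append(Issue("unknown-variable", f"update declared for unknown variable {name!r}"))

    declared_params = {p.name: p.arity for p in n.parameters}
    for name in n.variables:
        expr = n.update.get(name)
        if expr is None:
            continue
        context = set(n.context(name))
        refs = variables_of(expr)
        for ref in sorted(refs - declared):
            issues.append(Issue("unknown-variable", f"update of {name!r} references unknown identifier {ref!r}"))
        for ref in sorted((refs & declared) - context):
            issues.append(
                Issue(
                    "missing-regulation",
                    f"update of {name!r} references {ref!r} but there is no regulation ({ref}, {name})",
                )
            )
        for src in sorted(context - refs):
            issues.append(
                Issue(
                    "unused-regulation",
                    f"regulation ({src}, {name}) declared but {src!r} never appears in the update of {name!r}",
                )
            )
        try:
            used_params = parameters_of(expr)
        except ValueError as exc:
            issues.append(Issue("arity-mismatch", f"update of {name!r}: {exc}"))
            used_params = {}
        for pname, arity in sorted(used_params.items()):
            if pname not in declared_params:
                issues.append(Issue("unknown-parameter", f"update of {name!r} applies undeclared parameter {pname!r}"))
            elif declared_params[pname] != arity:
                issues.append(
                    Issue(
                        "arity-mismatch",
                        f"parameter {pname!r} declared with arity {declared_params[pname]}, "
                        f"applied to {arity} argument(s) in the update of {name!r}",
                    )
                )
        if not context and not used_params and expr is not None and refs & declared == set():
            if not _is_constant(expr):
                issues.append(
                    Issue(
                        "non-constant-source",
                        f"variable {name!r} has no regulators; its update expression must be constant",
                    )
                )
    return issues


def _is_constant(e: Expr) -> bool:
    return not variables_of(e) and not parameters_of(e)


def all_parametrisations(parameters: Sequence[ParameterDecl]) -> Iterator[Parametrisation]:
    """Enumerate every interpretation of the declared parameters (test/oracle use)."""
    names = [p.name for p in parameters]
    spaces = [list(product((0, 1), repeat=1 << p.arity)) for p in parameters]
    for combo in product(*spaces):
        yield Parametrisation(dict(zip(names, combo)))
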
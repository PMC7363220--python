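"""Symbolic encoding of parametrisation sets ("colours") as BDDs.

Each parameter with arity ``a`` contributes ``2**a`` decision bits, one per
truth-table row.  Bits are allocated contiguously per parameter, parameters
in declaration order, rows ascending, which makes the mapping between BDD
assignments and parametrisations a bijection.

Regulation properties become constraints over these bits: observability of a
regulation (B, A) says there is a context where toggling B toggles the
update function of A; activation (inhibition) says the update function is
monotone non-decreasing (non-increasing) in B.  The conjunction over all
annotated regulations is the set of *valid* colours.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Mapping

from . import bdd as _bdd
from .bdd import Assignment, Bdd
from .expr import App, BinOp, Const, Expr, Not, Var
from .network import (
    ACTIVATION,
    INHIBITION,
    MONO_UNKNOWN,
    OBS_REQUIRED,
    NetworkError,
    ParametrisedNetwork,
    Parametrisation,
    Regulation,
)

DEFAULT_ARITY_CAP = 8
DEFAULT_CONTEXT_CAP = 16


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class ColourSet:
    """A set of parametrisations, represented by a BDD over parameter bits."""

    bdd: Bdd

    def __and__(self, other: "ColourSet") -> "ColourSet":
        return ColourSet(self.bdd & other.bdd)

    def __or__(self, other: "ColourSet") -> "ColourSet":
        return ColourSet(self.bdd | other.bdd)

    def __sub__(self, other: "ColourSet") -> "ColourSet":
        return ColourSet(self.bdd & ~other.bdd)

    @property
    def is_empty(self) -> bool:
        return self.bdd.is_false

    def count(self) -> int:
        return _bdd.sat_count(self.bdd)

    def pick(self) -> Assignment:
        """Lexicographically smallest member (deterministic witness choice)."""
        return _bdd.pick_sat(self.bdd)

    def contains(self, a: Assignment) -> bool:
        return self.bdd.evaluate(a)

    def serialize(self) -> bytes:
        return _bdd.serialize(self.bdd)


class ParameterEncoder:
    """Deterministic bit layout for the parameters of one network."""

    def __init__(self, network: ParametrisedNetwork, arity_cap: int = DEFAULT_ARITY_CAP):
        self.network = network
        layout: dict[tuple[str, int], int] = {}
        bits: list[tuple[str, int]] = []
        for decl in network.parameters:
            if decl.arity > arity_cap:
                raise EncodingError(
                    f"parameter {decl.name!r} has arity {decl.arity}, above the cap "
                    f"{arity_cap}; its truth table would need {1 << decl.arity} bits"
                )
            for row in range(1 << decl.arity):
                layout[(decl.name, row)] = len(bits)
                bits.append((decl.name, row))
        self.bit_layout: dict[tuple[str, int], int] = layout
        self.bits: tuple[tuple[str, int], ...] = tuple(bits)
        self.num_bits: int = len(bits)

    # -- basic sets ------------------------------------------------------

    def empty(self) -> ColourSet:
        return ColourSet(_bdd.mk_const(False, self.num_bits))

    def universe(self) -> ColourSet:
        return ColourSet(_bdd.mk_const(True, self.num_bits))

    def bit(self, parameter: str, row: int) -> Bdd:
        try:
            index = self.bit_layout[(parameter, row)]
        except KeyError:
            raise EncodingError(f"no bit for parameter {parameter!r} row {row}") from None
        return _bdd.mk_var(index, self.num_bits)

    # -- parametrisation <-> assignment bijection ------------------------

    def decode(self, a: Assignment) -> Parametrisation:
        if len(a) != self.num_bits:
            raise EncodingError("assignment width does not match the encoder")
        tables: dict[str, list[int]] = {p.name: [0] * (1 << p.arity) for p in self.network.parameters}
        for index, (name, row) in enumerate(self.bits):
            tables[name][row] = a[index]
        return Parametrisation({name: tuple(rows) for name, rows in tables.items()})

    def encode(self, p: Parametrisation) -> Assignment:
        values = [0] * self.num_bits
        for index, (name, row) in enumerate(self.bits):
            values[index] = p.table(name)[row]
        return Assignment(tuple(values))

    def iter_colours(self, colours: ColourSet) -> Iterator[Parametrisation]:
        """Enumerate members of a colour set (test/oracle scale only)."""
        for mask in range(1 << self.num_bits):
            a = Assignment(tuple((mask >> i) & 1 for i in range(self.num_bits)))
            if colours.contains(a):
                yield self.decode(a)


def build_encoder(network: ParametrisedNetwork, arity_cap: int = DEFAULT_ARITY_CAP) -> ParameterEncoder:
    return ParameterEncoder(network, arity_cap)


def symbolic_row(
    network: ParametrisedNetwork,
    encoder: ParameterEncoder,
    variable: str,
    ctx: Mapping[str, int],
) -> ColourSet:
    """Colours under which the update function of ``variable`` is 1 on ``ctx``.

    ``ctx`` assigns a Boolean value to every regulator of ``variable``.  The
    result is computed by structural recursion: a parameter application
    contributes the decision bit of its (parameter, row) pair.
    """
    expr = network.update[variable]
    n = encoder.num_bits

    def rec(e: Expr) -> Bdd:
        if isinstance(e, Const):
            return _bdd.mk_const(e.value, n)
        if isinstance(e, Var):
            try:
                value = ctx[e.name]
            except KeyError:
                raise EncodingError(
                    f"context for {variable!r} does not assign {e.name!r}"
                ) from None
            return _bdd.mk_const(bool(value), n)
        if isinstance(e, Not):
            return ~rec(e.operand)
        if isinstance(e, BinOp):
            return _bdd.apply(e.op, rec(e.left), rec(e.right))
        if isinstance(e, App):
            arg_bdds = [rec(a) for a in e.args]
            k = len(arg_bdds)
            out = _bdd.mk_const(False, n)
            for row in range(1 << k):
                term = encoder.bit(e.param, row)
                for i, ab in enumerate(arg_bdds):
                    literal = ab if (row >> (k - 1 - i)) & 1 else ~ab
                    term = term & literal
                out = out | term
            return out
        raise EncodingError(f"not an expression node: {e!r}")

    return ColourSet(rec(expr))


def _context_rows(
    network: ParametrisedNetwork, variable: str, context_cap: int
) -> Iterator[dict[str, int]]:
    context = network.context(variable)
    if len(context) > context_cap:
        raise EncodingError(
            f"variable {variable!r} has {len(context)} regulators; constraint "
            f"construction enumerates 2^|context| rows and is capped at {context_cap}"
        )
    for bits in product((0, 1), repeat=len(context)):
        yield dict(zip(context, bits))


def observability_constraint(
    network: ParametrisedNetwork,
    encoder: ParameterEncoder,
    reg: Regulation,
    context_cap: int = DEFAULT_CONTEXT_CAP,
) -> ColourSet:
    """Colours where some context exists in which toggling the source toggles
    the target's update function."""
    context = network.context(reg.target)
    if reg.source not in context:
        return encoder.empty()
    others = [v for v in context if v != reg.source]
    if len(others) + 1 > context_cap:
        raise EncodingError(
            f"variable {reg.target!r} has too many regulators for constraint "
            f"construction (cap {context_cap})"
        )
    out = _bdd.mk_const(False, encoder.num_bits)
    for bits in product((0, 1), repeat=len(others)):
        ctx = dict(zip(others, bits))
        row0 = symbolic_row(network, encoder, reg.target, {**ctx, reg.source: 0})
        row1 = symbolic_row(network, encoder, reg.target, {**ctx, reg.source: 1})
        out = out | (row0.bdd ^ row1.bdd)
    return ColourSet(out)


def monotonicity_constraint(
    network: ParametrisedNetwork,
    encoder: ParameterEncoder,
    reg: Regulation,
    context_cap: int = DEFAULT_CONTEXT_CAP,
) -> ColourSet:
    """Colours where the target's update function is monotone in the source:
    non-decreasing for activation, non-increasing for inhibition."""
    if reg.monotonicity == MONO_UNKNOWN:
        raise EncodingError("monotonicity constraint requested for an unannotated regulation")
    context = network.context(reg.target)
    if reg.source not in context:
        # the source has no syntactic influence, hence trivially monotone
        return encoder.universe()
    others = [v for v in context if v != reg.source]
    if len(others) + 1 > context_cap:
        raise EncodingError(
            f"variable {reg.target!r} has too many regulators for constraint "
            f"construction (cap {context_cap})"
        )
    out = _bdd.mk_const(True, encoder.num_bits)
    for bits in product((0, 1), repeat=len(others)):
        ctx = dict(zip(others, bits))
        row0 = symbolic_row(network, encoder, reg.target, {**ctx, reg.source: 0})
        row1 = symbolic_row(network, encoder, reg.target, {**ctx, reg.source: 1})
        if reg.monotonicity == ACTIVATION:
            out = out & row0.bdd.imp(row1.bdd)
        else:
            out = out & row1.bdd.imp(row0.bdd)
    return ColourSet(out)


def valid_colours(
    network: ParametrisedNetwork,
    encoder: ParameterEncoder,
    context_cap: int = DEFAULT_CONTEXT_CAP,
) -> ColourSet:
    """Conjunction of every declared regulation property."""
    out = encoder.universe()
    for reg in network.regulations:
        if reg.observable == OBS_REQUIRED:
            out = out & observability_constraint(network, encoder, reg, context_cap)
        if reg.monotonicity != MONO_UNKNOWN:
            out = out & monotonicity_constraint(network, encoder, reg, context_cap)
    return out
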
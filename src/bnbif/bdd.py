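"""Reduced ordered binary decision diagrams over a fixed variable universe.

This is a small, self-contained ROBDD implementation used to represent sets
of parametrisations ("colours") of a parametrised Boolean network.  Every
``Bdd`` is a standalone object: it carries its own node table rather than
living inside a shared manager.  The table is kept in a *canonical* order
(post-order depth-first traversal from the root, low child before high
child), so two ``Bdd`` objects over the same variable universe represent the
same Boolean function if and only if they compare equal — and if and only if
their serialized forms are byte-identical.

Node references are indices into the table.  Index ``0`` is the FALSE
terminal and index ``1`` the TRUE terminal; terminals carry the sentinel
variable index ``num_vars`` so that variable indices strictly increase on
every root-to-terminal path.

The variable order is fixed at creation; there is no dynamic reordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

FALSE = 0
TRUE = 1

__all__ = [
    "Bdd",
    "Assignment",
    "BddError",
    "mk_const",
    "mk_var",
    "apply",
    "negate",
    "exists",
    "sat_count",
    "pick_sat",
    "serialize",
    "deserialize",
]


class BddError(ValueError):
    """Raised for malformed operations or serialized input."""


@dataclass(frozen=True)
class Assignment:
    """A total valuation of the declared decision variables (0/1 per bit)."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(v not in (0, 1) for v in self.values):
            raise BddError("assignment values must be 0 or 1")

    def __getitem__(self, index: int) -> int:
        return self.values[index]

    def __len__(self) -> int:
        return len(self.values)


_BIN_OPS: dict[str, Callable[[int, int], int]] = {
    "and": lambda x, y: x & y,
    "or": lambda x, y: x | y,
    "xor": lambda x, y: x ^ y,
    "imp": lambda x, y: (1 - x) | y,
    "iff": lambda x, y: 1 - (x ^ y),
}


class _Builder:
    """Append-only node table with structural hashing (hash-consing)."""

    __slots__ = ("num_vars", "nodes", "unique")

    def __init__(self, num_vars: int) -> None:
        self.num_vars = num_vars
        self.nodes: list[tuple[int, int, int]] = [
            (num_vars, FALSE, FALSE),
            (num_vars, TRUE, TRUE),
        ]
        self.unique: dict[tuple[int, int, int], int] = {}

    def mk(self, var: int, low: int, high: int) -> int:
        if low == high:
            return low
        key = (var, low, high)
        ref = self.unique.get(key)
        if ref is None:
            ref = len(self.nodes)
            self.nodes.append(key)
            self.unique[key] = ref
        return ref


def _canonical(num_vars: int, nodes: Sequence[tuple[int, int, int]], root: int) -> tuple[tuple[tuple[int, int, int], ...], int]:
    """Renumber nodes in canonical (post-order, low-first) traversal order."""
    base = [(num_vars, FALSE, FALSE), (num_vars, TRUE, TRUE)]
    if root < 2:
        return tuple(base), root
    remap: dict[int, int] = {FALSE: FALSE, TRUE: TRUE}
    out = base
    stack: list[tuple[int, bool]] = [(root, False)]
    while stack:
        u, done = stack.pop()
        if u in remap:
            continue
        var, low, high = nodes[u]
        if done:
            remap[u] = len(out)
            out.append((var, remap[low], remap[high]))
        else:
            stack.append((u, True))
            stack.append((high, False))
            stack.append((low, False))
    return tuple(out), remap[root]


class Bdd:
    """A reduced ordered BDD with a canonical, standalone node table."""

    __slots__ = ("num_vars", "nodes", "root")

    def __init__(self, num_vars: int, nodes: Sequence[tuple[int, int, int]], root: int):
        self.num_vars = num_vars
        self.nodes, self.root = _canonical(num_vars, nodes, root)

    # -- constructors ---------------------------------------------------

    @staticmethod
    def const(value: bool, num_vars: int) -> "Bdd":
        if num_vars < 0:
            raise BddError("num_vars must be non-negative")
        return Bdd(num_vars, (), TRUE if value else FALSE)

    @staticmethod
    def var(index: int, num_vars: int) -> "Bdd":
        if not 0 <= index < num_vars:
            raise BddError(f"variable index {index} out of range [0, {num_vars})")
        b = _Builder(num_vars)
        root = b.mk(index, FALSE, TRUE)
        return Bdd(num_vars, b.nodes, root)

    # -- basic queries --------------------------------------------------

    @property
    def is_false(self) -> bool:
        return self.root == FALSE

    @property
    def is_true(self) -> bool:
        return self.root == TRUE

    def evaluate(self, assignment: Assignment | Sequence[int]) -> bool:
        values = assignment.values if isinstance(assignment, Assignment) else tuple(assignment)
        if len(values) != self.num_vars:
            raise BddError("assignment arity does not match num_vars")
        u = self.root
        while u > TRUE:
            var, low, high = self.nodes[u]
            u = high if values[var] else low
        return u == TRUE

    # -- structural equality / hashing ----------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bdd):
            return NotImplemented
        return (
            self.num_vars == other.num_vars
            and self.root == other.root
            and self.nodes == other.nodes
        )

    def __hash__(self) -> int:
        return hash((self.num_vars, self.root, self.nodes))

    def __repr__(self) -> str:
        return f"Bdd(num_vars={self.num_vars}, nodes={len(self.nodes) - 2}, root={self.root})"

    # -- operator sugar (delegates to module-level functions) ------------

    def __and__(self, other: "Bdd") -> "Bdd":
        return apply("and", self, other)

    def __or__(self, other: "Bdd") -> "Bdd":
        return apply("or", self, other)

    def __xor__(self, other: "Bdd") -> "Bdd":
        return apply("xor", self, other)

    def __invert__(self) -> "Bdd":
        return negate(self)

    def imp(self, other: "Bdd") -> "Bdd":
        return apply("imp", self, other)

    def iff(self, other: "Bdd") -> "Bdd":
        return apply("iff", self, other)


def mk_const(value: bool, num_vars: int) -> Bdd:
    """The constant-true or constant-false function over ``num_vars`` bits."""
    return Bdd.const(value, num_vars)


def mk_var(index: int, num_vars: int) -> Bdd:
    """The projection function "variable ``index`` is 1"."""
    return Bdd.var(index, num_vars)


def apply(op: str, a: Bdd, b: Bdd) -> Bdd:
    """Combine two BDDs with a binary connective (``and``/``or``/``xor``/``imp``/``iff``)."""
    try:
        fn = _BIN_OPS[op]
    except KeyError:
        raise BddError(f"unknown operator {op!r}") from None
    if a.num_vars != b.num_vars:
        raise BddError(
            f"mismatched variable universes: {a.num_vars} vs {b.num_vars}"
        )
    n = a.num_vars
    builder = _Builder(n)
    memo: dict[tuple[int, int], int] = {}
    an, bn = a.nodes, b.nodes

    def rec(u: int, v: int) -> int:
        if u <= TRUE and v <= TRUE:
            return fn(u, v)
        key = (u, v)
        res = memo.get(key)
        if res is not None:
            return res
        uvar = an[u][0]
        vvar = bn[v][0]
        var = uvar if uvar < vvar else vvar
        u0, u1 = (an[u][1], an[u][2]) if uvar == var else (u, u)
        v0, v1 = (bn[v][1], bn[v][2]) if vvar == var else (v, v)
        res = builder.mk(var, rec(u0, v0), rec(u1, v1))
        memo[key] = res
        return res

    root = rec(a.root, b.root)
    return Bdd(n, builder.nodes, root)


def negate(a: Bdd) -> Bdd:
    """Complement; ``negate(negate(a)) == a``."""
    if a.root <= TRUE:
        return Bdd.const(a.root == FALSE, a.num_vars)
    swap = {FALSE: TRUE, TRUE: FALSE}
    nodes = [
        (var, swap.get(low, low), swap.get(high, high))
        for var, low, high in a.nodes
    ]
    return Bdd(a.num_vars, nodes, a.root)


def restrict(a: Bdd, index: int, value: int) -> Bdd:
    """Cofactor: fix one variable to a constant."""
    if not 0 <= index < a.num_vars:
        raise BddError(f"variable index {index} out of range [0, {a.num_vars})")
    builder = _Builder(a.num_vars)
    memo: dict[int, int] = {}

    def rec(u: int) -> int:
        if u <= TRUE:
            return u
        res = memo.get(u)
        if res is not None:
            return res
        var, low, high = a.nodes[u]
        if var == index:
            res = rec(high if value else low)
        else:
            res = builder.mk(var, rec(low), rec(high))
        memo[u] = res
        return res

    return Bdd(a.num_vars, builder.nodes, rec(a.root))


def exists(a: Bdd, variables: Iterable[int]) -> Bdd:
    """Existential quantification over a set of variable indices."""
    result = a
    for index in sorted(set(variables), reverse=True):
        if not 0 <= index < a.num_vars:
            raise BddError(f"variable index {index} out of range [0, {a.num_vars})")
        result = apply("or", restrict(result, index, 0), restrict(result, index, 1))
    return result


def sat_count(a: Bdd) -> int:
    """Exact number of satisfying assignments over all declared variables."""
    n = a.num_vars
    if a.root <= TRUE:
        return (1 << n) if a.root == TRUE else 0
    memo: dict[int, int] = {FALSE: 0, TRUE: 1}

    def count(u: int) -> int:
        # number of satisfying assignments over variables >= var(u)
        res = memo.get(u)
        if res is not None:
            return res
        var, low, high = a.nodes[u]
        lo = count(low) << (a.nodes[low][0] - var - 1)
        hi = count(high) << (a.nodes[high][0] - var - 1)
        res = lo + hi
        memo[u] = res
        return res

    return count(a.root) << a.nodes[a.root][0]


def pick_sat(a: Bdd) -> Assignment:
    """The lexicographically smallest satisfying assignment (0 before 1).

    Variables are compared in index order; variables that do not constrain
    the function take value 0.
    """
    if a.root == FALSE:
        raise BddError("no witness exists: the set is empty")
    bits = [0] * a.num_vars
    u = a.root
    while u != TRUE:
        var, low, high = a.nodes[u]
        if low != FALSE:
            u = low
        else:
            bits[var] = 1
            u = high
    return Assignment(tuple(bits))


_MAGIC = "bnbdd"


def serialize(a: Bdd) -> bytes:
    """Stable text serialization (UTF-8).

    Format: ``bnbdd <num_vars> <num_nodes> <root>`` followed by one
    ``<var> <low> <high>`` triple per non-terminal node in canonical table
    order (indices 2, 3, ...).  The two terminal nodes are implicit.  The
    constant-false function is always ``b"bnbdd <n> 0 0"``.
    """
    parts = [_MAGIC, str(a.num_vars), str(len(a.nodes) - 2), str(a.root)]
    for var, low, high in a.nodes[2:]:
        parts.append(f"{var} {low} {high}")
    return " ".join(parts).encode("utf-8")


def deserialize(data: bytes | str) -> Bdd:
    """Inverse of :func:`serialize`; rejects malformed input with the token position."""
    text = data.decode("utf-8") if isinstance(data, bytes) else data
    tokens = text.split()

    def need(pos: int, what: str) -> str:
        if pos >= len(tokens):
            raise BddError(f"truncated BDD serialization: expected {what} at token {pos}")
        return tokens[pos]

    def need_int(pos: int, what: str) -> int:
        tok = need(pos, what)
        try:
            return int(tok)
        except ValueError:
            raise BddError(f"malformed BDD serialization: bad {what} {tok!r} at token {pos}") from None

    if need(0, "magic header") != _MAGIC:
        raise BddError(f"malformed BDD serialization: bad magic {tokens[0]!r} at token 0")
    num_vars = need_int(1, "variable count")
    num_nodes = need_int(2, "node count")
    root = need_int(3, "root reference")
    if num_vars < 0 or num_nodes < 0:
        raise BddError("malformed BDD serialization: negative header field")
    nodes: list[tuple[int, int, int]] = [
        (num_vars, FALSE, FALSE),
        (num_vars, TRUE, TRUE),
    ]
    seen: set[tuple[int, int, int]] = set()
    pos = 4
    for i in range(num_nodes):
        index = i + 2
        var = need_int(pos, "node variable")
        low = need_int(pos + 1, "low reference")
        high = need_int(pos + 2, "high reference")
        if not 0 <= var < num_vars:
            raise BddError(f"malformed BDD serialization: variable {var} out of range at token {pos}")
        for ref in (low, high):
            if not 0 <= ref < index:
                raise BddError(
                    f"malformed BDD serialization: forward/invalid reference {ref} at token {pos}"
                )
            if ref > TRUE and nodes[ref][0] <= var:
                raise BddError(
                    f"malformed BDD serialization: variable order violated at token {pos}"
                )
        if low == high:
            raise BddError(f"malformed BDD serialization: redundant node at token {pos}")
        triple = (var, low, high)
        if triple in seen:
            raise BddError(f"malformed BDD serialization: duplicate node at token {pos}")
        seen.add(triple)
        nodes.append(triple)
        pos += 3
    if pos != len(tokens):
        raise BddError(f"malformed BDD serialization: trailing data at token {pos}")
    if not 0 <= root < len(nodes):
        raise BddError("malformed BDD serialization: root reference out of range")
    return Bdd(num_vars, nodes, root)
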
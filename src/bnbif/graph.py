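"""Semi-symbolic edge-coloured asynchronous state transition graph.

States are explicit integer masks; the parametrisations ("colours") under
which a transition exists are symbolic (a :class:`ColourSet`).  Under the
asynchronous update scheme one variable changes per transition: ``s -> t``
with colour ``c`` iff ``t`` differs from ``s`` in exactly one variable ``A``
and the update function of ``A`` evaluates to the flipped value at ``s``
under ``c``.  Self-loops are never produced.

Successor generation is on the fly from a per-variable row cache: for each
variable we precompute, for every assignment of its regulators, the colour
set under which its update function is 1.  All colour sets handed out are
restricted to the valid colours of the network.
"""

from __future__ import annotations

import heapq
from typing import Iterable, Iterator, Mapping

from . import bdd as _bdd
from .bdd import Bdd
from .encoding import (
    DEFAULT_ARITY_CAP,
    DEFAULT_CONTEXT_CAP,
    ColourSet,
    ParameterEncoder,
    build_encoder,
    symbolic_row,
    valid_colours,
)
from .network import ParametrisedNetwork, validate_network

DEFAULT_STATE_LIMIT = 1 << 22


class GraphError(ValueError):
    pass


class ColouredStateSet:
    """A mapping state -> non-empty ColourSet (the semi-symbolic set type)."""

    __slots__ = ("_entries",)

    def __init__(self, entries: Mapping[int, ColourSet] | Iterable[tuple[int, ColourSet]] = ()):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._entries: dict[int, ColourSet] = {
            s: c for s, c in items if not c.is_empty
        }

    def get(self, state: int) -> ColourSet | None:
        return self._entries.get(state)

    def states(self) -> list[int]:
        return sorted(self._entries)

    def items(self) -> Iterator[tuple[int, ColourSet]]:
        return iter(sorted(self._entries.items()))

    def __contains__(self, state: int) -> bool:
        return state in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __bool__(self) -> bool:
        return bool(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ColouredStateSet):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        return f"ColouredStateSet({len(self._entries)} states)"


class ColouredGraph:
    """The edge-coloured asynchronous state transition graph of a network."""

    def __init__(
        self,
        network: ParametrisedNetwork,
        state_limit: int = DEFAULT_STATE_LIMIT,
        arity_cap: int = DEFAULT_ARITY_CAP,
        context_cap: int = DEFAULT_CONTEXT_CAP,
    ):
        issues = validate_network(network)
        if issues:
            raise GraphError(
                "network failed validation: " + "; ".join(str(i) for i in issues)
            )
        if network.num_states > state_limit:
            raise GraphError(
                f"network has 2^{network.num_variables} states, above the explicit "
                f"state limit {state_limit}; raise state_limit to proceed"
            )
        self.network = network
        self.encoder: ParameterEncoder = build_encoder(network, arity_cap)
        self.valid: ColourSet = valid_colours(network, self.encoder, context_cap)

        # row_cache[i][ctx_index] = colours under which F_i evaluates to 1,
        # ctx_index packing the regulator bits ascending by variable index.
        self._ctx_indices: list[list[int]] = []
        self._row_cache: list[list[Bdd]] = []
        for name in network.variables:
            ctx = [network.variable_index(v) for v in network.context(name)]
            cache: list[Bdd] = []
            for mask in range(1 << len(ctx)):
                assignment = {
                    network.variables[v]: (mask >> j) & 1 for j, v in enumerate(ctx)
                }
                cache.append(symbolic_row(network, self.encoder, name, assignment).bdd)
            self._ctx_indices.append(ctx)
            self._row_cache.append(cache)

    # -- raw successor colours -------------------------------------------

    def _ctx_key(self, variable: int, state: int) -> int:
        key = 0
        for j, v in enumerate(self._ctx_indices[variable]):
            key |= ((state >> v) & 1) << j
        return key

    def _flip_colours(self, state: int, variable: int) -> Bdd:
        """Colours (unrestricted) under which ``variable`` is enabled at ``state``."""
        on = self._row_cache[variable][self._ctx_key(variable, state)]
        return ~on if (state >> variable) & 1 else on

    def enabled_colours(self, state: int, variable: int) -> ColourSet:
        """Valid colours under which flipping ``variable`` is a transition."""
        return ColourSet(self._flip_colours(state, variable) & self.valid.bdd)

    # -- public edge relations -------------------------------------------

    def successors(self, state: int) -> list[tuple[str, int, ColourSet]]:
        """One ``(variable, target, colours)`` triple per enabled variable."""
        out = []
        for i, name in enumerate(self.network.variables):
            colours = self.enabled_colours(state, i)
            if not colours.is_empty:
                out.append((name, state ^ (1 << i), colours))
        return out

    def predecessors(self, state: int) -> list[tuple[str, int, ColourSet]]:
        """Triples ``(variable, source, colours)`` with ``source -> state``."""
        out = []
        for i, name in enumerate(self.network.variables):
            source = state ^ (1 << i)
            # t -> s by flipping i means F_i(t) equals s's bit for i
            on = self._row_cache[i][self._ctx_key(i, source)]
            colours_bdd = on if (state >> i) & 1 else ~on
            colours = ColourSet(colours_bdd & self.valid.bdd)
            if not colours.is_empty:
                out.append((name, source, colours))
        return out

    # -- reachability ------------------------------------------------------

    def _reach(
        self,
        seed: ColouredStateSet,
        within: ColouredStateSet | None,
        forward: bool,
    ) -> ColouredStateSet:
        result: dict[int, ColourSet] = {}
        heap: list[int] = []
        pending: set[int] = set()
        for s, c in seed.items():
            if within is not None:
                limit = within.get(s)
                if limit is None:
                    continue
                c = c & limit
                if c.is_empty:
                    continue
            result[s] = c
            heapq.heappush(heap, s)
            pending.add(s)
        step = self.successors if forward else self.predecessors
        while heap:
            s = heapq.heappop(heap)
            if s not in pending:
                continue
            pending.discard(s)
            base = result[s]
            for _, t, colours in step(s):
                new = base & colours
                if within is not None:
                    limit = within.get(t)
                    if limit is None:
                        continue
                    new = new & limit
                if new.is_empty:
                    continue
                old = result.get(t)
                merged = new if old is None else old | new
                if old is None or merged != old:
                    result[t] = merged
                    if t not in pending:
                        heapq.heappush(heap, t)
                        pending.add(t)
        return ColouredStateSet(result)

    def fwd_reach(
        self, seed: ColouredStateSet, within: ColouredStateSet | None = None
    ) -> ColouredStateSet:
        """Least fixed point of colour-wise forward closure from ``seed``."""
        return self._reach(seed, within, forward=True)

    def bwd_reach(
        self, seed: ColouredStateSet, within: ColouredStateSet | None = None
    ) -> ColouredStateSet:
        """Least fixed point of colour-wise backward closure from ``seed``."""
        return self._reach(seed, within, forward=False)
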
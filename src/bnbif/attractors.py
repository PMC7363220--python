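"""Attractor detection: terminal SCCs of the coloured asynchronous graph.

An attractor of one parametrisation (colour) is a bottom strongly connected
component of that colour's state transition graph.  The coloured search
finds, for every valid colour simultaneously, all such components, using a
forward/backward pivot decomposition on the semi-symbolic representation:

1. pick the smallest state ``s`` still in the universe, with colours ``C``;
2. ``F`` = forward closure of ``(s, C)`` inside the universe, ``B`` = the
   backward closure of ``(s, C)`` inside ``F`` — per colour, ``B`` is
   exactly the SCC of ``s``;
3. colours with no edge escaping ``B`` (i.e. absent from ``F \\ B``) are
   *terminal*: ``B`` restricted to them is an attractor;
4. recurse on ``F \\ B`` (other components reachable from ``s``) and on the
   universe minus the backward closure of ``F`` (states that cannot reach
   ``s``'s component; removing the whole basin keeps every sub-universe
   forward-closed per colour, which makes the terminality test of step 3
   sound in the full graph).

The decomposition is deterministic (ascending pivot order, canonical output
order), cancellable between reachability fixpoints, and reports each
attractor through a callback as soon as it is found.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx

from . import bdd as _bdd
from .encoding import ColourSet
from .graph import ColouredGraph, ColouredStateSet
from .network import BooleanNetwork, NetworkError, evaluate


class CancelToken:
    """Cooperative cancellation flag, settable from another thread."""

    def __init__(self) -> None:
        self._event = threading.Event()

    def cancel(self) -> None:
        self._event.set()

    @property
    def cancelled(self) -> bool:
        return self._event.is_set()


@dataclass(frozen=True)
class ColouredAttractor:
    """A state set that is a terminal SCC under every colour in ``colours``."""

    states: frozenset[int]
    colours: ColourSet

    def sort_key(self) -> tuple:
        return (min(self.states), sorted(self.states), self.colours.serialize())


@dataclass
class AttractorResult:
    attractors: list[ColouredAttractor]
    complete: bool


@dataclass(frozen=True)
class Progress:
    """Progress snapshot emitted after every pivot elimination."""

    states_remaining: int
    attractors_found: int
    colours_solved_fraction: float


def _split_by_state_pattern(
    members: ColouredStateSet, colours: ColourSet
) -> list[tuple[frozenset[int], ColourSet]]:
    """Partition ``colours`` into groups sharing the same member state set."""
    parts: list[tuple[set[int], ColourSet]] = [(set(), colours)]
    for state, state_colours in members.items():
        next_parts: list[tuple[set[int], ColourSet]] = []
        for states, part_colours in parts:
            inside = part_colours & state_colours
            outside = part_colours - state_colours
            if not inside.is_empty:
                next_parts.append((states | {state}, inside))
            if not outside.is_empty:
                next_parts.append((states, outside))
        parts = next_parts
    return [(frozenset(states), c) for states, c in parts if states]


def find_attractors(
    g: ColouredGraph,
    on_found: Callable[[ColouredAttractor], None] | None = None,
    cancel: CancelToken | None = None,
    progress: Callable[[Progress], None] | None = None,
) -> AttractorResult:
    """All coloured attractors of ``g``, canonically ordered.

    For every valid colour ``c`` the returned attractors restricted to ``c``
    are exactly the bottom SCCs of the ``c``-instantiation.  Attractors with
    identical state sets are merged by unioning their colour sets.  On
    cancellation a partial list is returned with ``complete=False``.
    """
    found: dict[frozenset[int], ColourSet] = {}
    if g.valid.is_empty:
        return AttractorResult([], True)

    def report(states: frozenset[int], colours: ColourSet) -> None:
        attractor = ColouredAttractor(states, colours)
        if states in found:
            found[states] = found[states] | colours
        else:
            found[states] = colours
        if on_found is not None:
            on_found(attractor)

    universe = ColouredStateSet(
        {s: g.valid for s in range(g.network.num_states)}
    )
    tasks: list[ColouredStateSet] = [universe]
    total_colours = g.valid.count()
    cancelled = False

    while tasks:
        if cancel is not None and cancel.cancelled:
            cancelled = True
            break
        task = tasks.pop()
        pivot = task.states()[0]
        pivot_colours = task.get(pivot)
        assert pivot_colours is not None
        seed = ColouredStateSet({pivot: pivot_colours})
        forward = g.fwd_reach(seed, within=task)
        if cancel is not None and cancel.cancelled:
            cancelled = True
            break
        backward = g.bwd_reach(seed, within=forward)

        escaping = g.valid - g.valid  # empty colour set of the right width
        outside: dict[int, ColourSet] = {}
        for state, colours in forward.items():
            scc_colours = backward.get(state)
            rest = colours if scc_colours is None else colours - scc_colours
            if not rest.is_empty:
                outside[state] = rest
                escaping = escaping | rest
        terminal = pivot_colours - escaping
        if not terminal.is_empty:
            for states, colours in _split_by_state_pattern(backward, terminal):
                report(states, colours)

        if cancel is not None and cancel.cancelled:
            cancelled = True
            break
        basin = g.bwd_reach(forward, within=task)
        remainder: dict[int, ColourSet] = {}
        for state, colours in task.items():
            removed = basin.get(state)
            rest = colours if removed is None else colours - removed
            if not rest.is_empty:
                remainder[state] = rest
        sub_outside = ColouredStateSet(outside)
        sub_remainder = ColouredStateSet(remainder)
        if sub_outside:
            tasks.append(sub_outside)
        if sub_remainder:
            tasks.append(sub_remainder)

        if progress is not None:
            solved_bdd = _bdd.mk_const(False, g.encoder.num_bits)
            for t in tasks:
                for _, colours in t.items():
                    solved_bdd = solved_bdd | colours.bdd
            remaining = _bdd.sat_count(solved_bdd & g.valid.bdd)
            progress(
                Progress(
                    states_remaining=sum(len(t) for t in tasks),
                    attractors_found=len(found),
                    colours_solved_fraction=1.0 - remaining / total_colours,
                )
            )

    attractors = [ColouredAttractor(states, colours) for states, colours in found.items()]
    attractors.sort(key=ColouredAttractor.sort_key)
    return AttractorResult(attractors, complete=not cancelled)


# -- explicit oracle ------------------------------------------------------


def build_explicit_stg(bn: BooleanNetwork) -> nx.DiGraph:
    """The full asynchronous state transition graph as a networkx digraph."""
    graph = nx.DiGraph()
    graph.add_nodes_from(range(bn.num_states))
    for state in range(bn.num_states):
        for i, name in enumerate(bn.variables):
            value = evaluate(bn.update[name], state, bn)
            if value != (state >> i) & 1:
                graph.add_edge(state, state ^ (1 << i))
    return graph


def brute_force_attractors(bn: BooleanNetwork, max_variables: int = 20) -> list[frozenset[int]]:
    """Bottom SCCs of the explicit asynchronous graph, sorted by minimal state.

    Independent of the symbolic machinery; intended as a reference for
    small networks (refuses more than ``max_variables`` variables).
    """
    if bn.num_variables > max_variables:
        raise NetworkError(
            f"brute force limited to {max_variables} variables, got {bn.num_variables}"
        )
    graph = build_explicit_stg(bn)
    bottoms = []
    for component in nx.strongly_connected_components(graph):
        if all(t in component for s in component for t in graph.successors(s)):
            bottoms.append(frozenset(component))
    bottoms.sort(key=min)
    return bottoms


def brute_force_behaviour(bn: BooleanNetwork, attractor: frozenset[int]) -> str:
    """Classify one explicit attractor: stable / oscillating / disordered."""
    if len(attractor) == 1:
        return "stable"
    graph = build_explicit_stg(bn)
    if all(graph.out_degree(s) == 1 for s in attractor):
        return "oscillating"
    return "disordered"
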
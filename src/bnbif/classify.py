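"""Behaviour classification and the bifurcation function.

Each attractor of one colour is *stable* (a single state), *oscillating*
(a single deterministic cycle) or *disordered* (anything else).  The
multiset of behaviours of all attractors of one colour is its *behaviour
class*; the *bifurcation function* maps every valid colour to its class,
partitioning the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering
from typing import Iterable, Mapping

from . import bdd as _bdd
from .attractors import ColouredAttractor
from .encoding import ColourSet, ParameterEncoder
from .graph import ColouredGraph
from .network import BooleanNetwork, ParametrisedNetwork, instantiate

STABLE = "stable"
OSCILLATING = "oscillating"
DISORDERED = "disordered"
_BEHAVIOURS = (STABLE, OSCILLATING, DISORDERED)
_LETTER = {STABLE: "S", OSCILLATING: "O", DISORDERED: "D"}


class ClassificationError(ValueError):
    pass


@total_ordering
@dataclass(frozen=True)
class BehaviourClass:
    """A multiset over {stable, oscillating, disordered}, e.g. ``"SSO"``."""

    counts: tuple[int, int, int]  # (n_stable, n_oscillating, n_disordered)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ClassificationError("behaviour counts must be non-negative")

    @staticmethod
    def empty() -> "BehaviourClass":
        return BehaviourClass((0, 0, 0))

    @staticmethod
    def from_string(text: str) -> "BehaviourClass":
        counts = [0, 0, 0]
        order = "SOD"
        for ch in text:
            if ch not in order:
                raise ClassificationError(f"bad behaviour letter {ch!r} in {text!r}")
            counts[order.index(ch)] += 1
        return BehaviourClass(tuple(counts))

    @staticmethod
    def from_behaviours(behaviours: Iterable[str]) -> "BehaviourClass":
        counts = [0, 0, 0]
        for b in behaviours:
            counts[_BEHAVIOURS.index(b)] += 1
        return BehaviourClass(tuple(counts))

    def add(self, behaviour: str) -> "BehaviourClass":
        counts = list(self.counts)
        counts[_BEHAVIOURS.index(behaviour)] += 1
        return BehaviourClass(tuple(counts))

    def __str__(self) -> str:
        s, o, d = self.counts
        return "S" * s + "O" * o + "D" * d

    def __lt__(self, other: "BehaviourClass") -> bool:
        return (sum(self.counts), self.counts) < (sum(other.counts), other.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class BifurcationFunction:
    """The partition of the valid colours by behaviour class."""

    classes: dict[BehaviourClass, ColourSet]
    valid: ColourSet

    def cardinalities(self) -> dict[BehaviourClass, int]:
        return {k: c.count() for k, c in sorted(self.classes.items())}

    def class_of(self, assignment) -> BehaviourClass:
        for cls, colours in self.classes.items():
            if colours.contains(assignment):
                return cls
        raise ClassificationError("assignment is not a valid colour")


def classify(g: ColouredGraph, attractor: ColouredAttractor) -> dict[str, ColourSet]:
    """Partition an attractor's colours by behaviour.

    A singleton attractor is stable under every colour.  A larger attractor
    oscillates under colour ``c`` iff every member state has exactly one
    enabled variable under ``c`` (determinism inside a terminal SCC forces a
    single covering cycle); the remaining colours are disordered.  The
    exactly-one test runs symbolically over the per-variable flip colours.
    """
    colours = attractor.colours
    if len(attractor.states) == 1:
        return {STABLE: colours}
    n_bits = g.encoder.num_bits
    oscillating = colours.bdd
    for state in sorted(attractor.states):
        none_so_far = _bdd.mk_const(True, n_bits)
        exactly_one = _bdd.mk_const(False, n_bits)
        for i in range(g.network.num_variables):
            flip = g.enabled_colours(state, i).bdd
            exactly_one = (exactly_one & ~flip) | (none_so_far & flip)
            none_so_far = none_so_far & ~flip
        oscillating = oscillating & exactly_one
        if oscillating == _bdd.mk_const(False, n_bits):
            break
    osc = ColourSet(oscillating)
    dis = colours - osc
    out: dict[str, ColourSet] = {}
    if not osc.is_empty:
        out[OSCILLATING] = osc
    if not dis.is_empty:
        out[DISORDERED] = dis
    return out


def build_bifurcation(
    classified: Iterable[tuple[str, ColourSet]],
    valid: ColourSet,
) -> BifurcationFunction:
    """Incrementally split the valid colours by behaviour increments.

    ``classified`` yields one ``(behaviour, colours)`` pair per attractor and
    behaviour; a colour's final class is the multiset of behaviours of all
    its attractors.  Raises if some valid colour ends up with no attractor.
    """
    partition: dict[BehaviourClass, ColourSet] = {BehaviourClass.empty(): valid}
    for behaviour, colours in classified:
        next_partition: dict[BehaviourClass, ColourSet] = {}

        def put(key: BehaviourClass, value: ColourSet) -> None:
            if value.is_empty:
                return
            if key in next_partition:
                next_partition[key] = next_partition[key] | value
            else:
                next_partition[key] = value

        for cls, cls_colours in partition.items():
            put(cls, cls_colours - colours)
            put(cls.add(behaviour), cls_colours & colours)
        partition = next_partition
    unclassified = partition.pop(BehaviourClass.empty(), None)
    if unclassified is not None and not unclassified.is_empty:
        raise ClassificationError(
            f"{unclassified.count()} valid colour(s) have no classified attractor; "
            "the attractor list is incomplete"
        )
    return BifurcationFunction(partition, valid)


def class_cardinalities(bf: BifurcationFunction) -> dict[BehaviourClass, int]:
    return bf.cardinalities()


def witness(
    network: ParametrisedNetwork,
    encoder: ParameterEncoder,
    colours: ColourSet,
) -> BooleanNetwork:
    """A concrete instantiation drawn deterministically from a colour set
    (lexicographically smallest parametrisation)."""
    if colours.is_empty:
        raise ClassificationError("cannot produce a witness of an empty colour set")
    return instantiate(network, encoder.decode(colours.pick()))
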
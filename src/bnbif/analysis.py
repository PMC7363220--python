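"""End-to-end attractor bifurcation analysis of a parametrised network."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .attractors import (
    AttractorResult,
    CancelToken,
    ColouredAttractor,
    Progress,
    find_attractors,
)
from .classify import BifurcationFunction, build_bifurcation, classify
from .encoding import ColourSet, DEFAULT_ARITY_CAP
from .graph import ColouredGraph, DEFAULT_STATE_LIMIT
from .network import ParametrisedNetwork


@dataclass(frozen=True)
class ClassifiedAttractor:
    """An attractor together with its per-behaviour colour partition."""

    states: frozenset[int]
    colours: ColourSet
    behaviours: dict[str, ColourSet]

    @property
    def size(self) -> int:
        return len(self.states)


@dataclass
class AnalysisResult:
    graph: ColouredGraph
    attractors: list[ClassifiedAttractor]
    bifurcation: BifurcationFunction | None
    complete: bool


def analyse(
    network: ParametrisedNetwork,
    *,
    state_limit: int = DEFAULT_STATE_LIMIT,
    arity_cap: int = DEFAULT_ARITY_CAP,
    on_attractor: Callable[[ColouredAttractor], None] | None = None,
    progress: Callable[[Progress], None] | None = None,
    cancel: CancelToken | None = None,
) -> AnalysisResult:
    """Find all coloured attractors, classify them, build the bifurcation
    function.  On cancellation the result carries the attractors found so
    far, no bifurcation function, and ``complete=False``."""
    graph = ColouredGraph(network, state_limit=state_limit, arity_cap=arity_cap)
    search: AttractorResult = find_attractors(
        graph, on_found=on_attractor, cancel=cancel, progress=progress
    )
    classified: list[ClassifiedAttractor] = []
    increments: list[tuple[str, ColourSet]] = []
    for attractor in search.attractors:
        behaviours = classify(graph, attractor)
        classified.append(
            ClassifiedAttractor(attractor.states, attractor.colours, behaviours)
        )
        increments.extend(behaviours.items())
    bifurcation = None
    if search.complete:
        bifurcation = build_bifurcation(increments, graph.valid)
    return AnalysisResult(graph, classified, bifurcation, search.complete)
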
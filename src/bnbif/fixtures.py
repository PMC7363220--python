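"""Seeded random network generator for tests and benchmarks.

Generated networks have in-degree at most 3; each update expression is
either a random read-once parameter-free formula over the regulators (every
regulator appears exactly once, possibly negated, combined with random
binary connectives) or a single uninterpreted-function application over
them.  Regulation flags on parameter-free updates reflect the actual
semantic properties of the drawn formula (sometimes weakened to "unknown");
flags on parameterised updates are drawn at random, and the whole network
is re-rolled if the constraints admit no valid parametrisation.
"""

from __future__ import annotations

import random
from itertools import product

from .encoding import build_encoder, valid_colours
from .expr import App, BinOp, Expr, Not, Var
from .io_native import ModelDocument
from .network import (
    ACTIVATION,
    INHIBITION,
    MONO_UNKNOWN,
    OBS_REQUIRED,
    OBS_UNKNOWN,
    ParameterDecl,
    ParametrisedNetwork,
    Regulation,
    validate_network,
)


class FixtureError(RuntimeError):
    pass


def _eval_free(e: Expr, ctx: dict[str, int]) -> int:
    if isinstance(e, Var):
        return ctx[e.name]
    if isinstance(e, Not):
        return 1 - _eval_free(e.operand, ctx)
    if isinstance(e, BinOp):
        left, right = _eval_free(e.left, ctx), _eval_free(e.right, ctx)
        return {"and": left & right, "or": left | right, "xor": left ^ right}[e.op]
    raise FixtureError(f"unexpected node in generated expression: {e!r}")


def _semantic_flags(e: Expr, context: tuple[str, ...], source: str) -> tuple[bool, str]:
    """(observable, monotonicity) of a parameter-free formula in ``source``."""
    others = [v for v in context if v != source]
    observable = False
    non_decreasing = True
    non_increasing = True
    for bits in product((0, 1), repeat=len(others)):
        ctx = dict(zip(others, bits))
        lo = _eval_free(e, {**ctx, source: 0})
        hi = _eval_free(e, {**ctx, source: 1})
        if lo != hi:
            observable = True
        if lo > hi:
            non_decreasing = False
        if hi > lo:
            non_increasing = False
    if non_decreasing and not non_increasing:
        mono = ACTIVATION
    elif non_increasing and not non_decreasing:
        mono = INHIBITION
    else:
        mono = MONO_UNKNOWN
    return observable, mono


def generate_fixture(
    n_vars: int,
    max_arity: int = 2,
    parameter_probability: float = 0.5,
    seed: int = 0,
    max_parameters: int | None = None,
    max_colours: int | None = None,
    retry_budget: int = 200,
) -> ModelDocument:
    """A random well-formed parametrised network, deterministic in ``seed``."""
    if n_vars < 1:
        raise FixtureError("need at least one variable")
    rng = random.Random(seed)
    names = [f"v{i}" for i in range(n_vars)]

    for _attempt in range(retry_budget):
        regulations: list[Regulation] = []
        parameters: list[ParameterDecl] = []
        update: dict[str, Expr] = {}
        n_parameterised = 0
        for i, name in enumerate(names):
            parameterised = rng.random() < parameter_probability and (
                max_parameters is None or n_parameterised < max_parameters
            )
            if parameterised:
                degree = rng.randint(1, max(1, min(max_arity, n_vars)))
            else:
                degree = rng.randint(1, min(3, n_vars))
            context = tuple(sorted(rng.sample(range(n_vars), degree)))
            context_names = tuple(names[j] for j in context)
            if parameterised:
                n_parameterised += 1
                pname = f"P{i}"
                parameters.append(ParameterDecl(pname, degree))
                update[name] = App(pname, tuple(Var(v) for v in context_names))
                for src in context_names:
                    observable = (
                        OBS_REQUIRED if rng.random() < 0.5 else OBS_UNKNOWN
                    )
                    mono = rng.choice([ACTIVATION, INHIBITION, MONO_UNKNOWN])
                    regulations.append(Regulation(src, name, observable, mono))
            else:
                literals: list[Expr] = [
                    Not(Var(v)) if rng.random() < 0.5 else Var(v)
                    for v in context_names
                ]
                rng.shuffle(literals)
                expr = literals[0]
                for lit in literals[1:]:
                    expr = BinOp(rng.choice(["and", "or", "xor"]), expr, lit)
                update[name] = expr
                for src in context_names:
                    observable, mono = _semantic_flags(expr, context_names, src)
                    obs_flag = (
                        OBS_REQUIRED
                        if observable and rng.random() < 0.8
                        else OBS_UNKNOWN
                    )
                    mono_flag = mono if rng.random() < 0.8 else MONO_UNKNOWN
                    regulations.append(Regulation(src, name, obs_flag, mono_flag))

        network = ParametrisedNetwork(names, regulations, parameters, update)
        issues = validate_network(network)
        if issues:  # pragma: no cover - generator invariant
            raise FixtureError(f"generated network failed validation: {issues}")
        encoder = build_encoder(network)
        valid = valid_colours(network, encoder)
        if valid.is_empty:
            continue
        if max_colours is not None and valid.count() > max_colours:
            continue
        return ModelDocument(network, {"name": f"fixture-{seed}"})
    raise FixtureError(
        f"could not draw a network with non-empty valid colours within "
        f"{retry_budget} attempts (seed {seed})"
    )
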
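"""Shared fixtures: the three-variable example network and oracle helpers."""

from __future__ import annotations

import pytest

from bnbif import (
    BehaviourClass,
    ModelDocument,
    analyse,
    brute_force_attractors,
    brute_force_behaviour,
    generate_fixture,
    three_variable_example,
)
from bnbif.network import Parametrisation, instantiate


@pytest.fixture()
def worked_example():
    """The parametrised three-gene circuit with F_B = P(A, C)."""
    return three_variable_example()


@pytest.fixture()
def worked_doc(worked_example):
    return ModelDocument(worked_example, {"name": "three-variable example"})


P_OR = Parametrisation({"P": (0, 1, 1, 1)})
P_AND = Parametrisation({"P": (0, 0, 0, 1)})


def per_colour_oracle(network, result):
    """For every valid colour: (assignment, bottom SCCs, behaviour class).

    Computed entirely with the explicit-graph oracle (instantiate, build the
    full asynchronous STG, take bottom SCCs), independent of the symbolic
    search whose output it is compared against.
    """
    encoder = result.graph.encoder
    records = []
    for p in encoder.iter_colours(result.graph.valid):
        bn = instantiate(network, p)
        expected = brute_force_attractors(bn)
        cls = BehaviourClass.from_behaviours(
            brute_force_behaviour(bn, a) for a in expected
        )
        records.append((encoder.encode(p), expected, cls))
    return records


def make_fixture_suite(seeds, n_vars=None):
    """Generate and analyse the seeded random-network suite."""
    suite = []
    for seed in seeds:
        nv = n_vars if n_vars is not None else 4 + seed % 4
        doc = generate_fixture(
            nv,
            max_arity=2,
            parameter_probability=0.5,
            seed=seed,
            max_parameters=2,
            max_colours=64,
        )
        result = analyse(doc.network)
        suite.append((seed, doc, result))
    return suite
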
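# bnbif — attractor bifurcation analysis of parametrised Boolean networks

Boolean networks are a standard qualitative model of gene regulation: each
gene is a Boolean variable `A ∈ 𝒱` with an update function `F_A` over its
regulators, and under the *asynchronous* semantics one variable is updated
per step, chosen nondeterministically.  The long-term behaviours are the
**attractors** — terminal (bottom) strongly connected components of the
state transition graph — each of which is *stable* (a single state),
*oscillating* (a single deterministic cycle) or *disordered* (anything
else).

In practice the update functions are rarely fully known.  `bnbif` works
with **parametrised** Boolean networks, whose update expressions may
contain *uninterpreted* Boolean functions (`F̂_B = P(A, C)` with `P` an
unknown binary function), constrained by qualitative regulation properties:

* **observability** of a regulation `(A, B)` — some context exists where
  toggling `A` toggles `F_B`;
* **activation / inhibition** — `F_B` is monotone non-decreasing /
  non-increasing in `A`.

An interpretation of every unknown function (a *parametrisation*, or
*colour*) that satisfies all declared properties is *valid*.  For the full
set `P` of valid parametrisations simultaneously, `bnbif` computes the
**bifurcation function**

```
𝒜 : P → ℭ,    𝒜(p) = the multiset of attractor behaviours of the p-instantiation,
```

whose level sets partition the parameter space into behaviour classes
(written `"S"`, `"O"`, `"SSD"`, ...), together with the exact cardinality of
each class and a concrete *witness* network per class.

Internally the tool is semi-symbolic: states are explicit, colour sets are
reduced ordered BDDs over one decision bit per truth-table row of each
unknown function.  Attractors for all colours at once are found by a
deterministic forward/backward pivot decomposition of the edge-coloured
transition graph; behaviours are decided symbolically per attractor.

## Worked example

The built-in three-gene circuit (`bnbif.three_variable_example()`) has
`F_A = A | !B | !C`, `F_C = !B` and an unknown update `F̂_B = P(A, C)` whose
regulations `(A, B)` and `(C, B)` are observable activations.  Only two
interpretations of `P` survive these constraints — OR and AND — and they
behave differently:

```
$ bnbif analyse example.bn -o example.results.json --no-progress
{"event": "done", "complete": true, "attractors": 2, "classes": {"O": "1", "S": "1"}, "output": "example.results.json"}
```

Two behaviour classes, one parametrisation each: under `P = OR` the network
has a single stable attractor, the fixed point `110` (A=1, B=1, C=0); under
`P = AND` it has a single oscillating attractor, the 4-state cycle
`{100, 101, 111, 110}`.  A witness for the oscillating class is a concrete,
parameter-free network:

```
$ bnbif witness example.results.json O
...
$B: A & C
...
```

The same pipeline is available as a library:

```python
import bnbif
result = bnbif.analyse(bnbif.three_variable_example())
print(result.graph.valid.count())                                   # 2
print({str(k): v for k, v in result.bifurcation.cardinalities().items()})
# {'O': 1, 'S': 1}
```

Model files use a small native text dialect (regulations `A -> B`,
`A -| B`, `A -? B`, with a trailing `?` when observability is not required;
updates `$B: P(A, C)`) or SBML Level 3 qual; `bnbif convert` translates
between them.  Analysis results are written as a self-contained JSON bundle
embedding the model, the parameter-bit layout and one serialized BDD per
behaviour class, so the partition can be post-processed by other tools.

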
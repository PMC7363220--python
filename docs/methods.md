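# Methods

This note documents the model, the algorithms, the numerical/ordering
conventions and the deliberate design choices behind `bnbif`.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Model

A parametrised Boolean network is `(𝒱, R, 𝔓, 𝔉)`: Boolean variables `𝒱`,
regulations `R ⊆ 𝒱 × 𝒱` with optional observability and sign annotations,
uninterpreted Boolean function names `𝔓` with fixed arities, and one update
expression per variable over its regulators (its *context*).  A
*parametrisation* `p` assigns each `P ∈ 𝔓` a concrete truth table;
substituting `p` yields the *p-instantiation*, an ordinary Boolean network.
Under asynchronous semantics, `s → t` iff `t` flips exactly one variable
`A` of `s` and `F_A(s)` equals the flipped value; self-loops are excluded.
Attractors are bottom SCCs; behaviours are stable (singleton), oscillating
(every attractor state has exactly one outgoing transition — inside a
terminal SCC this forces a single covering cycle) or disordered.

Validation enforces that the context of each variable is *exactly* the set
of variables its update expression syntactically references.  A regulation
whose source never appears in the target's expression is rejected even when
the expression contains parameters: an uninterpreted function application
makes a variable an input only if it occurs among the arguments.

## Parameter encoding

Each parameter of arity `a` contributes `2^a` BDD decision bits, one per
truth-table row; bits are contiguous per parameter, parameters in
declaration order, rows ascending.  Truth-table rows are indexed with the
*first* argument most significant (`P(A, C)` at `A=1, C=0` reads row `10` =
2).  Assignments over all bits are therefore in bijection with
parametrisations, and `sat_count` of a colour-set BDD is an exact (Python
arbitrary-precision) cardinality.

Property constraints are built by enumerating the `2^{|context|}` input
rows of each annotated update function (capped at 16 regulators per
variable, with a clear error beyond): observability is an OR of XORs of the
symbolic rows that differ only in the source; activation/inhibition an AND
of implications between them.  Regulations annotated `unknown` contribute
no constraint; validity is the conjunction over all regulations and every
colour set handed out by the graph layer is pre-intersected with it.

## BDD engine

A deliberately small, self-contained ROBDD library: fixed variable order,
no complement edges, no dynamic reordering, append-only node table with
structural hashing.  Every `Bdd` is a standalone array kept in a canonical
order (post-order DFS from the root, low child first), so semantic equality
coincides with structural equality and with byte equality of the text
serialization — the property the bifurcation-function export relies on.
`pick_sat` returns the lexicographically smallest satisfying assignment
(variable order, 0 before 1), which makes witness extraction deterministic.
These simplifications are appropriate because the colour spaces in scope
are truth-table encodings with at most a few hundred bits; they would be
the wrong trade-off for general model checking.

## Coloured graph and attractor search

The representation is semi-symbolic: explicit integer state masks mapped to
symbolic colour sets.  Per variable, the colour set of "update evaluates to
1" is precomputed for each of its `2^{|context|}` regulator assignments, so
successor generation costs `|𝒱|` BDD operations per state.  Networks with
more than `2^22` states are refused by default (`state_limit`), since the
universe is materialised explicitly.

Attractors are found by a pivot decomposition over a worklist of coloured
sub-universes, starting from all states × valid colours:

1. pivot = smallest state mask with non-empty colours `C`;
2. `F` = forward closure of the pivot within the sub-universe; `B` =
   backward closure of the pivot within `F` (per colour, exactly the
   pivot's SCC);
3. colours absent from `F \ B` cannot escape: `B` restricted to them is
   reported as attractors, split into groups of colours sharing the same
   member-state set (identical state sets are merged across the whole run);
4. recurse on `F \ B` and on the sub-universe minus the *backward closure
   of `F`* (the pivot's whole basin).

Removing the full basin — rather than only `F` — keeps every sub-universe
forward-closed per colour, which is what makes the escape test in step 3
correct against the full graph; states that can reach `F` cannot belong to
any attractor disjoint from it, so discarding them loses nothing.  The
scheme is deterministic (ascending pivots, canonical output order by
minimal state then colour serialization), reports each attractor through a
callback the moment it is found, and honours a cooperative cancellation
token between reachability fixpoints, returning a partial list flagged
incomplete.  Execution is sequential; the determinism contract means any
task-parallel execution of step 4's independent sub-universes must produce
the identical result, which is why all outputs are independent of the CLI's
`--workers` value.

Correctness is anchored in an independent oracle rather than in fidelity to
any particular published component algorithm: for every valid colour of
every test network, the search's output is compared with an explicit
bottom-SCC decomposition (`networkx` condensation of the full transition
graph) of that colour's instantiation.

## Classification and bifurcation function

Singleton attractors are stable for all their colours.  For larger
attractors the oscillating colours are computed symbolically: for each
member state, an exactly-one pass over the per-variable flip colour sets;
the conjunction over states gives the colours with deterministic dynamics
inside the attractor.  The remainder is disordered.  The attractor's period
(its size) is reported as metadata but is not part of class identity — a
class is a multiset over {S, O, D} only, written with S before O before D.

The bifurcation function is built incrementally: starting from
{empty class ↦ valid}, each (behaviour, colours) increment splits every
entry into "unchanged" and "class + behaviour" parts.  The result is
asserted to be a partition of the valid colours (pairwise disjoint,
cardinalities summing to `|valid|`); any colour left without an attractor
raises an internal completeness error.  Witnesses instantiate the
lexicographically smallest member of a class's colour set.

## File formats

The native dialect covers exactly the model's information content:
`#key: value` annotations, regulation lines (`->` activation, `-|`
inhibition, `-?` unknown sign, trailing `?` = observability not required)
and `$VAR: expression` updates; parameters are declared implicitly at first
application with arity consistency enforced; variable order is the update
line order.  Expression grammar: identifiers `[A-Za-z_][A-Za-z0-9_]*`,
operators `!`, `&`, `|`, `^`, `=>`, `<=>` in decreasing binding strength,
right-associative, constants `true`/`false`/`1`/`0`.

SBML Level 3 qual import/export maps variables to Boolean qualitative
species (`maxLevel="1"`; anything higher is rejected), updates to
transition function terms in the qual-restricted MathML subset, and signs
to `qual:sign`.  Two pieces of information have no standard home and are
stored inside SBML `<annotation>` elements under a package namespace
(`urn:bnbif:annotations`), keeping parameter-free documents
schema-conformant: the "observability not required" flag and the parameter
declaration order.  Uninterpreted-function applications are MathML
`csymbol` applications with `definitionURL="urn:bnbif:uninterpreted-function"`;
this encoding is a documented convention of this package, not a published
standard.

Results are exported as one JSON bundle embedding the model text, the
parameter-bit manifest, the serialized colour-set BDD and decimal-string
cardinality per class, and per-attractor metadata — enough for external
post-processing and for witness extraction without re-analysis.

## Synthetic test networks

`generate_fixture(n_vars, max_arity, parameter_probability, seed, ...)`
draws networks with in-degree ≤ 3.  Each update is either a single
uninterpreted-function application over its regulators or a random
*read-once* formula (every regulator once, possibly negated, random
`&`/`|`/`^` combinators) — read-once formulas depend essentially on every
input, so declared observability can never be vacuous.  Flags on
parameter-free updates reflect the formula's actual semantic properties,
randomly weakened to `unknown`; flags on parameterised updates are drawn at
random, and the network is re-rolled (bounded budget) when the constraints
admit no valid parametrisation or exceed a requested colour bound.  The
test suite uses 4–7 variables, at most 2 parameters of arity ≤ 2 and at
most 64 valid colours per network — sizes at which the explicit oracle is
exhaustive per colour, chosen so the whole 200-network sweep completes in
well under a minute.

What the generator does *not* emulate: the scale-free regulation structure,
high in-degrees and canalysing update functions typical of curated
biological models, or parameter spaces beyond ~2^8 colours.  Passing the
oracle suite therefore demonstrates algorithmic correctness on the coloured
semantics, not performance or robustness at genome-scale model sizes.

## Known limitations

* The explicit state universe bounds networks to ~22 variables by default;
  a fully symbolic state representation is out of scope.
* The pure-Python BDD engine favours canonicity and auditability over
  speed; large-arity parameters (cap: 8) are refused.
* Multi-valued variables, synchronous/generalised update schemes and
  basin-of-attraction computation are out of scope.
* No byte-level compatibility with any other tool's text format or SBML
  parameter encoding is claimed.
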
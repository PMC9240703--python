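# Methods

## Statement dialect

A statement is `stimulus operator stimulus` with single-character,
case-sensitive alphanumeric stimuli and operator in `{=, <, >, ku}`. All
whitespace is stripped before parsing, so `A=B` and `A = B` name the same
statement; the canonical rendering is `A = B` (spaces) for the determinate
operators and `AkuB` (no spaces) for known-unknown. Non-alphanumeric
stimulus symbols are rejected with an explicit error rather than passed
through with undefined behaviour, and self-relations (`A=A`) are rejected:
no derivation rule is defined over them and the pair-validation gate could
never consume them.

Statement identity is the exact `(left, op, right)` triple. `A < B` and
`B > A` are different statements that both appear in output. This is
deliberate: trained and mutually-entailed responses are distinct behavioural
events, and the tables record them as separate rows.

## Derivation rules

**Mutual entailment** swaps the operands and maps the operator
`= → =`, `< → >`, `> → <`, `ku → ku`. It is an involution, tested
exhaustively over the full representable statement space.

**Combinatorial entailment** applies to an unordered pair of distinct
statements sharing exactly one stimulus (four stimulus tokens, three unique
names — the `u = c − 1` gate). Each statement is normalised to
`unique op shared`, inverting the operator via the mutual-entailment map when
the unique stimulus is on the right. The derived statement `da R db` comes
from a fixed decision table over the normalised operator pair:

| `ra` \ `rb` | `=` | `<` | `>` |
|---|---|---|---|
| `=` | `=` | `>` | `<` |
| `<` | `<` | `ku` | `<` |
| `>` | `>` | `>` | `ku` |

The two `ku` cells are the pairs in which both unique stimuli sit strictly
below, or strictly above, the shared stimulus; every consistent numeric
assignment to the three stimuli then still leaves the `da`-vs-`db` direction
open, which the test suite verifies by enumerating all 13 weak orderings of
three elements per cell. Combining the pair in the opposite order yields
exactly the mutual entailment of the forward result, so a single table entry
plus one mutual-entailment call covers both derivable statements — this
nesting is also how the closure engine records CE/CME row pairs.

## Known-unknown modes

How indeterminate cells and `ku` inputs are treated is a three-valued mode:

* `off` — indeterminate pairs derive nothing; `ku` statements never combine.
* `emit` (default) — indeterminate pairs derive a `ku` statement; `ku`
  statements still never serve as combination inputs.
* `propagate` — additionally, a combinable pair containing exactly one `ku`
  statement derives `ku` ("dominant transitivity"). Pairs of two `ku`
  statements are excluded in every mode; combining them would generate `ku`
  statements without end.

The published worked examples are internally inconsistent on this point: the
three-stimulus mixed-network table omits the two `ku` records that the
complex-network table's behaviour implies for the analogous configuration.
Rather than guess which behaviour the original implementation actually had,
all three modes are exposed; `off` reproduces the smaller printed table
verbatim and `emit` reproduces the equivalence-network and complex-network
tables verbatim, which is why `emit` is the default. No semantic ground
truth exists for `propagate` (a `ku` premise asserts nothing a weak ordering
can check), so the oracle deliberately does not validate it.

## The closure engine

`relation_train` proceeds in two phases.

*Seed pass.* All base triples are pre-registered first, then each base
statement is appended in input order as Directly Trained, immediately
followed by its mutual entailment as Mutually Entailed unless that triple is
itself a base statement (base precedence: a trained statement is never
shadowed by an earlier statement's entailment). Duplicate base statements
are dropped with a logged warning.

*Sweep loop.* Each sweep visits all unordered index pairs `(i < j)` of the
record list as it stood at sweep start, in ascending order. A pair that
passes the KU input filter and the shared-stimulus gate is combined; a new
triple is appended as Combinatorially Entailed with the pair as parents,
immediately followed by its mutual entailment (Combinatorially Mutually
Entailed, same parents) if new. The loop ends after the first sweep that
appends nothing.

Consequences of this design:

* **Termination** is unconditional: at most one record per ordered stimulus
  pair per operator bounds the table at `4·n·(n−1)` records, and every sweep
  either grows the table or ends the loop.
* **Provenance is first-wins.** A statement derivable through several pairs
  records whichever pair the sweep met first. The published complex-network
  table attributes at least one row to a different (equally valid) parent
  pair than this order produces, and the original iteration order is not
  recoverable; derivation level and parents of multiply-derivable statements
  are therefore order-dependent, and cross-implementation comparisons are
  made on statement *sets*. Record order is append order; `sorted()` offers
  a display-only stable sort (trained/mutual block, then by stimuli).
* **No consistency checking.** A contradictory base set derives a table
  containing, e.g., both `A < C` and `A > C`. This is intentional: the
  engine models derivation as behaviour, and behaving organisms derive from
  contradictory training histories without halting.

## The oracle

The semantic model for `=`, `<`, `>` is the weak ordering — a ranking of
stimuli with ties, the minimal structure in which all three relations are
expressible (permutations could not satisfy an `=` premise). Orderings are
enumerated as ordered set partitions, per connected component of the non-KU
premise graph, with a documented cap of 8 stimuli per component (545,835
orderings); property tests stay at ≤ 6.

* `forced_relations`: the determinate statements holding in **every**
  consistent ordering — what a sound and complete deriver must output.
* `expected_ku`: `(x, ku, y)` exactly when the forced closure places both
  `x` and `y` strictly below, or strictly above, some third stimulus. This
  restates the engine's emit-mode KU semantics declaratively, with no
  reference to the sweep.
* `check_agreement`: soundness (no table statement outside the forced set),
  completeness (no forced relation missing), and exact match of the
  combinatorially derived KU set. Trained/mutually-entailed `ku` records are
  excluded from the KU comparison — a `ku` statement in the base is an input
  fact, not a semantic claim the oracle can ground.

The oracle *refuses* contradictory bases (`ContradictionError`) while the
engine tolerates them; the divergence is by design, and the command-line
`validate` command surfaces it as a distinct exit code (3).

For consistent determinate premises, the engine's pairwise composition rules
are exactly the path-consistency compositions of the three-valued point
algebra, for which chaining is complete; the zero-disagreement sweep (all 48
comparative pair arrangements plus 100 random consistent bases) checks this
empirically rather than assuming it.

## Input-form enumeration

Over three labelled stimuli there are 12 comparative statement forms
(6 ordered stimulus pairs × `<`/`>`) and 3 equivalence forms (unordered
stimulus pairs — `A = B` and `B = A` are one form, reflecting the symmetry
of equivalence, while `A < B` and `B > A` remain distinct forms). Counting
unordered pairs of distinct forms sharing exactly one stimulus gives 48
comparative-only input forms, and 72 when at most one statement per pair may
be an equivalence. This identification scheme is the unique natural one
reproducing both published counts, and the enumeration (not a closed form)
is what `count_input_forms` executes — the same pair list feeds the
zero-disagreement sweep.

## Random base-set generator

`random_base_set` draws distinct statements over a configurable alphabet
with per-operator weights, seeded and fully reproducible. Defaults: 6
stimuli, 4 statements, weights `< : 1, > : 1, = : 0.4, ku : 0.4` — mirroring
the composition of the published complex worked example, where comparatives
dominate and equivalence and known-unknown statements are occasional.
`ensure_connected` (default on) makes every statement after the first reuse
an already-mentioned stimulus, so the premises form one connected network;
`require_consistent` re-draws until the non-KU premises admit a weak
ordering, for test suites that need oracle-checkable sets. Contradictions
are otherwise permitted, matching engine tolerance.

What the generator does *not* emulate: human derivation errors, contextual
control (a single relational context is assumed throughout — multiple
contexts must be run as independent instances), operators beyond the four,
or multi-character stimulus names. Passing tests on generated sets therefore
demonstrate correctness of the symbolic closure, not fidelity to human
responding, which is known to deviate from strict logic precisely in the
known-unknown cases.

## Graphs and rendering

A derivation table maps to a directed multigraph: stimuli as vertices, one
edge per unique relation string, coloured Blue (trained), Purple (mutually
entailed) or Orange (combinatorially derived). Connectivity and default
rendering treat the graph as undirected — mutual-entailment pairs already
encode both directions — and isolated networks are its connected components,
ordered by smallest member. Self-loops are structurally representable but
unreachable, since the parser rejects self-relations. Exports: GraphML (full
attributes, round-trippable), Graphviz DOT (hand-emitted; colour-mapped
edges with relation labels), edge-list CSV, and seeded force-directed PNG/SVG
plots with optional suppression of combinatorial edge labels for dense
networks. Only topology and colouring are asserted anywhere; layout
coordinates are reproducible for a fixed seed but otherwise arbitrary.

## Problem sizes

All published worked examples are small (≤ 8 base statements, ≤ 10 stimuli)
and derive in milliseconds. The validation sweep uses the full 48-pair
comparative enumeration plus 100 random bases of 4–6 stimuli, and property
tests run 30 further seeds for the KU characterisation; the whole suite
completes in a few seconds on one CPU. The oracle's per-component
8-stimulus cap is an enumeration bound, not an engine limit — the engine
itself scales to the low tens of stimuli before the quadratic sweep over the
`4·n·(n−1)`-bounded table becomes noticeable.

## Known limitations

* Derivation level and provenance of multiply-derivable statements are
  iteration-order artefacts (see above); only statement sets are stable.
* The `~2^(n−1)` growth heuristic sometimes quoted for derived-relation
  counts is an approximation and is not asserted anywhere; `summarize`
  reports actual counts.
* The oracle validates `emit`-mode semantics only; `propagate` mode is
  implemented but semantically ungrounded.
* No contextual control, no relation classes beyond `=`, `<`, `>`, `ku`, no
  edge weighting, no interactive visualisation.
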
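# relframe

Derivation engine for relational networks in the Relational Frame Theory
(RFT) tradition. Given a base set of trained two-stimulus relational
statements, `relframe` derives the complete closed set of entailed relations,
reports it as a provenance table, and exposes it as an edge-coloured network
graph with isolated-network detection. A brute-force weak-ordering oracle
validates the derivation logic independently.

## Who this is for

Researchers and practitioners working with derived stimulus relations —
stimulus equivalence, comparative relational training, relational reasoning
protocols — who need to know the *full* network a training set entails
without deriving it by hand. Deriving even a dozen trained relations by hand
is slow and error-prone; the closure here is exact, repeatable, and
inspectable edge by edge.

## The model

A statement relates two single-character stimuli (`0-9`, `a-z`, `A-Z`,
case-sensitive) through one of four relational operators: equivalence
(`=`), the comparatives (`<`, `>`), and *known-unknown* (`ku`) — a derived
relation whose direction cannot be resolved from the premises. Two rules
generate untrained relations:

* **Mutual entailment (ME).** Each statement `x r y` entails `y r' x`, where
  `r'` swaps `<` with `>` and leaves `=` and `ku` fixed. `A < B` entails
  `B > A`.
* **Combinatorial entailment (CE).** Two statements sharing exactly one
  stimulus entail a relation between their two unique stimuli `da`, `db`.
  After normalising both statements to the form `unique op shared`, a fixed
  3×3 decision table yields the result: e.g. `(<,=) → <`, `(<,>) → <`,
  and the indeterminate cells `(<,<)` and `(>,>)` — both unique stimuli
  strictly below, or strictly above, the shared one — yield `ku`.

`relation_train` seeds a table with the trained statements (Blue edges) and
their mutual entailments (Purple), then sweeps all statement pairs to a fixed
point, recording each new CE (Orange) immediately followed by its ME, with
the parent pair as provenance. Statements are identified by their exact
`(left, op, right)` triple, so `A < B` and `B > A` are distinct records. The
table is bounded by `4·n·(n−1)` records over `n` stimuli, so termination is
guaranteed — even for contradictory base sets, which are accepted by design
(derivation models behaviour, not logical consistency).

Three KU modes control indeterminate derivation: `off` (suppress), `emit`
(default: derive `ku` statements, but never combine through them) and
`propagate` (a pair with one `ku` statement also derives `ku`).

The oracle interprets `=`, `<`, `>` over **weak orderings** (rankings with
ties) of the stimuli: a relation is *forced* when it holds in every ordering
consistent with the base set, and a pair is known-unknown when the
determinate closure places both stimuli strictly on the same side of some
third stimulus. Enumeration is exhaustive per connected component (≤ 8
stimuli each), giving ground truth that is independent of the sweep engine.

## Worked example

```bash
relframe derive A=B B=C --out table1.csv
```

prints

```
From To Operator                  Derivation_Level Relation Edge_color Derived_from
   A  B        =                  Directly Trained    A = B       Blue           NA
   B  A        =                 Mutually Entailed    B = A     Purple           NA
   B  C        =                  Directly Trained    B = C       Blue           NA
   C  B        =                 Mutually Entailed    C = B     Purple           NA
   A  C        =          Combinatorially Entailed    A = C     Orange  A = B,B = C
   C  A        = Combinatorially Mutually Entailed    C = A     Orange  A = B,B = C
# 6 records over 3 stimuli (2 trained, 4 derived), 1 network(s)
```

— the two trained equivalences (Blue), their reversals (Purple), and the
combinatorial closure `A = C` / `C = A` (Orange) with the parent pair that
derived them. The same pipeline scales up: the shipped `tutorial3` fixture
(8 trained statements over 10 stimuli, mixing `<`, `=`, and `ku`) closes to
48 statements that split into two isolated networks:

```bash
relframe derive --fixture tutorial3 --out table3.csv
relframe graph table3.csv --components
#   g h i j k m
#   l n o p
relframe graph table3.csv --format png --out net.png --no-ce-labels
```

`relframe validate --fixture tutorial3` re-derives the set and checks it
against the brute-force oracle (exit 0 on agreement; contradictory bases are
reported with exit 3, since the oracle — unlike the engine — refuses them).

The same operations are available as library functions
(`relation_train`, `build_graph`, `connected_components`, `check_agreement`,
`count_input_forms`, …); see the docstrings and `docs/methods.md`.

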
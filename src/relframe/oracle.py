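"""Brute-force semantic validator for the derivation engine.

The determinate operators =, < and > are interpreted over weak orderings —
rankings of the stimuli that allow ties, the minimal model in which all three
relations are expressible.  Enumerating every weak ordering consistent with a
base set gives ground truth that is independent of the sweep-based engine:

* a relation is *forced* when it holds between two stimuli in every consistent
  ordering (these are exactly the relations a sound and complete deriver must
  output), and
* a stimulus pair is *known-unknown* when the determinate closure places both
  stimuli strictly below, or both strictly above, some third stimulus — two
  premise chains that meet without resolving the pair's own direction.

KU statements in a base set carry no order information and are ignored by the
oracle.  Contradictory bases (no consistent ordering) are reported through
:class:`ContradictionError` rather than silently yielding nothing — the
engine, by design, tolerates contradictions while the oracle refuses them.

Enumeration is per connected component of the premise graph and is capped at
8 stimuli per component (ordered-Bell growth).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import pandas as pd

from .closure import DerivationTable
from .core import Operator, Statement, parse_statement

__all__ = [
    "WeakOrdering",
    "ContradictionError",
    "consistent_assignments",
    "forced_relations",
    "expected_ku",
    "check_agreement",
    "DiscrepancyReport",
    "MAX_ORACLE_STIMULI",
]

#: Enumeration cap per premise-connected component (545,835 weak orderings).
MAX_ORACLE_STIMULI = 8


class ContradictionError(ValueError):
    """No weak ordering satisfies the base set (contradictory premises)."""


@dataclass(frozen=True)
class WeakOrdering:
    """A ranking of stimuli with ties: rank 0 is lowest, ranks are contiguous."""

    ranks: tuple[tuple[str, int], ...]

    @property
    def assignment(self) -> dict[str, int]:
        return dict(self.ranks)

    def satisfies(self, statement: Statement) -> bool:
        """Whether the statement holds under this ordering.  KU statements
        constrain nothing and are vacuously satisfied."""
        if statement.op is Operator.KU:
            return True
        ranks = self.assignment
        left, right = ranks[statement.left], ranks[statement.right]
        if statement.op is Operator.EQ:
            return left == right
        if statement.op is Operator.LT:
            return left < right
        return left > right

    def relation(self, x: str, y: str) -> Operator:
        ranks = self.assignment
        if ranks[x] == ranks[y]:
            return Operator.EQ
        return Operator.LT if ranks[x] < ranks[y] else Operator.GT


def _ordered_block_partitions(items: list[str]) -> Iterator[list[list[str]]]:
    """All ordered set partitions (sequences of non-empty disjoint blocks)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in _ordered_block_partitions(rest):
        for i, block in enumerate(partial):
            yield partial[:i] + [[first] + block] + partial[i + 1 :]
        for i in range(len(partial) + 1):
            yield partial[:i] + [[first]] + partial[i:]


def _weak_orderings(stimuli: Sequence[str]) -> Iterator[WeakOrdering]:
    for blocks in _ordered_block_partitions(sorted(stimuli)):
        yield WeakOrdering(
            tuple((s, rank) for rank, block in enumerate(blocks) for s in block)
        )


def _coerce(base: Iterable[Union[str, Statement]]) -> list[Statement]:
    return [
        s if isinstance(s, Statement) else parse_statement(s) for s in base
    ]


def consistent_assignments(
    base: Iterable[Union[str, Statement]], stimuli: Iterable[str]
) -> list[WeakOrdering]:
    """All weak orderings of ``stimuli`` satisfying every non-KU base statement."""
    stimuli = sorted(set(stimuli))
    if len(stimuli) > MAX_ORACLE_STIMULI:
        raise ValueError(
            f"oracle enumeration is capped at {MAX_ORACLE_STIMULI} stimuli per "
            f"component, got {len(stimuli)}"
        )
    statements = [s for s in _coerce(base) if s.op is not Operator.KU]
    return [
        ordering
        for ordering in _weak_orderings(stimuli)
        if all(ordering.satisfies(s) for s in statements)
    ]


def _premise_components(statements: list[Statement]) -> list[list[str]]:
    """Connected components of the graph whose edges are the non-KU premises."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in statements:
        for stim in (s.left, s.right):
            parent.setdefault(stim, stim)
        parent[find(s.left)] = find(s.right)
    groups: dict[str, list[str]] = {}
    for stim in parent:
        groups.setdefault(find(stim), []).append(stim)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def forced_relations(
    base: Iterable[Union[str, Statement]]
) -> frozenset[Statement]:
    """All determinate statements holding in every consistent weak ordering.

    Evaluated per connected component of the non-KU premise graph; only pairs
    within one component can be forced.  Raises :class:`ContradictionError` if
    any component admits no consistent ordering.
    """
    statements = [s for s in _coerce(base) if s.op is not Operator.KU]
    forced: set[Statement] = set()
    for component in _premise_components(statements):
        members = set(component)
        local = [s for s in statements if s.left in members]
        orderings = consistent_assignments(local, component)
        if not orderings:
            raise ContradictionError(
                f"no consistent ordering for stimuli {component}: "
                "the base set is contradictory"
            )
        for x, y in itertools.permutations(component, 2):
            relations = {o.relation(x, y) for o in orderings}
            if len(relations) == 1:
                forced.add(Statement(x, relations.pop(), y))
    return frozenset(forced)


def expected_ku(
    base: Iterable[Union[str, Statement]]
) -> frozenset[Statement]:
    """The known-unknown statements the determinate closure warrants.

    ``(x, ku, y)`` is expected exactly when some stimulus ``s`` has both ``x``
    and ``y`` strictly below it, or both strictly above it, in the forced
    closure — stated here independently of the engine's sweep algorithm.
    """
    statements = [s for s in _coerce(base) if s.op is not Operator.KU]
    forced = forced_relations(statements)
    ku: set[Statement] = set()
    for component in _premise_components(statements):
        for x, y in itertools.permutations(component, 2):
            if x == y:
                continue
            for s in component:
                if s in (x, y):
                    continue
                below = (
                    Statement(x, Operator.LT, s) in forced
                    and Statement(y, Operator.LT, s) in forced
                )
                above = (
                    Statement(x, Operator.GT, s) in forced
                    and Statement(y, Operator.GT, s) in forced
                )
                if below or above:
                    ku.add(Statement(x, Operator.KU, y))
                    break
    return frozenset(ku)


@dataclass
class DiscrepancyReport:
    """Engine-vs-oracle comparison.  Empty on full agreement."""

    unsound: list[Statement] = field(default_factory=list)
    incomplete: list[Statement] = field(default_factory=list)
    ku_spurious: list[Statement] = field(default_factory=list)
    ku_missing: list[Statement] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (
            self.unsound or self.incomplete or self.ku_spurious or self.ku_missing
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"kind": kind, "statement": s.render()}
            for kind, bucket in (
                ("unsound", self.unsound),
                ("incomplete", self.incomplete),
                ("ku_spurious", self.ku_spurious),
                ("ku_missing", self.ku_missing),
            )
            for s in bucket
        ]
        return pd.DataFrame(rows, columns=["kind", "statement"])


def check_agreement(
    table: DerivationTable, base: Iterable[Union[str, Statement]]
) -> DiscrepancyReport:
    """Compare an engine-derived table against oracle ground truth.

    Three checks: (a) every determinate table statement must be forced
    (soundness); (b) every forced relation must be in the table
    (completeness); (c) the table's combinatorially derived KU statements must
    match :func:`expected_ku` exactly.  Trained and mutually entailed KU
    statements (KU statements present in the base) carry no semantic claim and
    are excluded from (c).
    """
    base_statements = _coerce(base)
    forced = forced_relations(base_statements)
    expected = expected_ku(base_statements)

    table_determinate = {
        r.statement for r in table.records if r.statement.op is not Operator.KU
    }
    table_ku_derived = {
        r.statement
        for r in table.records
        if r.statement.op is Operator.KU and r.level.is_combinatorial
    }
    by_text = lambda s: s.render()
    return DiscrepancyReport(
        unsound=sorted(table_determinate - forced, key=by_text),
        incomplete=sorted(forced - table_determinate, key=by_text),
        ku_spurious=sorted(table_ku_derived - expected, key=by_text),
        ku_missing=sorted(expected - table_ku_derived, key=by_text),
    )
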
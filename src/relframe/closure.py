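"""Fixed-point derivation of the complete relational network from a base set.

:func:`relation_train` seeds a table with the directly trained statements and
their mutual entailments, then repeatedly sweeps all pairs of recorded
statements, appending every new combinatorial entailment (immediately followed
by its mutual entailment) until a full sweep derives nothing new.  Each record
carries its derivation level, the edge colour used in visualisation, and — for
combinatorially derived statements — the two parent statements.

The engine deliberately performs no consistency checking: a contradictory base
set derives a table containing contradictory statements, modelling the fact
that derivation is a behavioural process rather than a logic proof.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd

from .core import (
    KUMode,
    Operator,
    ParseError,
    Statement,
    combinatorial_entail,
    make_context,
    mutual_entail,
    parse_statement,
    render_statement,
)

__all__ = [
    "DerivationLevel",
    "DerivationRecord",
    "DerivationTable",
    "relation_train",
    "dedup_relations",
    "summarize",
    "write_table",
    "read_table",
    "TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "From",
    "To",
    "Operator",
    "Derivation_Level",
    "Relation",
    "Edge_color",
    "Derived_from",
]


class DerivationLevel(enum.Enum):
    """How a statement entered the table. Edge colour is a function of level."""

    DIRECT = "Directly Trained"
    MUTUAL = "Mutually Entailed"
    COMBINATORIAL = "Combinatorially Entailed"
    COMBINATORIAL_MUTUAL = "Combinatorially Mutually Entailed"

    @property
    def color(self) -> str:
        if self is DerivationLevel.DIRECT:
            return "Blue"
        if self is DerivationLevel.MUTUAL:
            return "Purple"
        return "Orange"

    @property
    def is_combinatorial(self) -> bool:
        return self in (
            DerivationLevel.COMBINATORIAL,
            DerivationLevel.COMBINATORIAL_MUTUAL,
        )


@dataclass(frozen=True)
class DerivationRecord:
    """One table row: a statement, its derivation level, and its provenance.

    ``parents`` is empty for trained and mutually entailed statements and
    holds exactly the two combined parent statements for combinatorially
    derived ones.
    """

    statement: Statement
    level: DerivationLevel
    parents: tuple[Statement, ...] = ()

    def __post_init__(self) -> None:
        if self.level.is_combinatorial:
            if len(self.parents) != 2:
                raise ValueError(
                    f"combinatorially derived records need two parents, "
                    f"got {len(self.parents)}"
                )
        elif self.parents:
            raise ValueError(f"{self.level.value} records carry no parents")

    @property
    def color(self) -> str:
        return self.level.color


@dataclass
class DerivationTable:
    """Ordered, duplicate-free list of derivation records.

    Records appear in derivation (append) order.  No two records share the
    same ``(left, operator, right)`` triple, and every record's mutual
    entailment is also present.
    """

    records: list[DerivationRecord] = field(default_factory=list)
    ku_mode: Optional[KUMode] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DerivationRecord]:
        return iter(self.records)

    def statements(self) -> list[Statement]:
        return [r.statement for r in self.records]

    def statement_set(self) -> frozenset[Statement]:
        return frozenset(r.statement for r in self.records)

    @property
    def stimuli(self) -> frozenset[str]:
        return frozenset(
            s for r in self.records for s in (r.statement.left, r.statement.right)
        )

    def sorted(self) -> "DerivationTable":
        """Display-order copy: trained/mutual block before combinatorial block,
        each sorted by (From, To).  Derivation output itself stays in append
        order; this is cosmetic only."""
        key = lambda r: (
            r.level.is_combinatorial,
            r.statement.left,
            r.statement.right,
        )
        return DerivationTable(sorted(self.records, key=key), self.ku_mode)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            s = r.statement
            rows.append(
                {
                    "From": s.left,
                    "To": s.right,
                    "Operator": s.op.value,
                    "Derivation_Level": r.level.value,
                    "Relation": render_statement(s),
                    "Edge_color": r.color,
                    "Derived_from": (
                        ",".join(render_statement(p) for p in r.parents)
                        if r.parents
                        else "NA"
                    ),
                }
            )
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _coerce_statements(base: Sequence[Union[str, Statement]]) -> list[Statement]:
    parsed = []
    for item in base:
        if isinstance(item, Statement):
            parsed.append(item)
        else:
            try:
                parsed.append(parse_statement(item))
            except ParseError as exc:
                raise ParseError(f"invalid base statement {item!r}: {exc}") from exc
    return parsed


def _skip_pair(a: Statement, b: Statement, ku_mode: KUMode) -> bool:
    """Input filter applied before combination.

    Under ``off``/``emit`` KU statements never serve as combination inputs;
    under ``propagate`` only pairs of two KU statements are excluded (those
    would otherwise derive KU statements without end).
    """
    a_ku = a.op is Operator.KU
    b_ku = b.op is Operator.KU
    if ku_mode is KUMode.PROPAGATE:
        return a_ku and b_ku
    return a_ku or b_ku


def relation_train(
    base: Sequence[Union[str, Statement]],
    ku_mode: KUMode = KUMode.EMIT,
) -> DerivationTable:
    """Derive the complete relational network entailed by a base set.

    The seed pass records each base statement as Directly Trained (duplicates
    are dropped with a warning) followed by its mutual entailment — unless that
    entailment is itself a base statement, in which case the base statement
    keeps precedence and is recorded as Directly Trained when its turn comes.

    The closure loop then sweeps all unordered pairs of recorded statements in
    list order; every pair passing validation and the KU input filter is
    combined, and a new result is appended as Combinatorially Entailed with its
    parent pair, immediately followed by its mutual entailment
    (Combinatorially Mutually Entailed, same parents).  Sweeps repeat until one
    appends nothing.  The table is bounded by ``4 * n * (n - 1)`` records for
    ``n`` stimuli, which guarantees termination.

    A statement derivable through several pairs keeps the first derivation
    encountered (first-wins provenance).
    """
    if not base:
        raise ValueError("base set must contain at least one statement")
    parsed = _coerce_statements(base)
    base_triples = set(parsed)

    seen: dict[Statement, DerivationRecord] = {}
    records: list[DerivationRecord] = []

    def add(stmt: Statement, level: DerivationLevel, parents: tuple = ()) -> None:
        record = DerivationRecord(stmt, level, parents)
        seen[stmt] = record
        records.append(record)

    for stmt in parsed:
        if stmt in seen:
            logger.warning("duplicate base statement %s dropped", stmt)
            continue
        add(stmt, DerivationLevel.DIRECT)
        me = mutual_entail(stmt)
        if me not in seen and me not in base_triples:
            add(me, DerivationLevel.MUTUAL)

    sweep = 0
    while True:
        sweep += 1
        n = len(records)
        appended = 0
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = records[i].statement, records[j].statement
                if _skip_pair(si, sj, ku_mode):
                    continue
                ctx = make_context(si, sj)
                if ctx is None:
                    continue
                derived = combinatorial_entail(ctx, ku_mode)
                if derived is None or derived in seen:
                    continue
                add(derived, DerivationLevel.COMBINATORIAL, (si, sj))
                appended += 1
                me = mutual_entail(derived)
                if me not in seen:
                    add(me, DerivationLevel.COMBINATORIAL_MUTUAL, (si, sj))
                    appended += 1
        logger.info(
            "sweep %d: %d pairs examined, %d records appended (table size %d)",
            sweep,
            n * (n - 1) // 2,
            appended,
            len(records),
        )
        if appended == 0:
            break

    return DerivationTable(records, ku_mode)


def dedup_relations(table: DerivationTable) -> DerivationTable:
    """Keep the first record per rendered Relation string (first-wins).

    Engine output is already unique by triple, hence by Relation string, and
    passes through unchanged; externally loaded tables may carry duplicates.
    Idempotent.
    """
    seen: set[str] = set()
    kept = []
    for record in table.records:
        key = render_statement(record.statement)
        if key not in seen:
            seen.add(key)
            kept.append(record)
    return DerivationTable(kept, table.ku_mode)


def summarize(table: DerivationTable) -> dict:
    """Summary counts: records by level and operator, stimuli, trained vs
    derived, and the number of isolated networks (connected components)."""
    from .graphio import build_graph, connected_components  # local: avoids cycle

    by_level = {level.value: 0 for level in DerivationLevel}
    by_operator = {op.value: 0 for op in Operator}
    for record in table.records:
        by_level[record.level.value] += 1
        by_operator[record.statement.op.value] += 1
    trained = by_level[DerivationLevel.DIRECT.value]
    n_components = (
        len(connected_components(build_graph(table))) if table.records else 0
    )
    return {
        "total": len(table.records),
        "by_level": by_level,
        "by_operator": by_operator,
        "stimuli": len(table.stimuli),
        "trained": trained,
        "derived": len(table.records) - trained,
        "components": n_components,
    }


def write_table(table: DerivationTable, path: Union[str, Path]) -> None:
    """Write the table as CSV with the standard seven-column schema."""
    table.to_dataframe().to_csv(path, index=False)


_LEVEL_BY_LABEL = {level.value: level for level in DerivationLevel}


def read_table(path: Union[str, Path]) -> DerivationTable:
    """Load a derivation-table CSV.

    Requires the ``Relation``, ``Derivation_Level`` and ``Derived_from``
    columns; ``From``/``To``/``Operator`` are recovered from the Relation
    string and ``Edge_color`` is recomputed from the level when absent.
    ``read_table(write_table(t))`` reproduces ``t``'s records exactly.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"Relation", "Derivation_Level", "Derived_from"} - set(df.columns)
    if missing:
        raise ValueError(f"table CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        statement = parse_statement(row.Relation)
        level_label = row.Derivation_Level.strip()
        if level_label not in _LEVEL_BY_LABEL:
            raise ValueError(f"unknown derivation level {level_label!r}")
        level = _LEVEL_BY_LABEL[level_label]
        raw_parents = row.Derived_from.strip()
        parents: tuple[Statement, ...] = ()
        if raw_parents and raw_parents.upper() != "NA":
            parents = tuple(
                parse_statement(part) for part in raw_parents.split(",")
            )
        records.append(DerivationRecord(statement, level, parents))
    return DerivationTable(records)
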
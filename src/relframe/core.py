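"""Relational statements and the entailment rules that operate on pairs of them.

A relational statement relates two single-character stimuli through one of four
relational operators: equivalence (``=``), the comparatives less-than (``<``)
and greater-than (``>``), and the known-unknown operator (``ku``) standing for
a relation whose direction cannot be resolved from the available premises.

Two derivation rules act on statements:

* **Mutual entailment** reverses a statement (``A < B`` entails ``B > A``;
  equivalence and known-unknown are their own reverses).
* **Combinatorial entailment** combines two statements sharing exactly one
  stimulus into a statement relating their two unique stimuli
  (``A < B`` and ``B < C`` entail ``A < C``).

Statements are compared by their exact ``(left, operator, right)`` triple:
``A < B`` and ``B > A`` are distinct statements that coexist in derivation
output, mirroring how trained and mutually-entailed responses are recorded
separately.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "Operator",
    "KUMode",
    "Statement",
    "CombinationContext",
    "ParseError",
    "parse_statement",
    "render_statement",
    "mutual_entail",
    "make_context",
    "combinatorial_entail",
    "enumerate_input_forms",
    "count_input_forms",
    "STIMULUS_ALPHABET",
]

#: Legal stimulus symbols: digits, lower- and upper-case letters (case-sensitive).
STIMULUS_ALPHABET = (
    "0123456789abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"
)
_STIMULUS_SET = frozenset(STIMULUS_ALPHABET)


class Operator(enum.Enum):
    """The closed four-operator set. ``value`` is the surface token."""

    EQ = "="
    LT = "<"
    GT = ">"
    KU = "ku"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Operator map applied by mutual entailment when operands are swapped.
MUTUAL_OPERATOR = {
    Operator.EQ: Operator.EQ,
    Operator.LT: Operator.GT,
    Operator.GT: Operator.LT,
    Operator.KU: Operator.KU,
}


class KUMode(enum.Enum):
    """How indeterminate (known-unknown) derivations are handled.

    off
        Indeterminate combinations yield nothing; KU statements never
        participate in combination.
    emit
        Indeterminate combinations yield a KU statement, but KU statements
        never serve as combination inputs.  This is the default: it is the
        behaviour that reproduces the largest published worked example.
    propagate
        As ``emit``, and additionally a combinable pair containing exactly one
        KU statement derives a KU statement ("dominant transitivity").  Pairs
        of two KU statements never combine in any mode.
    """

    OFF = "off"
    EMIT = "emit"
    PROPAGATE = "propagate"


class ParseError(ValueError):
    """Raised for malformed statement text."""


@dataclass(frozen=True)
class Statement:
    """One ``(left, operator, right)`` relational statement."""

    left: str
    op: Operator
    right: str

    def __post_init__(self) -> None:
        for symbol in (self.left, self.right):
            if len(symbol) != 1 or symbol not in _STIMULUS_SET:
                raise ParseError(
                    f"stimulus must be a single alphanumeric character, got {symbol!r}"
                )
        if self.left == self.right:
            raise ParseError(
                f"self-relations are not defined (got {self.left!r} on both sides)"
            )

    def render(self) -> str:
        return render_statement(self)

    def __str__(self) -> str:
        return self.render()

    @property
    def stimuli(self) -> frozenset[str]:
        return frozenset((self.left, self.right))


def parse_statement(text: str) -> Statement:
    """Parse ``"<stimulus><operator><stimulus>"`` text into a :class:`Statement`.

    Whitespace anywhere in the input is ignored, so ``"A = B"`` and ``"A=B"``
    are the same statement.  ``ku`` is recognised as a two-character operator,
    e.g. ``"gkuj"`` parses to ``(g, KU, j)``.

    Raises
    ------
    ParseError
        For empty input, multi-character stimuli, unknown operators,
        non-alphanumeric stimulus symbols, or self-relations such as ``A=A``.
    """
    stripped = "".join(text.split())
    if not stripped:
        raise ParseError("empty relational statement")
    if len(stripped) == 4 and stripped[1:3] == "ku":
        left, op, right = stripped[0], Operator.KU, stripped[3]
    elif len(stripped) == 3 and stripped[1] in ("=", "<", ">"):
        left, op, right = stripped[0], Operator(stripped[1]), stripped[2]
    else:
        raise ParseError(
            f"cannot parse {text!r}: expected one stimulus character, one of "
            f"'=', '<', '>', 'ku', then one stimulus character"
        )
    return Statement(left, op, right)


def render_statement(s: Statement) -> str:
    """Canonical text form: ``"A = B"`` style for =, <, >; ``"gkuj"`` for ku."""
    if s.op is Operator.KU:
        return f"{s.left}ku{s.right}"
    return f"{s.left} {s.op.value} {s.right}"


def mutual_entail(s: Statement) -> Statement:
    """Return the mutually entailed statement: operands swapped, operator mapped
    ``= -> =``, ``< -> >``, ``> -> <``, ``ku -> ku``.  An involution."""
    return Statement(s.right, MUTUAL_OPERATOR[s.op], s.left)


@dataclass(frozen=True)
class CombinationContext:
    """A validated pair of statements sharing exactly one stimulus.

    ``rel_a_to_shared`` / ``rel_b_to_shared`` are the operators after each
    statement is normalised to the form ``unique OP shared`` (applying the
    mutual-entailment operator map when the unique stimulus sits on the
    right-hand side).
    """

    stmt_a: Statement
    stmt_b: Statement
    shared: str
    unique_a: str
    unique_b: str
    rel_a_to_shared: Operator
    rel_b_to_shared: Operator


def _normalise_to_shared(stmt: Statement, shared: str) -> tuple[str, Operator]:
    """Return ``(unique, op)`` with the statement read as ``unique op shared``."""
    if stmt.left == shared:
        return stmt.right, MUTUAL_OPERATOR[stmt.op]
    return stmt.left, stmt.op


def make_context(a: Statement, b: Statement) -> Optional[CombinationContext]:
    """Validate a statement pair for combination.

    Returns a :class:`CombinationContext` iff the two statements are distinct
    triples and share exactly one stimulus (four stimulus tokens, three unique
    names).  Pairs sharing zero or two stimuli are silently non-combinable and
    yield ``None`` — including a statement paired with its own mutual
    entailment, which is what prevents derivation loops.
    """
    if a == b:
        return None
    tokens = (a.left, a.right, b.left, b.right)
    if len(set(tokens)) != 3:
        return None
    (shared,) = a.stimuli & b.stimuli
    unique_a, rel_a = _normalise_to_shared(a, shared)
    unique_b, rel_b = _normalise_to_shared(b, shared)
    return CombinationContext(a, b, shared, unique_a, unique_b, rel_a, rel_b)


#: Decision table for combining ``da RA shared`` with ``db RB shared`` into
#: ``da R db``, over the determinate operators.
_DECISION_TABLE = {
    (Operator.EQ, Operator.EQ): Operator.EQ,
    (Operator.EQ, Operator.LT): Operator.GT,
    (Operator.EQ, Operator.GT): Operator.LT,
    (Operator.LT, Operator.EQ): Operator.LT,
    (Operator.GT, Operator.EQ): Operator.GT,
    (Operator.LT, Operator.GT): Operator.LT,
    (Operator.GT, Operator.LT): Operator.GT,
    (Operator.LT, Operator.LT): Operator.KU,
    (Operator.GT, Operator.GT): Operator.KU,
}


def combinatorial_entail(
    ctx: CombinationContext, ku_mode: KUMode = KUMode.EMIT
) -> Optional[Statement]:
    """Combine a validated pair into the statement relating its unique stimuli.

    With both normalised operators determinate the result comes from a fixed
    3x3 decision table; the ``(<,<)`` and ``(>,>)`` cells — two stimuli both
    below, or both above, the shared one — are indeterminate and produce a KU
    statement under ``emit``/``propagate`` or nothing under ``off``.

    A pair containing a KU statement produces nothing under ``off``/``emit``;
    under ``propagate`` a single-KU pair yields a KU statement.  Two KU
    statements never combine.
    """
    ra, rb = ctx.rel_a_to_shared, ctx.rel_b_to_shared
    if ra is Operator.KU or rb is Operator.KU:
        if ra is Operator.KU and rb is Operator.KU:
            return None
        if ku_mode is KUMode.PROPAGATE:
            return Statement(ctx.unique_a, Operator.KU, ctx.unique_b)
        return None
    result = _DECISION_TABLE[(ra, rb)]
    if result is Operator.KU and ku_mode is KUMode.OFF:
        return None
    return Statement(ctx.unique_a, result, ctx.unique_b)


def _statement_forms(include_equivalence: bool) -> list[Statement]:
    """Structurally unique single-statement forms over three labelled stimuli.

    Comparative statements are ordered stimulus pairs with ``<`` or ``>``
    (12 forms).  Equivalence statements are unordered stimulus pairs (3 forms:
    ``A = B`` and ``B = A`` are the same form, written canonically).
    """
    stimuli = "ABC"
    forms = [
        Statement(x, op, y)
        for x, y in itertools.permutations(stimuli, 2)
        for op in (Operator.LT, Operator.GT)
    ]
    if include_equivalence:
        forms.extend(
            Statement(x, Operator.EQ, y)
            for x, y in itertools.combinations(stimuli, 2)
        )
    return forms


def enumerate_input_forms(
    include_equivalence: bool = False,
) -> Iterator[tuple[Statement, Statement]]:
    """Yield the structurally unique input-pair forms for combination.

    A form is an unordered pair of distinct statements over three labelled
    stimuli sharing exactly one stimulus.  With ``include_equivalence`` at most
    one statement of the pair may be an equivalence statement.
    """
    for a, b in itertools.combinations(_statement_forms(include_equivalence), 2):
        if a.op is Operator.EQ and b.op is Operator.EQ:
            continue
        if len(set((a.left, a.right, b.left, b.right))) == 3:
            yield a, b


def count_input_forms(include_equivalence: bool = False) -> int:
    """Count the unique input-pair forms (48 comparative-only; 72 when one
    equivalence statement per pair is allowed)."""
    return sum(1 for _ in enumerate_input_forms(include_equivalence))
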
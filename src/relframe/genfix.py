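"""Published worked-example base sets and a seeded random base-set generator.

The four named fixtures are the exact base sets of the published tutorials
(three-stimulus equivalence network, three-stimulus mixed network, the
twelve-stimulus complex network that splits into two isolated networks) plus
the three-statement contradictory set used to demonstrate that derivation
tolerates inconsistency.  The same sets ship as one-statement-per-line text
files under ``relframe/data/`` for command-line use.

:func:`random_base_set` produces reproducible random base sets for
property-based testing and network-growth exploration.  Default operator
weights mirror the composition of the complex worked example — comparatives
dominate, with occasional equivalence and known-unknown statements.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .core import Operator, Statement, parse_statement
from .oracle import MAX_ORACLE_STIMULI, consistent_assignments

__all__ = ["FIXTURES", "fixture", "fixture_path", "GeneratorConfig", "random_base_set"]

FIXTURES: dict[str, list[str]] = {
    "tutorial1": ["A=B", "B=C"],
    "tutorial2": ["A>B", "B=C"],
    "tutorial3": ["gkuj", "h<i", "i<k", "k<j", "l<o", "mkuk", "n=o", "p>o"],
    "contradiction": ["A>B", "B=C", "C>A"],
}


def fixture(name: str) -> list[str]:
    """Return a named published base set (a fresh copy)."""
    try:
        return list(FIXTURES[name])
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


def fixture_path(name: str) -> Path:
    """Path to the shipped one-statement-per-line text file for a fixture."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    return Path(resources.files("relframe").joinpath(f"data/{name}.txt"))


def _default_weights() -> dict[str, float]:
    return {"<": 1.0, ">": 1.0, "=": 0.4, "ku": 0.4}


@dataclass
class GeneratorConfig:
    """Configuration for :func:`random_base_set`.

    ``operator_weights`` maps operator tokens to non-negative sampling weights
    (zero removes an operator); ``ensure_connected`` forces every statement
    after the first to reuse an already-mentioned stimulus, so the premises
    form a single connected network; ``require_consistent`` rejects and
    resamples sets that admit no weak ordering (oracle-checked, so it needs
    componentwise stimulus counts within the oracle cap).
    """

    n_stimuli: int = 6
    n_statements: int = 4
    operator_weights: dict[str, float] = field(default_factory=_default_weights)
    seed: int = 0
    ensure_connected: bool = True
    require_consistent: bool = False

    def __post_init__(self) -> None:
        if self.n_stimuli < 2:
            raise ValueError("need at least two stimuli")
        if self.n_statements < 1:
            raise ValueError("need at least one statement")
        if self.n_stimuli > len(_ALPHABET):
            raise ValueError(f"at most {len(_ALPHABET)} stimuli supported")
        weights = {Operator(k): v for k, v in self.operator_weights.items()}
        if any(v < 0 for v in weights.values()) or sum(weights.values()) <= 0:
            raise ValueError("operator weights must be non-negative with positive sum")


_ALPHABET = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def _sample_set(config: GeneratorConfig, rng: random.Random) -> list[Statement]:
    stimuli = list(_ALPHABET[: config.n_stimuli])
    operators = [Operator(k) for k, w in config.operator_weights.items() if w > 0]
    weights = [config.operator_weights[op.value] for op in operators]
    capacity = len(operators) * config.n_stimuli * (config.n_stimuli - 1)
    if config.n_statements > capacity:
        raise ValueError(
            f"cannot draw {config.n_statements} distinct statements from "
            f"{capacity} representable ones"
        )
    chosen: list[Statement] = []
    used: list[str] = []
    attempts = 0
    while len(chosen) < config.n_statements:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("generator failed to find a fresh statement")
        if config.ensure_connected and used:
            left = rng.choice(used)
        else:
            left = rng.choice(stimuli)
        right = rng.choice([s for s in stimuli if s != left])
        if rng.random() < 0.5:
            left, right = right, left
        op = rng.choices(operators, weights=weights)[0]
        candidate = Statement(left, op, right)
        if candidate in chosen:
            continue
        chosen.append(candidate)
        for s in (left, right):
            if s not in used:
                used.append(s)
    return chosen


def random_base_set(config: GeneratorConfig) -> list[str]:
    """Draw a reproducible random base set of distinct statements.

    Deterministic for a fixed seed.  With ``require_consistent`` the draw is
    repeated (bounded) until the non-KU premises admit at least one weak
    ordering in every connected component.
    """
    rng = random.Random(config.seed)
    for _ in range(1000):
        statements = _sample_set(config, rng)
        if not config.require_consistent:
            return [s.render() for s in statements]
        determinate = [s for s in statements if s.op is not Operator.KU]
        stimuli = {x for s in determinate for x in (s.left, s.right)}
        if len(stimuli) > MAX_ORACLE_STIMULI:
            raise ValueError(
                "require_consistent needs componentwise stimulus counts within "
                f"the oracle cap ({MAX_ORACLE_STIMULI})"
            )
        if not determinate or consistent_assignments(determinate, stimuli):
            return [s.render() for s in statements]
    raise ValueError("could not generate a consistent base set for this config")
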
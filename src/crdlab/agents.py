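"""Artificial-delegate agents programmed through strategy tables.

In the delegation treatments, a participant does not act round by round.
Instead they fill in a table that fully programs an agent:

* a **starting action** played unconditionally in round 1;
* **Strategy 1** — for every value of the other members' previous-round
  average contribution (rounded to the closest element of the action
  space), the action to play next;
* a **switch value** between 0 and 120 — once the public account reaches
  it, the agent permanently abandons Strategy 1;
* **Strategy 2** — a second reaction table of the same shape, used after
  the switch fires.

The switch is checked at round boundaries against the public account
accumulated through the previous round, and is irreversible.  Because the
public account never decreases, "has ever reached" and "currently at or
above" coincide, so the policy below is stateless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .game import CRDConfigError, GameConfig, RoundPolicy

__all__ = [
    "StrategyTable",
    "TableClassification",
    "round_to_space",
    "delegate_policy",
    "classify_table",
]

SWITCH_MAX = 120  # upper bound participants could enter for the switch value


def round_to_space(average: float, space: Sequence[int], tie: str = "up") -> int:
    """Round a real-valued average to the closest element of the action space.

    Ties are broken toward the larger element by default (``tie="up"``);
    ``tie="down"`` flips the rule for sensitivity checks.  In the study's
    spaces the rule only matters for the 3-choice space at averages 1.0
    and 3.0.  Elements of the space map to themselves.
    """
    if tie not in ("up", "down"):
        raise ValueError(f"tie must be 'up' or 'down', got {tie!r}")
    space = tuple(space)
    if not 0 <= average <= max(space):
        raise ValueError(
            f"average {average} outside the valid range [0, {max(space)}]"
        )
    best = space[0]
    best_dist = abs(average - best)
    for a in space[1:]:
        d = abs(average - a)
        if d < best_dist or (d == best_dist and tie == "up"):
            best, best_dist = a, d
    return best


def _as_entries(mapping: Union[Mapping[int, int], Sequence[int]],
                space: tuple[int, ...], name: str) -> tuple[int, ...]:
    if isinstance(mapping, Mapping):
        missing = [a for a in space if a not in mapping]
        if missing:
            raise CRDConfigError(f"{name} is missing entries for {missing}")
        extra = [a for a in mapping if a not in space]
        if extra:
            raise CRDConfigError(f"{name} has entries for non-actions {extra}")
        entries = tuple(int(mapping[a]) for a in space)
    else:
        entries = tuple(int(v) for v in mapping)
        if len(entries) != len(space):
            raise CRDConfigError(
                f"{name} must have {len(space)} entries, got {len(entries)}"
            )
    bad = [v for v in entries if v not in space]
    if bad:
        raise CRDConfigError(f"{name} maps to values outside the space: {bad}")
    return entries


@dataclass(frozen=True)
class StrategyTable:
    """A delegate agent's full program.

    ``strategy1`` and ``strategy2`` are stored as tuples aligned with
    ``action_space``: entry *i* is the action to play when the others'
    rounded previous-round average equals ``action_space[i]``.  Dicts
    keyed by rounded average are accepted on construction.
    """

    action_space: tuple[int, ...]
    starting_action: int
    strategy1: tuple[int, ...]
    switch_value: int
    strategy2: tuple[int, ...]

    def __post_init__(self) -> None:
        space = tuple(int(a) for a in self.action_space)
        object.__setattr__(self, "action_space", space)
        object.__setattr__(self, "strategy1",
                           _as_entries(self.strategy1, space, "strategy1"))
        object.__setattr__(self, "strategy2",
                           _as_entries(self.strategy2, space, "strategy2"))
        if self.starting_action not in space:
            raise CRDConfigError(
                f"starting_action {self.starting_action} not in {space}"
            )
        if not 0 <= self.switch_value <= SWITCH_MAX:
            raise CRDConfigError(
                f"switch_value must lie in [0, {SWITCH_MAX}], got {self.switch_value}"
            )

    def reaction(self, strategy: int, rounded_avg: int) -> int:
        """Action of strategy 1 or 2 at a rounded others' average."""
        entries = self.strategy1 if strategy == 1 else self.strategy2
        return entries[self.action_space.index(rounded_avg)]


def delegate_policy(table: StrategyTable, config: GameConfig,
                    tie: str = "up") -> RoundPolicy:
    """Compile a strategy table into a round policy.

    Round 1 plays the starting action.  From round 2 on, Strategy 2 is
    active iff the pre-round public account has reached the switch value
    (sticky by monotonicity of the account); the active strategy is looked
    up at the others' previous-round average rounded into the space.
    """
    if table.action_space != config.action_space:
        raise CRDConfigError(
            f"table action space {table.action_space} does not match the "
            f"game's {config.action_space}"
        )
    space = table.action_space

    def policy(round_index: int, others_avg, public_account: int) -> int:
        if round_index == 1:
            return table.starting_action
        entries = (table.strategy2 if public_account >= table.switch_value
                   else table.strategy1)
        return entries[space.index(round_to_space(others_avg, space, tie=tie))]

    return policy


@dataclass(frozen=True)
class TableClassification:
    strategy1_constant: bool
    fully_constant: bool


def classify_table(table: StrategyTable) -> TableClassification:
    """Detect unconditionally programmed agents.

    ``strategy1_constant``: all Strategy 1 entries equal.  ``fully_constant``
    (a "truly fixed-behavior" program): Strategy 2 entries and the starting
    action all equal that same value too, so the realized behavior is
    literally fixed whatever the group does.
    """
    s1_const = len(set(table.strategy1)) == 1
    fully = (
        s1_const
        and len(set(table.strategy2)) == 1
        and table.strategy2[0] == table.strategy1[0]
        and table.starting_action == table.strategy1[0]
    )
    return TableClassification(strategy1_constant=s1_const, fully_constant=fully)
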
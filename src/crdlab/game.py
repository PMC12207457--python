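"""Collective-risk dilemma (CRD) game engine.

The CRD is a threshold public goods game: a group of players, each endowed
with a private stock of ECoins, contributes over a fixed number of rounds to
a shared public account.  If the account reaches a collective threshold,
every player keeps whatever remains of their endowment.  If it falls short,
the whole group faces a single gamble: with probability ``risk`` everybody
loses their remaining endowment, otherwise everybody keeps it.

This module provides the deterministic accounting (contributions, public
account, private accounts) and the stochastic risk resolution.  Strategy
logic lives elsewhere; the engine only knows about *round policies* —
callables ``policy(round_index, others_prev_avg, public_account) -> action``
where ``round_index`` is 1-based, ``others_prev_avg`` is the average of the
other members' contributions in the previous round (``None`` in round 1,
when no history exists), and ``public_account`` is the account total before
the current round.  Moves within a round are simultaneous: every policy in
a round observes the same pre-round public account.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "THREE_CHOICES",
    "FIVE_CHOICES",
    "NO_HISTORY",
    "RoundPolicy",
    "GameConfig",
    "GroupTrajectory",
    "CRDConfigError",
    "InvalidActionError",
    "default_config",
    "play_game",
    "resolve_outcome",
    "constant_policy",
    "as_rng",
]

#: The two action spaces used in the study: coarse (3 choices) and fine (5).
THREE_CHOICES: tuple[int, ...] = (0, 2, 4)
FIVE_CHOICES: tuple[int, ...] = (0, 1, 2, 3, 4)

#: Sentinel passed to policies in round 1, where no previous round exists.
NO_HISTORY = None

RoundPolicy = Callable[[int, Optional[float], int], int]

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


class CRDConfigError(ValueError):
    """Raised for invalid game configurations or mismatched policy sets."""


class InvalidActionError(ValueError):
    """Raised when a policy returns an action outside the action space."""


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GameConfig:
    """All parameters of one CRD treatment.

    Defaults are the study conditions: groups of 4, 10 rounds, endowment 40,
    threshold 80, risk 50%, and the 3-choice action space (0, 2, 4).
    """

    group_size: int = 4
    rounds: int = 10
    endowment: int = 40
    threshold: int = 80
    risk: float = 0.5
    action_space: tuple[int, ...] = THREE_CHOICES

    def __post_init__(self) -> None:
        object.__setattr__(self, "action_space", tuple(int(a) for a in self.action_space))
        if self.group_size < 2:
            raise CRDConfigError(f"group_size must be >= 2, got {self.group_size}")
        if self.rounds < 1:
            raise CRDConfigError(f"rounds must be >= 1, got {self.rounds}")
        if self.endowment < 0 or self.threshold < 0:
            raise CRDConfigError("endowment and threshold must be nonnegative")
        if not 0.0 <= self.risk <= 1.0:
            raise CRDConfigError(f"risk must lie in [0, 1], got {self.risk}")
        space = self.action_space
        if len(space) < 2 or any(b <= a for a, b in zip(space, space[1:])):
            raise CRDConfigError(f"action_space must be strictly increasing, got {space}")
        if 0 not in space:
            raise CRDConfigError("action_space must contain 0")
        if max(space) * self.rounds > self.endowment:
            raise CRDConfigError(
                "max action x rounds exceeds the endowment; a player could overdraw"
            )

    @property
    def n_choices(self) -> int:
        return len(self.action_space)


def default_config(choices: int = 3, **overrides) -> GameConfig:
    """The study's default configuration for the 3- or 5-choice treatment."""
    if choices == 3:
        space = THREE_CHOICES
    elif choices == 5:
        space = FIVE_CHOICES
    else:
        raise CRDConfigError(f"choices must be 3 or 5, got {choices}")
    return GameConfig(action_space=space, **overrides)


@dataclass(frozen=True)
class GroupTrajectory:
    """Complete record of one group's game, including resolved payoffs.

    ``contributions`` has shape (rounds, group_size); ``risk_draw`` is the
    group-level loss event and is ``None`` when the group succeeded (no
    gamble takes place).  ``payoffs`` are final ECoins per player.
    """

    config: GameConfig
    contributions: np.ndarray
    public_account_by_round: np.ndarray
    final_public_account: int
    success: bool
    risk_draw: Optional[bool]
    payoffs: np.ndarray

    @property
    def total_contributions(self) -> np.ndarray:
        """Per-player total contribution over the whole game."""
        return self.contributions.sum(axis=0)

    @property
    def private_accounts(self) -> np.ndarray:
        """Pre-risk private accounts: endowment minus own total contribution."""
        return self.config.endowment - self.total_contributions


def _validate_contributions(contributions: np.ndarray, config: GameConfig) -> np.ndarray:
    arr = np.asarray(contributions, dtype=int)
    if arr.shape != (config.rounds, config.group_size):
        raise CRDConfigError(
            f"contributions must have shape {(config.rounds, config.group_size)}, "
            f"got {arr.shape}"
        )
    if not np.isin(arr, config.action_space).all():
        bad = arr[~np.isin(arr, config.action_space)]
        raise InvalidActionError(
            f"contributions contain values outside the action space "
            f"{config.action_space}: {sorted(set(bad.tolist()))}"
        )
    return arr


def resolve_outcome(
    contributions: Sequence[Sequence[int]],
    config: GameConfig,
    seed: SeedLike = None,
) -> GroupTrajectory:
    """Resolve a completed contribution table into a full trajectory.

    Success is deterministic (final public account >= threshold, boundary
    inclusive).  On failure a single group-level Bernoulli(risk) loss event
    is drawn and shared by all members: everyone's payoff is zero if it
    fires, otherwise everyone keeps their remaining endowment.
    """
    arr = _validate_contributions(contributions, config)
    by_round = arr.sum(axis=1).cumsum()
    final = int(by_round[-1])
    success = final >= config.threshold
    remaining = config.endowment - arr.sum(axis=0)
    if success:
        risk_draw: Optional[bool] = None
        payoffs = remaining
    else:
        risk_draw = bool(as_rng(seed).random() < config.risk)
        payoffs = np.zeros_like(remaining) if risk_draw else remaining
    return GroupTrajectory(
        config=config,
        contributions=arr,
        public_account_by_round=by_round,
        final_public_account=final,
        success=success,
        risk_draw=risk_draw,
        payoffs=payoffs,
    )


def play_game(
    policies: Sequence[RoundPolicy],
    config: Optional[GameConfig] = None,
    seed: SeedLike = None,
) -> GroupTrajectory:
    """Play one CRD with one round policy per player.

    ``seed`` drives only the risk resolution; stochastic policies carry
    their own random state.  Policies are queried simultaneously within a
    round: each sees the public account as of the end of the previous round
    and the other members' previous-round average (``None`` in round 1).
    """
    config = config or GameConfig()
    if len(policies) != config.group_size:
        raise CRDConfigError(
            f"expected {config.group_size} policies, got {len(policies)}"
        )
    n = config.group_size
    contrib = np.zeros((config.rounds, n), dtype=int)
    public_account = 0
    for r in range(config.rounds):
        if r == 0:
            others_avg = [NO_HISTORY] * n
        else:
            prev = contrib[r - 1]
            prev_total = prev.sum()
            others_avg = [(prev_total - prev[i]) / (n - 1) for i in range(n)]
        for i, policy in enumerate(policies):
            action = policy(r + 1, others_avg[i], public_account)
            if action not in config.action_space:
                raise InvalidActionError(
                    f"player {i} returned {action!r} in round {r + 1}, "
                    f"not in action space {config.action_space}"
                )
            contrib[r, i] = action
        public_account += int(contrib[r].sum())
    return resolve_outcome(contrib, config, seed)


def constant_policy(action: int) -> RoundPolicy:
    """A policy that plays the same action every round (testing/baselines)."""

    def policy(round_index: int, others_avg: Optional[float], public_account: int) -> int:
        return action

    return policy
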
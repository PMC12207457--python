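"""Synthetic study populations with behavioral profiles and revision.

The generator emulates the statistical structure the analysis layer
assumes for the 2x2 (number of choices x delegation) experiment:

* four behavioral profiles — **early** (high contributions in rounds 1–5,
  low afterwards), **high**, **fair** (the 2-ECoins fair share each round)
  and **low** contributors — as latent per-round target levels;
* treatment-specific mixtures over the profiles, anchored on the printed
  fair-contributor shares (46/57% for 3 choices, 47/40% for 5 choices in
  delegation/no-delegation) with the remainder split so that delegation
  cells carry more high and low contributors and no-delegation cells more
  early contributors;
* in delegation cells, participant-programmed strategy tables sampled
  around the profile (conditional with probability ``p_conditional``,
  jittered per entry), replayed by the deterministic delegate interpreter;
* in no-delegation cells, noisy round policies snapped to the action space;
* outcome-dependent revision between Game 1 and a surprise-restart Game 2:
  members of failed delegation groups shift their latent targets up,
  successful delegation groups that overshot correct slightly down, and
  members of failed no-delegation groups give up (become exact
  zero-contributors) with probability ``p_giveup``.

Everything derives from a single master seed via ``numpy`` seed-sequence
spawning, so a :class:`StudyDesign` reproduces byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agents import StrategyTable, delegate_policy, round_to_space
from .dataio import StudyDataset
from .game import (
    CRDConfigError,
    GameConfig,
    GroupTrajectory,
    RoundPolicy,
    as_rng,
    default_config,
    play_game,
)

__all__ = [
    "PROFILE_LABELS",
    "BehaviorProfile",
    "RevisionParams",
    "StudyDesign",
    "MemberState",
    "default_profile",
    "profile_policy",
    "sample_strategy_table",
    "revise_behavior",
    "generate_study",
    "design_from_json",
    "design_to_json",
]

PROFILE_LABELS = ("early", "high", "fair", "low")

ROUNDS = 10

# Latent per-round targets (ECoins). "fair" is the per-round fair share 2;
# "low" at 0.8 snaps to 0 in the 3-choice space and to 1 in the 5-choice
# space (selfish without contributing nothing); "high" at 3.5 snaps to 4.
DEFAULT_TARGETS: Mapping[str, tuple[float, ...]] = {
    "early": (4.0,) * 5 + (0.0,) * 5,
    "high": (3.5,) * ROUNDS,
    "fair": (2.0,) * ROUNDS,
    "low": (0.8,) * ROUNDS,
}


@dataclass(frozen=True)
class BehaviorProfile:
    """A latent behavioral profile: label, per-round targets, noise level."""

    label: str
    targets: tuple[float, ...]
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(float(t) for t in self.targets))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(self.targets) != ROUNDS:
            raise ValueError(f"targets must have length {ROUNDS}")


def default_profile(label: str, noise_sd: float = 0.5) -> BehaviorProfile:
    if label not in PROFILE_LABELS:
        raise ValueError(f"unknown profile label {label!r}")
    return BehaviorProfile(label=label, targets=DEFAULT_TARGETS[label], noise_sd=noise_sd)


@dataclass(frozen=True)
class RevisionParams:
    """Between-game revision magnitudes (ECoins on the latent scale).

    ``delta_up``: upward target shift after group failure in delegation
    cells.  ``delta_down``: downward correction after success when the
    group overshot the threshold (delegation).  ``p_giveup``: probability
    that a member of a failed no-delegation group becomes an exact
    zero-contributor in Game 2.
    """

    delta_up: float = 1.0
    delta_down: float = 0.5
    p_giveup: float = 0.5


Cell = tuple[int, bool]  # (choices, delegation)

CELLS: tuple[Cell, ...] = ((3, True), (3, False), (5, True), (5, False))

# Group counts per cell matching the study's printed sample sizes
# (115 groups total; 108 and 176 delegation individuals for 3/5 choices).
DEFAULT_N_GROUPS: Mapping[Cell, int] = {
    (3, True): 27,
    (3, False): 22,
    (5, True): 44,
    (5, False): 22,
}

# Profile mixtures per cell.  Fair shares are the printed values; the
# remainder is split so delegation carries more high/low contributors and
# no-delegation more early contributors, with fewer low contributors in
# the 5-choice no-delegation cell.
DEFAULT_MIXTURES: Mapping[Cell, Mapping[str, float]] = {
    (3, True): {"early": 0.10, "high": 0.28, "fair": 0.46, "low": 0.16},
    (3, False): {"early": 0.24, "high": 0.04, "fair": 0.57, "low": 0.15},
    (5, True): {"early": 0.12, "high": 0.25, "fair": 0.47, "low": 0.16},
    (5, False): {"early": 0.42, "high": 0.13, "fair": 0.40, "low": 0.05},
}


@dataclass(frozen=True)
class StudyDesign:
    """Full specification of one synthetic study run."""

    n_groups: Mapping[Cell, int] = field(
        default_factory=lambda: dict(DEFAULT_N_GROUPS))
    mixtures: Mapping[Cell, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_MIXTURES.items()})
    noise_sd: float = 0.5
    p_conditional: float = 0.9
    revision: RevisionParams = field(default_factory=RevisionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, n in self.n_groups.items():
            if n < 1:
                raise CRDConfigError(f"n_groups for cell {cell} must be >= 1")
            mix = self.mixtures[cell]
            if set(mix) - set(PROFILE_LABELS):
                raise CRDConfigError(
                    f"mixture for cell {cell} names unknown profiles: "
                    f"{sorted(set(mix) - set(PROFILE_LABELS))}"
                )
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise CRDConfigError(
                    f"mixture for cell {cell} sums to {total}, expected 1"
                )

    @property
    def cells(self) -> tuple[Cell, ...]:
        return tuple(self.n_groups)


def profile_policy(profile: BehaviorProfile, space: Sequence[int],
                   seed=None) -> RoundPolicy:
    """A noisy round policy tracking the profile's latent targets.

    Each round plays ``round_to_space(clip(target + N(0, noise_sd)))``.
    With ``noise_sd == 0`` the policy is deterministic.  The policy owns
    its random stream; replaying it with the same seed replays the noise.
    """
    rng = as_rng(seed)
    space = tuple(space)
    hi = float(max(space))

    def policy(round_index: int, others_avg, public_account: int) -> int:
        latent = profile.targets[round_index - 1]
        if profile.noise_sd > 0:
            latent += rng.normal(0.0, profile.noise_sd)
        return round_to_space(min(max(latent, 0.0), hi), space)

    return policy


def _snap(x: float, space: tuple[int, ...], tie: str = "up") -> int:
    hi = float(max(space))
    return round_to_space(min(max(x, 0.0), hi), space, tie=tie)


# Strength of conditional (reciprocal) response: how much a table entry
# leans toward the others' observed average around the fair-share anchor 2.
RECIPROCITY = 0.4

# Early contributors switch strategies once the account nears the halfway
# mark: against fair-share opponents the account passes ~50 after round 5.
EARLY_SWITCH_MEAN = 50.0
EARLY_SWITCH_SD = 10.0
EARLY_SWITCH_CAP = 80


def sample_strategy_table(profile: BehaviorProfile, space: Sequence[int],
                          seed=None, p_conditional: float = 0.9,
                          tie: str = "up") -> StrategyTable:
    """Sample a delegate strategy table realizing the profile.

    Conditional tables (probability ``p_conditional``) react to the others'
    rounded average with slope ``RECIPROCITY`` around the fair share, with
    per-entry Gaussian jitter of sd ``profile.noise_sd``; the entry at the
    fair-share average reproduces the profile target, so replay against
    fair opponents matches the target levels in expectation.  Early
    profiles implement their drop through the switch: Strategy 1 encodes
    the early (rounds 1–5) level, Strategy 2 the late level, with the
    switch drawn around the public-account level a fair-track group passes
    mid-game.  Non-early profiles get Strategy 2 identical to Strategy 1
    and an inert switch.  With ``p_conditional == 0`` the table is fully
    constant (same action everywhere, including the starting action).
    """
    rng = as_rng(seed)
    space = tuple(space)
    sd = profile.noise_sd
    targets = profile.targets

    if rng.random() >= p_conditional:
        c = _snap(float(np.mean(targets)) + rng.normal(0.0, sd), space, tie)
        const = (c,) * len(space)
        return StrategyTable(space, c, const, SWITCH_INERT, const)

    t_early = float(np.mean(targets[:5]))
    t_late = float(np.mean(targets[5:]))

    def entries(level: float) -> tuple[int, ...]:
        # A conditional program should actually react: redraw the jitter if
        # snapping collapsed every entry to one action.  With sd = 0 the
        # draw is deterministic, so constancy is accepted after the cap.
        for _ in range(20):
            out = tuple(
                _snap(level + RECIPROCITY * (a - 2.0) + rng.normal(0.0, sd),
                      space, tie)
                for a in space
            )
            if len(set(out)) > 1 or sd == 0:
                return out
        return out

    s1 = entries(t_early)
    if profile.label == "early":
        s2 = entries(t_late)
        switch = int(np.clip(round(rng.normal(EARLY_SWITCH_MEAN, EARLY_SWITCH_SD)),
                             0, EARLY_SWITCH_CAP))
    else:
        s2 = s1
        switch = SWITCH_INERT
    start = _snap(targets[0] + rng.normal(0.0, sd), space, tie)
    return StrategyTable(space, start, s1, switch, s2)


# Switch value used when Strategy 2 equals Strategy 1 (firing is harmless).
SWITCH_INERT = 120


@dataclass
class MemberState:
    """One participant's latent state: profile, and table for delegation."""

    player_id: str
    profile: BehaviorProfile
    space: tuple[int, ...]
    delegation: bool
    p_conditional: float
    table_seed: Optional[np.random.SeedSequence] = None
    table: Optional[StrategyTable] = None


def _build_table(member: MemberState) -> StrategyTable:
    return sample_strategy_table(
        member.profile, member.space, seed=np.random.default_rng(member.table_seed),
        p_conditional=member.p_conditional,
    )


def revise_behavior(member: MemberState, group_success: bool,
                    delegation: bool, params: RevisionParams, seed=None,
                    overshoot: int = 0) -> MemberState:
    """Revise a member's latent behavior after seeing the Game 1 outcome.

    Delegation: failure shifts the latent targets up by ``delta_up``;
    success with overshoot corrects down by ``delta_down``; the revised
    table is rebuilt from the member's own table seed, so all-zero
    parameters reproduce the Game 1 table exactly.  No-delegation: after
    failure the member gives up (targets 0, noise 0) with probability
    ``p_giveup``; otherwise, and always after success, behavior is
    unchanged up to noise.
    """
    rng = as_rng(seed)
    hi = float(max(member.space))
    profile = member.profile
    if delegation:
        if not group_success:
            shift = params.delta_up
        elif overshoot > 0:
            shift = -params.delta_down
        else:
            shift = 0.0
        new_targets = tuple(min(max(t + shift, 0.0), hi) for t in profile.targets)
        new_profile = replace(profile, targets=new_targets)
        revised = replace_member(member, new_profile)
        revised.table = _build_table(revised)
        return revised
    if not group_success and rng.random() < params.p_giveup:
        new_profile = BehaviorProfile(label="low", targets=(0.0,) * ROUNDS,
                                      noise_sd=0.0)
        return replace_member(member, new_profile)
    return replace_member(member, profile)


def replace_member(member: MemberState, profile: BehaviorProfile) -> MemberState:
    return MemberState(
        player_id=member.player_id,
        profile=profile,
        space=member.space,
        delegation=member.delegation,
        p_conditional=member.p_conditional,
        table_seed=member.table_seed,
        table=member.table,
    )


def _table_row(gid: str, game: int, member: MemberState) -> dict:
    t = member.table
    row = {
        "group_id": gid,
        "game": game,
        "player_id": member.player_id,
        "profile": member.profile.label,
        "start": t.starting_action,
        "switch": t.switch_value,
    }
    for a, v in zip(t.action_space, t.strategy1):
        row[f"s1_at_{a}"] = v
    for a, v in zip(t.action_space, t.strategy2):
        row[f"s2_at_{a}"] = v
    return row


def _emit_rows(rows: list, gid: str, game: int, members: Sequence[MemberState],
               traj: GroupTrajectory, choices: int, delegation: bool) -> None:
    loss = traj.risk_draw if traj.risk_draw is not None else ""
    for r in range(traj.config.rounds):
        pa = int(traj.public_account_by_round[r])
        for i, m in enumerate(members):
            rows.append((
                gid, game, r + 1, m.player_id, choices, delegation,
                int(traj.contributions[r, i]), pa, traj.success, loss,
                int(traj.payoffs[i]), m.profile.label,
            ))


def generate_study(design: StudyDesign) -> StudyDataset:
    """Simulate the full factorial study specified by ``design``.

    For every group: sample member profiles from the cell mixture, build
    tables (delegation) or noisy policies (no-delegation), play Game 1,
    revise each member given the outcome, and play Game 2 with the same
    composition.  All randomness flows from the design's master seed via
    per-cell / per-group seed-sequence spawning.
    """
    root = np.random.SeedSequence(design.seed)
    cell_seeds = root.spawn(len(design.cells))
    rows: list[tuple] = []
    table_rows: list[dict] = []

    for cell_ss, cell in zip(cell_seeds, design.cells):
        choices, delegation = cell
        config = default_config(choices)
        space = config.action_space
        mix = design.mixtures[cell]
        probs = np.array([mix.get(lbl, 0.0) for lbl in PROFILE_LABELS])
        n_groups = design.n_groups[cell]
        group_seeds = cell_ss.spawn(n_groups)
        tag = f"{choices}{'d' if delegation else 'n'}"

        for g, gss in enumerate(group_seeds):
            gid = f"{tag}-g{g:03d}"
            (ss_profiles, ss_tables, ss_noise1, ss_risk1,
             ss_revise, ss_noise2, ss_risk2) = gss.spawn(7)
            rng_profiles = np.random.default_rng(ss_profiles)
            labels = rng_profiles.choice(len(PROFILE_LABELS),
                                         size=config.group_size, p=probs)
            table_seeds = ss_tables.spawn(config.group_size)
            members = [
                MemberState(
                    player_id=f"{gid}-p{i}",
                    profile=default_profile(PROFILE_LABELS[lbl], design.noise_sd),
                    space=space,
                    delegation=delegation,
                    p_conditional=design.p_conditional,
                    table_seed=table_seeds[i],
                )
                for i, lbl in enumerate(labels)
            ]

            def policies_for(game_members, noise_ss):
                if delegation:
                    for m in game_members:
                        m.table = _build_table(m)
                    return [delegate_policy(m.table, config) for m in game_members]
                children = noise_ss.spawn(len(game_members))
                return [
                    profile_policy(m.profile, space, seed=child)
                    for m, child in zip(game_members, children)
                ]

            traj1 = play_game(policies_for(members, ss_noise1), config, seed=ss_risk1)
            _emit_rows(rows, gid, 1, members, traj1, choices, delegation)
            if delegation:
                table_rows.extend(_table_row(gid, 1, m) for m in members)

            overshoot = max(0, traj1.final_public_account - config.threshold)
            revise_seeds = ss_revise.spawn(config.group_size)
            revised = [
                revise_behavior(m, traj1.success, delegation, design.revision,
                                seed=rseed, overshoot=overshoot)
                for m, rseed in zip(members, revise_seeds)
            ]

            if delegation:
                policies2 = [delegate_policy(m.table, config) for m in revised]
            else:
                policies2 = policies_for(revised, ss_noise2)
            traj2 = play_game(policies2, config, seed=ss_risk2)
            _emit_rows(rows, gid, 2, revised, traj2, choices, delegation)
            if delegation:
                table_rows.extend(_table_row(gid, 2, m) for m in revised)

    data = pd.DataFrame(rows, columns=[
        "group_id", "game", "round", "player_id", "treatment_choices",
        "treatment_delegation", "contribution", "public_account_after_round",
        "success", "loss_event", "payoff", "profile",
    ])
    tables = pd.DataFrame(table_rows) if table_rows else None
    return StudyDataset(data=data, tables=tables)


def design_to_json(design: StudyDesign) -> dict:
    """JSON-serializable form of a design (cells keyed by 'choices,deleg')."""
    return {
        "cells": [
            {
                "choices": c,
                "delegation": d,
                "n_groups": design.n_groups[(c, d)],
                "mixture": dict(design.mixtures[(c, d)]),
            }
            for (c, d) in design.cells
        ],
        "noise_sd": design.noise_sd,
        "p_conditional": design.p_conditional,
        "revision": {
            "delta_up": design.revision.delta_up,
            "delta_down": design.revision.delta_down,
            "p_giveup": design.revision.p_giveup,
        },
        "seed": design.seed,
    }


def design_from_json(obj: dict) -> StudyDesign:
    """Inverse of :func:`design_to_json`; missing fields take defaults."""
    kwargs: dict = {}
    if "cells" in obj:
        n_groups = {}
        mixtures = {}
        for cell in obj["cells"]:
            key = (int(cell["choices"]), bool(cell["delegation"]))
            n_groups[key] = int(cell["n_groups"])
            mixtures[key] = {k: float(v) for k, v in cell["mixture"].items()}
        kwargs["n_groups"] = n_groups
        kwargs["mixtures"] = mixtures
    for name in ("noise_sd", "p_conditional", "seed"):
        if name in obj:
            kwargs[name] = obj[name]
    if "revision" in obj:
        kwargs["revision"] = RevisionParams(**obj["revision"])
    return StudyDesign(**kwargs)
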
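"""Group- and individual-level summary statistics of CRD play.

Group level: the final public account, success, and the within-group
variance of the members' private accounts — the inequality measure.  The
variance is computed on *pre-risk* private accounts (endowment minus own
total contribution) with the sample (n-1) denominator: the loss gamble is
group-wide, so post-risk payoffs would only rescale, not reorder, the
asymmetry in contribution effort.  A post-risk variant is exposed for
sensitivity.

Individual level: the contribution frequency (fraction of rounds with a
strictly positive contribution), total contribution, and the between-game
contribution delta (Game 2 total minus Game 1 total).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataio import StudyDataset
from .game import GroupTrajectory

__all__ = [
    "GroupMetrics",
    "contribution_frequency",
    "group_metrics",
    "between_game_delta",
    "cluster_change_rate",
    "group_metrics_frame",
    "individual_metrics_frame",
]


@dataclass(frozen=True)
class GroupMetrics:
    final_public_account: int
    success: bool
    private_account_variance: float


def contribution_frequency(actions: Sequence[int], rounds: int = 10) -> float:
    """Fraction of rounds with a strictly positive contribution."""
    arr = np.asarray(actions)
    if arr.shape != (rounds,):
        raise ValueError(f"expected {rounds} actions, got shape {arr.shape}")
    return float((arr > 0).mean())


def group_metrics(trajectory: GroupTrajectory, post_risk: bool = False) -> GroupMetrics:
    """Summaries of one group's game.

    ``post_risk=True`` computes the variance on realized payoffs instead
    of pre-risk private accounts.
    """
    accounts = trajectory.payoffs if post_risk else trajectory.private_accounts
    return GroupMetrics(
        final_public_account=trajectory.final_public_account,
        success=trajectory.success,
        private_account_variance=float(np.var(accounts, ddof=1)),
    )


def between_game_delta(game1_actions: Sequence[int],
                       game2_actions: Sequence[int]) -> int:
    """Game 2 total contribution minus Game 1 total contribution."""
    a1, a2 = np.asarray(game1_actions), np.asarray(game2_actions)
    if a1.shape != a2.shape:
        raise ValueError(f"length mismatch: {a1.shape} vs {a2.shape}")
    return int(a2.sum() - a1.sum())


def cluster_change_rate(labels_game1: Sequence, labels_game2: Sequence) -> float:
    """Fraction of individuals whose behavior label differs between games."""
    l1, l2 = list(labels_game1), list(labels_game2)
    if len(l1) != len(l2):
        raise ValueError(f"length mismatch: {len(l1)} vs {len(l2)}")
    if not l1:
        raise ValueError("empty label sequences")
    return float(np.mean([a != b for a, b in zip(l1, l2)]))


def group_metrics_frame(dataset: StudyDataset, endowment: int = 40,
                        post_risk: bool = False) -> pd.DataFrame:
    """Tidy per-(group, game) metrics from a long-format study table."""
    d = dataset.data
    per_player = (
        d.groupby(["group_id", "game", "player_id"], sort=False)
        .agg(
            total=("contribution", "sum"),
            payoff=("payoff", "first"),
            choices=("treatment_choices", "first"),
            delegation=("treatment_delegation", "first"),
            success=("success", "first"),
        )
        .reset_index()
    )
    per_player["account"] = (
        per_player["payoff"] if post_risk else endowment - per_player["total"]
    )
    out = (
        per_player.groupby(["group_id", "game"], sort=False)
        .agg(
            final_public_account=("total", "sum"),
            success=("success", "first"),
            private_account_variance=("account", lambda s: s.var(ddof=1)),
            treatment_choices=("choices", "first"),
            treatment_delegation=("delegation", "first"),
        )
        .reset_index()
    )
    return out


def individual_metrics_frame(dataset: StudyDataset, rounds: int = 10) -> pd.DataFrame:
    """Tidy per-(player, game) metrics, with between-game deltas merged in."""
    d = dataset.data
    per = (
        d.groupby(["group_id", "player_id", "game"], sort=False)
        .agg(
            total_contribution=("contribution", "sum"),
            n_positive=("contribution", lambda s: int((s > 0).sum())),
            n_rounds=("contribution", "size"),
            treatment_choices=("treatment_choices", "first"),
            treatment_delegation=("treatment_delegation", "first"),
            success=("success", "first"),
        )
        .reset_index()
    )
    per["contribution_frequency"] = per["n_positive"] / per["n_rounds"]
    per = per.drop(columns=["n_positive", "n_rounds"])
    wide = per.pivot_table(index=["group_id", "player_id"], columns="game",
                           values="total_contribution", aggfunc="first")
    if {1, 2} <= set(wide.columns):
        delta = (wide[2] - wide[1]).rename("between_game_delta").reset_index()
        per = per.merge(delta, on=["group_id", "player_id"], how="left")
    else:
        per["between_game_delta"] = np.nan
    return per
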
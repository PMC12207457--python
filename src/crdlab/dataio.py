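"""Canonical study-data formats and the column-mapping adapter.

A study — synthetic or deposited — is held as a :class:`StudyDataset`: a
long-format table with one row per (group, game, round, player) plus, for
delegation cells, one strategy-table row per (player, game).  ``read_study``
validates files against the game's invariants and recomputes derivable
columns (public account, success) rather than trusting them; discrepancies
are raised with row references, never silently accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .game import FIVE_CHOICES, THREE_CHOICES, GameConfig, default_config

__all__ = [
    "CANONICAL_COLUMNS",
    "StudyDataset",
    "StudyValidationError",
    "write_study",
    "read_study",
    "action_vectors",
]

#: Required columns of the canonical long format, one row per
#: (group, game, round, player).
CANONICAL_COLUMNS = (
    "group_id",
    "game",
    "round",
    "player_id",
    "treatment_choices",
    "treatment_delegation",
    "contribution",
    "public_account_after_round",
    "success",
    "loss_event",
    "payoff",
)

#: Columns carried when present but not required (synthetic ground truth).
OPTIONAL_COLUMNS = ("profile",)


class StudyValidationError(ValueError):
    """A study file violated the canonical invariants.

    ``problems`` holds one message per violation, each with row references.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "\n  - ".join(self.problems[:10])
        more = "" if len(self.problems) <= 10 else f"\n  ... {len(self.problems) - 10} more"
        super().__init__(f"study validation failed:\n  - {preview}{more}")


@dataclass
class StudyDataset:
    """Long-format study records plus optional delegate strategy tables."""

    data: pd.DataFrame
    tables: Optional[pd.DataFrame] = None

    def config_for(self, choices: int) -> GameConfig:
        return default_config(int(choices))

    @property
    def n_groups(self) -> int:
        return self.data["group_id"].nunique()

    @property
    def n_individuals(self) -> int:
        return self.data.groupby(["group_id", "player_id"]).ngroups

    def cell(self, choices: int, delegation: bool) -> "StudyDataset":
        """Restrict to one treatment cell."""
        d = self.data
        mask = (d["treatment_choices"] == choices) & (
            d["treatment_delegation"] == delegation
        )
        t = self.tables
        if t is not None and len(t):
            gids = d.loc[mask, "group_id"].unique()
            t = t[t["group_id"].isin(gids)].reset_index(drop=True)
        return StudyDataset(d[mask].reset_index(drop=True), t)


def _space_for(choices: int) -> tuple[int, ...]:
    return THREE_CHOICES if int(choices) == 3 else FIVE_CHOICES


def write_study(dataset: StudyDataset, path: Union[str, Path],
                tables_path: Union[str, Path, None] = None) -> None:
    """Write the canonical CSV (and the companion tables CSV if given)."""
    cols = [c for c in CANONICAL_COLUMNS + OPTIONAL_COLUMNS if c in dataset.data.columns]
    dataset.data[cols].to_csv(path, index=False)
    if tables_path is not None and dataset.tables is not None:
        dataset.tables.to_csv(tables_path, index=False)


def read_study(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
    tables_path: Union[str, Path, None] = None,
    rounds: int = 10,
) -> StudyDataset:
    """Read and validate a study CSV, optionally renaming foreign columns.

    ``column_map`` maps canonical names to source column names; canonical
    names absent from the map are assumed to already be present.  Derivable
    columns (``public_account_after_round``, ``success``) are recomputed
    from contributions and cross-checked against any provided values.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing_src = [s for s in rename if s not in df.columns]
        if missing_src:
            raise StudyValidationError(
                [f"column map refers to absent source columns: {missing_src}"]
            )
        df = df.rename(columns=rename)

    problems: list[str] = []
    derivable = {"public_account_after_round", "success"}
    required = [c for c in CANONICAL_COLUMNS if c not in derivable]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise StudyValidationError([f"unmapped required columns: {absent}"])

    df = df.copy()
    df["treatment_delegation"] = df["treatment_delegation"].astype(bool)
    for col in ("game", "round", "treatment_choices", "contribution"):
        df[col] = df[col].astype(int)

    # Per (group, game) block checks and recomputation of derived columns.
    recomputed_pa = np.empty(len(df), dtype=int)
    recomputed_success = np.empty(len(df), dtype=bool)
    for (gid, game), block in df.groupby(["group_id", "game"], sort=False):
        choices = block["treatment_choices"].iloc[0]
        if block["treatment_choices"].nunique() > 1 or block["treatment_delegation"].nunique() > 1:
            problems.append(f"group {gid}: treatment labels vary within the group")
        space = _space_for(choices)
        cfg = default_config(int(choices))
        bad = block.loc[~block["contribution"].isin(space)]
        for idx, row in bad.iterrows():
            problems.append(
                f"row {idx} (group {gid}, game {game}): contribution "
                f"{row['contribution']} outside the {choices}-choice space {space}"
            )
        n_players = block["player_id"].nunique()
        if len(block) != n_players * rounds:
            problems.append(
                f"group {gid} game {game}: expected {n_players * rounds} rows "
                f"({n_players} players x {rounds} rounds), found {len(block)}"
            )
            continue
        per_round = block.groupby("round")["contribution"].sum().sort_index()
        pa = per_round.cumsum()
        final = int(pa.iloc[-1])
        success = final >= cfg.threshold
        ordered = block.sort_values("round")
        recomputed_pa[ordered.index] = pa.loc[ordered["round"]].to_numpy()
        recomputed_success[block.index] = success
        if "public_account_after_round" in df.columns:
            given = block["public_account_after_round"].to_numpy()
            expect = pa.loc[block["round"]].to_numpy()
            mism = np.flatnonzero(given != expect)
            if mism.size:
                problems.append(
                    f"group {gid} game {game}: public_account_after_round "
                    f"disagrees with recomputed values at rows "
                    f"{block.index[mism][:5].tolist()}"
                )
        if "success" in df.columns:
            if not (block["success"].astype(bool) == success).all():
                problems.append(
                    f"group {gid} game {game}: provided success flag disagrees "
                    f"with recomputed outcome (final account {final})"
                )

    # Game 2 must be paired with Game 1.
    games = df.groupby("group_id")["game"].agg(lambda s: set(s))
    for gid, gset in games.items():
        if 2 in gset and 1 not in gset:
            problems.append(f"group {gid}: Game 2 present without Game 1")

    if problems:
        raise StudyValidationError(problems)

    df["public_account_after_round"] = recomputed_pa
    df["success"] = recomputed_success
    # successful groups never face the gamble: loss_event is blank there
    df["loss_event"] = df["loss_event"].astype(object).where(
        df["loss_event"].notna(), "")

    tables = pd.read_csv(tables_path) if tables_path is not None else None
    order = [c for c in CANONICAL_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    return StudyDataset(df[order], tables)


def action_vectors(
    dataset: StudyDataset,
    choices: Optional[int] = None,
    game: Optional[int] = None,
    rounds: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pivot the long table into per-(group, player, game) action vectors.

    Returns an index frame (group_id, player_id, game, treatments, and the
    ``profile`` ground-truth column when present) aligned row-by-row with a
    matrix of shape (n_vectors, rounds).
    """
    d = dataset.data
    if choices is not None:
        d = d[d["treatment_choices"] == choices]
    if game is not None:
        d = d[d["game"] == game]
    keys = ["group_id", "player_id", "game"]
    extra = ["treatment_choices", "treatment_delegation"] + [
        c for c in OPTIONAL_COLUMNS if c in d.columns
    ]
    wide = d.pivot_table(index=keys + extra, columns="round",
                         values="contribution", aggfunc="first")
    wide = wide.reindex(columns=range(1, rounds + 1))
    if wide.isna().any().any():
        raise StudyValidationError(["incomplete action vectors in pivot"])
    index = wide.index.to_frame(index=False)
    return index, wide.to_numpy(dtype=float)
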
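"""Synthetic-population generator: profiles, tables, study assembly, revision."""

import numpy as np
import pandas as pd
import pytest

from crdlab import (
    BehaviorProfile,
    CRDConfigError,
    MemberState,
    RevisionParams,
    StudyDesign,
    classify_table,
    constant_policy,
    default_config,
    default_profile,
    generate_study,
    play_game,
    profile_policy,
    revise_behavior,
    sample_strategy_table,
)
from crdlab.game import FIVE_CHOICES, THREE_CHOICES
from crdlab.population import design_from_json, design_to_json


def replay_against_fair(table, cfg):
    """Contributions of one delegate grouped with three fair-share players."""
    from crdlab import delegate_policy

    policies = [delegate_policy(table, cfg)] + [constant_policy(2)] * 3
    return play_game(policies, cfg, seed=0).contributions[:, 0]


class TestProfilePolicy:
    def test_fair_profile_noiseless_plays_two_each_round(self):
        pol = profile_policy(default_profile("fair", 0.0), THREE_CHOICES, seed=0)
        assert [pol(r, 2.0 if r > 1 else None, 0) for r in range(1, 11)] == [2] * 10

    def test_early_profile_noiseless_front_loads(self):
        pol = profile_policy(default_profile("early", 0.0), FIVE_CHOICES, seed=0)
        acts = [pol(r, None if r == 1 else 2.0, 0) for r in range(1, 11)]
        assert np.mean(acts[:5]) > 2 and np.mean(acts[5:]) < 2

    def test_low_profile_is_selfish_but_nonzero_with_five_choices(self):
        profile = BehaviorProfile("low", (1.0,) * 10, noise_sd=0.0)
        pol = profile_policy(profile, FIVE_CHOICES, seed=0)
        assert [pol(r, None if r == 1 else 2.0, 0) for r in range(1, 11)] == [1] * 10

    def test_noise_stream_reproducible(self):
        prof = default_profile("fair", 0.5)
        runs = []
        for _ in range(2):
            pol = profile_policy(prof, FIVE_CHOICES, seed=42)
            runs.append([pol(r, None if r == 1 else 2.0, 0) for r in range(1, 11)])
        assert runs[0] == runs[1]


class TestSampleStrategyTable:
    def test_fair_noiseless_table_replays_fair_share(self, cfg3, cfg5):
        for cfg in (cfg3, cfg5):
            table = sample_strategy_table(
                default_profile("fair", 0.0), cfg.action_space, seed=1)
            assert replay_against_fair(table, cfg).tolist() == [2] * 10

    def test_early_table_switches_to_low_second_strategy(self):
        rng = np.random.default_rng(3)
        mids = []
        for _ in range(20):
            t = sample_strategy_table(
                default_profile("early", 0.5), FIVE_CHOICES, seed=rng,
                p_conditional=1.0)
            assert t.switch_value <= 80
            mids.append((t.strategy1[2], t.strategy2[2]))
        # strategy 2 sits below strategy 1 on the middle of the space
        assert np.mean([s2 for _, s2 in mids]) < np.mean([s1 for s1, _ in mids])

    def test_zero_conditional_probability_gives_fixed_table(self):
        t = sample_strategy_table(default_profile("fair", 0.5), THREE_CHOICES,
                                  seed=5, p_conditional=0.0)
        assert classify_table(t).fully_constant

    def test_conditional_tables_dominate_at_defaults(self):
        rng = np.random.default_rng(11)
        n_conditional = sum(
            not classify_table(
                sample_strategy_table(default_profile("fair", 0.5),
                                      THREE_CHOICES, seed=rng)
            ).strategy1_constant
            for _ in range(200)
        )
        assert n_conditional >= 0.9 * 200 * 0.9  # >= 0.9 up to binomial noise


class TestGenerateStudy:
    def test_counts(self):
        design = StudyDesign(
            n_groups={(3, True): 10, (3, False): 10, (5, True): 10, (5, False): 10},
            seed=0,
        )
        ds = generate_study(design)
        assert ds.n_groups == 40
        assert ds.n_individuals == 160
        vectors = ds.data.groupby(["group_id", "player_id", "game"]).ngroups
        assert vectors == 320
        assert len(ds.data) == 320 * 10

    def test_all_fair_noiseless_groups_hit_threshold_exactly(self):
        mix = {"early": 0.0, "high": 0.0, "fair": 1.0, "low": 0.0}
        design = StudyDesign(
            n_groups={(3, True): 5, (3, False): 5, (5, True): 5, (5, False): 5},
            mixtures={c: mix for c in [(3, True), (3, False), (5, True), (5, False)]},
            noise_sd=0.0,
            revision=RevisionParams(0.0, 0.0, 0.0),
            seed=2,
        )
        ds = generate_study(design)
        finals = ds.data.groupby(["group_id", "game"])["contribution"].sum()
        assert (finals == 80).all()
        assert ds.data["success"].all()

    def test_reproducible_byte_identical(self, small_design, small_study):
        again = generate_study(small_design)
        assert small_study.data.to_csv(index=False) == again.data.to_csv(index=False)
        assert small_study.tables.to_csv(index=False) == again.tables.to_csv(index=False)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(CRDConfigError):
            StudyDesign(mixtures={c: {"fair": 0.5} for c in
                                  [(3, True), (3, False), (5, True), (5, False)]})

    def test_design_json_round_trip(self, small_design):
        assert design_from_json(design_to_json(small_design)) == small_design


def _member(profile, space, seed=0, delegation=True):
    m = MemberState(
        player_id="p0",
        profile=profile,
        space=space,
        delegation=delegation,
        p_conditional=0.9,
        table_seed=np.random.SeedSequence(seed),
    )
    if delegation:
        m.table = sample_strategy_table(
            m.profile, space, seed=np.random.default_rng(m.table_seed),
            p_conditional=m.p_conditional)
    return m


class TestReviseBehavior:
    def test_zero_params_are_identity(self):
        m = _member(default_profile("high", 0.5), THREE_CHOICES, seed=4)
        revised = revise_behavior(m, group_success=False, delegation=True,
                                  params=RevisionParams(0.0, 0.0, 0.0), seed=0)
        assert revised.profile.targets == m.profile.targets
        assert revised.table == m.table

    def test_delegation_failure_raises_contributions(self, cfg3):
        m = _member(default_profile("low", 0.0), THREE_CHOICES, seed=4)
        before = replay_against_fair(m.table, cfg3).sum()
        revised = revise_behavior(m, group_success=False, delegation=True,
                                  params=RevisionParams(delta_up=1.0), seed=0)
        after = replay_against_fair(revised.table, cfg3).sum()
        assert after > before

    def test_giveup_forces_zero_contributions(self, cfg3):
        m = _member(default_profile("fair", 0.5), THREE_CHOICES,
                    seed=4, delegation=False)
        revised = revise_behavior(m, group_success=False, delegation=False,
                                  params=RevisionParams(p_giveup=1.0), seed=0)
        pol = profile_policy(revised.profile, THREE_CHOICES, seed=0)
        acts = [pol(r, None if r == 1 else 2.0, 0) for r in range(1, 11)]
        assert acts == [0] * 10

    def test_no_delegation_success_unchanged(self):
        m = _member(default_profile("fair", 0.5), THREE_CHOICES,
                    seed=4, delegation=False)
        revised = revise_behavior(m, group_success=True, delegation=False,
                                  params=RevisionParams(), seed=0)
        assert revised.profile == m.profile


def test_revision_directions_across_seeds():
    """Averaged over replicate seeds: failed delegation members raise their
    contributions in Game 2; failed no-delegation groups' public accounts
    drop between games."""
    deltas, drops = [], []
    for seed in range(10):
        design = StudyDesign(
            n_groups={(3, True): 15, (3, False): 15, (5, True): 15, (5, False): 15},
            seed=seed,
        )
        ds = generate_study(design)
        totals = (
            ds.data.groupby(["group_id", "player_id", "game"])
            .agg(total=("contribution", "sum"),
                 deleg=("treatment_delegation", "first"),
                 success=("success", "first"))
            .reset_index()
        )
        wide = totals.pivot_table(index=["group_id", "player_id"], columns="game",
                                  values="total")
        meta = totals[totals["game"] == 1].set_index(["group_id", "player_id"])
        failed_del = meta[(meta["deleg"]) & (~meta["success"].astype(bool))].index
        if len(failed_del):
            deltas.append((wide.loc[failed_del, 2] - wide.loc[failed_del, 1]).mean())
        group_pa = ds.data.groupby(["group_id", "game"])["contribution"].sum().unstack()
        g1 = totals[(totals["game"] == 1) & (~totals["deleg"])]
        failed_nd = g1[~g1["success"].astype(bool)]["group_id"].unique()
        if len(failed_nd):
            drops.append((group_pa.loc[failed_nd, 2] - group_pa.loc[failed_nd, 1]).mean())
    assert np.mean(deltas) > 0
    assert np.mean(drops) < 0
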
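# crdlab

Simulation and analysis of **collective-risk dilemmas (CRD) with programmable
artificial delegates**.

A CRD is a threshold public goods game: a group of `N = 4` players, each
endowed with `E = 40` ECoins, contributes over `T = 10` rounds to a shared
public account. If the account reaches the threshold `τ = 80`, every player
keeps `E − Σₜ aᵢₜ` (their private account); otherwise the whole group loses
everything with probability `r = 0.5`, so a player's payoff is

```
πᵢ = E − Σₜ aᵢₜ          if Σᵢₜ aᵢₜ ≥ τ, or with prob. 1 − r on failure
πᵢ = 0                    with prob. r on failure
```

Per-round actions come from a coarse (`{0, 2, 4}`) or fine (`{0, 1, 2, 3, 4}`)
action space. In *delegation* treatments a participant does not act in rounds;
they program an agent with a starting action, two reaction tables mapping the
others' rounded previous-round average onto a next action, and a public-account
*switch* level at which the agent permanently moves from the first table to the
second. The package provides:

- `crdlab.game` — the game engine (accounting, group-level risk resolution);
- `crdlab.agents` — the delegate interpreter and strategy-table classification;
- `crdlab.population` — a synthetic-population generator: four behavioral
  profiles (early / high / fair / low contributors), treatment-specific
  mixtures, sampled strategy tables, and outcome-dependent revision between two
  consecutive games (a "surprise restart");
- `crdlab.metrics` — public-account, success, within-group private-account
  variance, contribution frequency, between-game deltas;
- `crdlab.clustering` — K-means on 10-round action vectors, elbow selection of
  k, and rule-based naming of clusters as behavioral profiles;
- `crdlab.stats` — one-sided Welch t, Fisher's exact test, and the two-way
  factorial ANOVA with interaction;
- `crdlab.dataio` / `crdlab.cli` — a canonical long CSV format, a column-map
  adapter for externally deposited data, and the `crdlab simulate / analyze /
  reproduce` commands.

It is intended for researchers in behavioral game theory who want a tested,
reproducible pipeline for CRD delegation experiments — to regenerate the
analysis on synthetic data, to stress-test the analysis choices (rounding tie
rules, ANOVA sum-of-squares types, pre- vs post-risk variance), or to ingest
their own deposited CSVs.

## Worked example

```python
import collections
import crdlab as c

dataset = c.generate_study(c.StudyDesign(seed=1))

gm = c.group_metrics_frame(dataset)
g1 = gm[(gm.game == 1) & (gm.treatment_choices == 3)]
del_pa = g1[g1.treatment_delegation]["final_public_account"]
nod_pa = g1[~g1.treatment_delegation]["final_public_account"]
print("Game-1 mean public account (3 choices):",
      f"{del_pa.mean():.2f} delegation vs {nod_pa.mean():.2f} no-delegation")
res = c.welch_t(del_pa, nod_pa, alternative="greater")
print(f"one-sided Welch t = {res.statistic:.2f}, p = {res.p_value:.1e}")

idx, X = c.action_vectors(dataset, choices=5)
print("elbow-selected k (5 choices, games pooled):",
      c.select_k_elbow(X, range(1, 9), seed=0).k)
labels, _, _ = c.label_behaviors(X, k=4, seed=0)
print("behavior labels:", dict(collections.Counter(labels.tolist())))
```

prints

```
Game-1 mean public account (3 choices): 103.41 delegation vs 74.55 no-delegation
one-sided Welch t = 4.62, p = 2.5e-05
elbow-selected k (5 choices, games pooled): 4
behavior labels: {'fair': 179, 'low': 109, 'high': 148, 'early': 92}
```

The default design is a 2×2 factorial (number of choices × delegation) of 115
groups / 460 individuals, each group playing two consecutive 10-round games.
Delegation groups overshoot the threshold in Game 1 and contribute
significantly more than no-delegation groups under the coarse action space
(positive Welch t); pooled Game 1 + Game 2 action vectors cluster into the four
behavioral profiles, with the fair-share contributors (2 ECoins every round)
the most common. See `docs/methods.md` for what the generator does and does
not emulate.

The same pipeline is available from the shell:

```bash
crdlab simulate --seed 1 --out study.csv --tables-out tables.csv
crdlab analyze --study study.csv --tables tables.csv --out analysis/
crdlab reproduce --data study.csv --tables tables.csv --out headlines.json
```

`reproduce` accepts a `--column-map map.json` to adapt externally deposited
CSV schemas to the canonical column names; derivable columns (public account,
success) are always recomputed and cross-checked, never trusted.

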
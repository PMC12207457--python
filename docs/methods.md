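# Methods

## The game and its accounting

The collective-risk dilemma implemented here is a threshold public goods
game with delayed, probabilistic payoffs. Defaults: groups of 4, 10 rounds,
endowment 40 ECoins, collective threshold 80 ECoins, risk 0.5, and one of
two action spaces — coarse `(0, 2, 4)` or fine `(0, 1, 2, 3, 4)`. The
threshold comparison is inclusive (a final public account of exactly 80
counts as success): the target is defined as an amount to *collectively
contribute*, and landing on it leaves nothing unmet. On failure a single
group-level Bernoulli(risk) loss event is drawn and shared by all members —
the gamble is over the group's fate, not independent per player. Moves
within a round are simultaneous: every policy sees the public account as of
the end of the previous round. All currency quantities are integers; the
configuration invariant `max(action) × rounds ≤ endowment` guarantees no
player can overdraw.

A *round policy* is the only strategy interface the engine knows:
`policy(round, others_prev_avg, public_account)`, where the second argument
is the arithmetic mean of the **other** group members' previous-round
contributions (a real number), and is a `None` sentinel in round 1 —
consulting history that does not exist is a bug, not a default.

## Delegate agents

A delegate program is (starting action, Strategy 1, switch value in
[0, 120], Strategy 2). Each strategy is a total map from the others'
previous-round average — rounded to the closest element of the action
space — onto a next action. Rounding ties break toward the larger element;
this only matters in the coarse space at averages 1.0 and 3.0, and the
interpreter accepts `tie="down"` so the sensitivity of any downstream result
to the tie rule can be checked. The switch is evaluated at round boundaries
against the public account accumulated through the previous round, with ≥
semantics, and is irreversible; since the public account never decreases,
"has ever reached" equals "currently at or above", which keeps the policy
stateless and trivially replayable.

A program is classified `strategy1_constant` when all Strategy 1 entries
are equal, and `fully_constant` when Strategy 2 entries and the starting
action equal that same value too — only then is the realized behavior
literally fixed regardless of the group.

## Synthetic populations

The generator produces study datasets with the structure the analysis layer
assumes. Four latent behavioral profiles are defined by per-round target
levels (ECoins):

| profile | targets | rationale |
|---|---|---|
| fair  | 2 every round | the per-round fair share: 4 × 2 × 10 = 80 exactly |
| high  | 3.5 every round | snaps to 4 in both spaces |
| low   | 0.8 every round | snaps to 0 (coarse) / 1 (fine): selfish without necessarily contributing zero |
| early | 4 in rounds 1–5, 0 in rounds 6–10 | front-loaded fair total of 20 |

No-delegation members play `round_to_space(target + N(0, σ))`, clipped to
the space, with σ = 0.5 by default. Delegation members are assigned sampled
strategy tables: with probability 0.9 the table is *conditional* — entries
`snap(level + 0.4·(a − 2) + N(0, σ))` across the others'-average axis `a`,
redrawing the jitter if snapping collapses the table to a constant — and
with probability 0.1 it is deliberately constant (same action everywhere,
including the start). The reciprocity slope 0.4 is kept below the coarse
space's snapping breakpoint of 0.5, so a conditional agent facing middling
opponent averages stays within its own profile's behavioral class; this
matches the observation that conditionally programmed agents nonetheless
realize near-fixed behavior during play. Early profiles implement their
drop through the switch: Strategy 1 encodes the early level, Strategy 2 the
late level, and the switch value is drawn from N(50, 10) capped at 80 —
against fair-share opponents the public account passes 50 right after round
5. Other profiles receive Strategy 2 identical to Strategy 1 with an inert
switch of 120.

Per-cell profile mixtures are anchored on the observed fair-contributor
shares (3 choices: 46% delegation / 57% no-delegation; 5 choices: 47% /
40%), with the remainder split so delegation cells carry more high and low
contributors and no-delegation cells more early contributors, and with
fewer low contributors in the fine-space no-delegation cell. Default group
counts per cell are 27 / 22 / 44 / 22 (delegation-3, no-delegation-3,
delegation-5, no-delegation-5) — 115 groups, 460 individuals, 108 + 176
delegation individuals.

Between the two games each member is revised given the Game 1 outcome:

- delegation ∧ failure: latent targets shift up by `delta_up` (default 1.0);
- delegation ∧ success with overshoot: targets shift down by `delta_down`
  (default 0.5);
- no-delegation ∧ failure: with probability `p_giveup` (default 0.5) the
  member gives up — targets 0 with the noise removed, so a resigned member
  contributes exactly nothing;
- otherwise behavior is unchanged up to noise.

Revision acts on the latent targets, and delegation tables are rebuilt from
the member's *own* table seed, so all-zero revision parameters reproduce the
Game 1 program exactly and Game 2 play remains policy-generated rather than
copied. No attempt is made to fit revision magnitudes to data: they are free
parameters whose defaults are chosen to reproduce the *signs* of the
between-game effects (failed delegation members contribute more in Game 2;
failed no-delegation groups contribute less).

All randomness flows from one master seed through `numpy.random.SeedSequence`
spawning (cell → group → {profiles, tables, per-game noise, risk draws,
revision}), making a `StudyDesign` byte-identically reproducible.

### What the generator does and does not emulate

It reproduces: integer round contributions restricted to the treatment's
space; the four behavioral profiles and their treatment mixtures; mostly
conditional delegate programs (the realized strategy1-constant rate lands
near the observed 10–14%); delegation groups being *less precise* — table
jitter persists across all 10 rounds, whereas no-delegation per-round noise
averages out, so delegation cells show higher within-group private-account
variance and more threshold overshoot; and outcome-dependent revision.

It does **not** model within-game adaptation: profile policies are
open-loop (target plus noise), with no goal tracking against the public
account. Real no-delegation participants steer toward the threshold, which
is why their observed success rates (up to 91%) and precision exceed what
these synthetic no-delegation cells produce. Passing tests on synthetic
data therefore validate the *pipeline* — accounting, interpreter,
clustering, tests — and the qualitative treatment contrasts, not the
quantitative success levels of human play.

## Metrics

The inequality measure is the within-group variance (sample, n−1
denominator) of the members' final private accounts, computed **pre-risk**
(endowment minus own total contribution): the loss gamble is group-wide, so
post-risk payoffs would either multiply the whole vector by zero or leave
it unchanged, adding nothing about contribution asymmetry; a post-risk
option exists for sensitivity. Contribution frequency is the fraction of a
player's 10 rounds with a strictly positive contribution. The between-game
delta is Game 2 total minus Game 1 total contribution per individual.

## Clustering

K-means (Lloyd, Euclidean, best of 10 random initializations) runs on raw
10-round action vectors — all coordinates share units, and standardizing
would distort the fair-share anchor at 2 — with Game 1 and Game 2 vectors
pooled (individuals may change behavior between games but follow the same
repertoire) and, by default, the two choice conditions clustered
separately. The number of clusters is chosen by the elbow rule, formalized
as the **knee of the log-inertia curve**: the k whose log within-cluster sum
of squares lies farthest below the chord joining the curve's endpoints.
The log scale makes the criterion invariant to the overall inertia scale;
a raw-difference elbow is dominated by the single most distant cluster
(the early contributors) and can hide the elbow between clusters of
moderate separation. Zero inertia at the smallest k (all vectors identical)
returns that smallest k.

Centroids are named by literal reading of the profile definitions: *early*
if mean(rounds 1–5) > 2, mean(rounds 6–10) < 2 and the drop exceeds δ = 1.0;
otherwise *high*/*low* if the overall mean is more than ε = 0.5 above/below
2, else *fair*. δ and ε are free parameters of the naming rule only.

## Statistical tests

Group-level quantities are strongly heteroskedastic across treatments, so
two-sample comparisons use Welch's unequal-variance t with Satterthwaite
degrees of freedom, one-sided where the hypothesis is directional. 2×2
contingency comparisons use Fisher's exact test, two-sided by default.
The factorial analysis is a two-way ANOVA with interaction; cells are
unbalanced, and Type II sums of squares are the default (main effects
adjusted for each other, the interaction last), with Type III behind a
flag for sensitivity. No multiple-testing correction is applied anywhere.

## Numerical and robustness choices

- Rounding ties upward; flippable per call (`tie="down"`).
- Welch refuses two constant samples (undefined statistic); Fisher refuses
  zero margins; the ANOVA refuses empty cells.
- `read_study` recomputes every derivable column (public account, success)
  and fails loudly, with row references, on any disagreement or on
  contributions outside the treatment's space.
- Problem sizes in the test suite: the exhaustive delegate-semantics sweep
  covers all 3⁷ = 2,187 coarse-space programs; Monte-Carlo checks use
  10,000 draws; the qualitative treatment-sign check averages 20 replicate
  seeds of a 30-groups-per-cell design.

## Known limitations

- Open-loop profile policies (above): no within-game goal seeking, hence
  understated no-delegation precision and success.
- The revision model is sign-calibrated only; magnitudes are conventions.
- Cluster naming assumes the fair-share anchor of 2 ECoins per round and
  10-round games.
- Only 2×2 designs with the two study action spaces are generated, though
  the engine itself accepts any valid configuration.
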
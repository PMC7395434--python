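# Methods

## Game mechanics

The collective-risk dilemma is implemented exactly as specified by its
rules: `n` players (odd), endowment 40, menu {0, 2, 4}, 10 rounds, target
`2·10·n`, success iff the pooled total reaches the target.  The surplus
series is `S_r = C_r − 2·n·r` with `C_r` the cumulative pool after round
`r`; its final value equals total minus target, so `S_10 ≥ 0` is
equivalent to success.  Settlement converts savings at ¥2 per unit on top
of a ¥15 show-up fee.  On failure the loss lottery is drawn **once per
group** by default — all members share the outcome, matching the
shared-risk framing of the dilemma and the wording of the end-game risk
question ("your group could lose everything") — with
`GameConfig(per_player_lottery=True)` switching to one independent draw per
player; the underlying experimental protocol is ambiguous between the two
readings.  Decision timing within a round is not modeled: investments are
collected atomically per round.

Under default parameters the budget constraint never binds (the endowment
covers the maximum choice in every round), so `feasible_choices` is a
safety guard for non-default configurations only.

## Behavioral types

Three types with expected per-round investment linear in the round,
`m(r) = a + b·r`, calibrated so that the mean over rounds 1–10
(`a + 5.5·b`) and the slope equal the published population moments:

| type        | mean | slope  | derived intercept |
|-------------|------|--------|-------------------|
| cooperator  | 1.96 | 0.080  | 1.520             |
| free rider  | 0.77 | −0.022 | 0.891             |
| altruist    | 2.96 | 0.152  | 2.124             |

Realized investments are drawn as `2·Binomial(2, m(r)/4)` — the unique
binomial law on the {0, 2, 4} support with mean exactly `m(r)`.  Because
the link preserves the conditional mean and clipping of `m(r)` to [0, 4]
is inert for these parameters over rounds 1–10, both the marginal mean and
the OLS slope of investment on round are recovered without bias from
simulated play; this is what `scripts/acceptance.py` measures.  The
types' only published moments are these margins; any generative model
matching them is admissible, and this is the simplest.

Questionnaire behavior is an independent Bernoulli per scheduled question.
The yes-probability table is a generator choice, constrained qualitatively
(prosocial types: yes-Q1, no-Q2/Q3, yes-Q4 majorities; free riders roughly
mirrored) and quantitatively only through the pooled Q5 yes-rate ≈ 0.606.
Answers and investments share the type but are otherwise independent: the
available statistics identify an association between communication and
investing, not a reaction function, so the default agents do not condition
investments on the majority verdicts (a `PolicyContext.majority` hook
carries the verdicts for custom reactive policies).

The random-play null is uniform over the menu.  Its per-draw mean equals
the fair share, so the null's expected surplus is zero in every round —
the natural centering for the significance envelopes.

## Synthetic experiment

The generator reproduces the study design: control groups (3, 7, 11) in
counts (11, 8, 8) — 177 players — and treatment groups in counts
(10, 8, 8) — 174 players.  Types are i.i.d. within arm with prosocial
(cooperator + altruist) prevalence 0.575 in treatment and 0.425 in
control, split 2:1 cooperator:altruist (the split within the prosocial
mass is not separately published; cooperators are the commonest type).
The prevalence figures are read as within-arm proportions; the alternative
reading (share of all prosocial players found in each arm) nearly
coincides because the arms are nearly equal-sized.  Both the prevalences
and the split are config-exposed.

What the generator deliberately does **not** emulate: communication-reactive
investing (treatment groups differ from control only through the type
mixture), dropouts/timeouts, session/demographic structure, and any
group-composition feedback.  Consequently synthetic between-arm effects are
*weaker* than the real experiment's (synthetic success frequencies pool to
roughly 16/5/2% in control and 26/17/11% in treatment for sizes 3/7/11,
versus ~50/30/10% and ~90/60/20% observed with humans).  Passing recovery
tests therefore validates the machinery and the calibration, not the claim
that type mixture alone explains the experimental success rates — it
demonstrably does not, which is itself informative: on synthetic data a
single 53-group experiment usually lacks the power to reject even mutual
independence of the success table, whereas the real data selected the
conditional-independence model with arm×success and size×success terms.

## Null model and envelopes

The distribution of a random-play group's total is computed exactly by
iterated convolution of the per-draw pmf over `n × 10` draws (`float64`;
mass sums checked to 1e−12).  Success probability follows as the upper
tail at the target; the uniform draw's symmetry about the fair share gives
the cross-check `P(success) = (1 + P(total = target))/2`, satisfied to
1e−12.  Envelopes simulate 100,000 random groups by default (seeded,
reproducible), condition on *final* failure only — not path-wise — and
take per-round empirical quantiles with linear interpolation; at level
0.95 the curve is the 5th percentile, so 95% of unsuccessful random groups
stay above it.

## Log-linear family

The nine hierarchical models for the arm × success × size table range from
mutual independence through the three joint-independence and three
conditional-independence models and homogeneous association to saturated.
Fitting is by iterative proportional fitting to the model's sufficient
margins, converged when every fitted margin matches its observed margin to
1e−10 (direct models converge in one sweep; homogeneous association
iterates).  `G² = 2 Σ obs·ln(obs/fit)` over cells with positive observed
counts; degrees of freedom come from the hierarchical parameter count
(sum of `Π(levels−1)` over the generating class closure).  Selection takes
the most parsimonious model (fewest parameters, ties by smaller G²) whose
G² p-value against χ² exceeds 0.05; the saturated model guarantees a
candidate.  AIC (`G² − 2·df`) is reported alongside.

## Clustering into types

Players are represented by their raw 10-round investment vectors.  A
Ward-linkage Euclidean tree is always built and cut at k = 3; by default
the cut then initializes a latent-class trajectory EM — a three-component
mixture in which each class has a linear-in-round mean investment with the
same `2·Binomial(2, m/4)` observation law used by the generator — and each
player receives their posterior-mode class.  The plain tree cut
(`method="ward"`) recovers planted types at ~78% on default synthetic
data because adjacent types overlap substantially in Euclidean distance;
the EM refinement reaches ~89%, essentially the Bayes-optimal rate for
this mixture, and is deterministic given the data.  If the EM ever
collapses a class, the tree cut is kept.  Clusters are labelled by
ascending mean investment (free rider < cooperator < altruist), making
labels invariant to player order and cluster-id permutations.

## Trend, ANOVA, choice-model and Q5 analyses

Per-type means carry normal-approximation CIs over player-rounds; slopes
come from per-type OLS of investment on round.  The ANCOVA
(investment ~ type × round) and the two-way group-level ANOVA
(mean per-capita investment ~ arm × size) use Type II sums of squares,
appropriate for the unbalanced design; degenerate inputs (empty cells,
zero residual variance, single-level factors) raise or reduce gracefully.
The multinomial logit treats the fair share (2 units) as reference
outcome, with round centered at 5.5, a treatment indicator and size as a
categorical factor (all optional); fitting is Newton maximum likelihood
with a convergence contract (max |score| < 1e−6) and an explicit
separation error advising regularization.  The Q5 test is the exact
binomial upper tail at p = 1/2, the rate a fully informed group should
show given the known 50% loss probability.

## Multiple correspondence analysis

Indicator-matrix MCA (not Burt): rows are player-round questionnaires by
default (player-level modal aggregation available, ties to "no"), columns
the eight yes/no categories of Q1–Q4; Q5 is excluded as a late-appearing
question of a different nature.  The correspondence matrix is centered by
the outer product of its margins, standardized by the square-root masses,
and decomposed by SVD; squared singular values are the principal inertias.
For complete binary data the total inertia equals `J/Q − 1 = 1`, and
balanced independent questions give four equal non-trivial inertias of
1/4 — both used as exact self-checks (1e−8).  Categories nobody picked
carry zero mass and are dropped before decomposition.  No Benzécri
correction is applied by default.

## Problem sizes and determinism

Default test and script scales — 5,000–6,000 players per type for moment
recovery, 10⁶ replicates for the null-model cross-check (drawn as
multinomial counts), 200 replicate experiments for selection frequencies
and success-frequency ordering, 10⁵ settlements for payout bounds — were
chosen so every Monte-Carlo standard error is a small fraction of the
effect being measured while the whole suite stays interactive.  All
randomness flows through `numpy.random.default_rng` seeds; the experiment
generator is bit-reproducible per seed, and one master seed fans out to
stage seeds via `SeedSequence.spawn`.

## Known limitations

- Agents are static policies; no learning, no response to majorities.
- The synthetic arm effect on success is far weaker than the human data's
  (see above); analyses whose power depends on that effect (log-linear
  selection, the arm F-test) behave differently at synthetic scale.
- The exact per-outcome type abundances and the real experiment's MCA
  coordinates are not calibration targets; only the published margins are.
- Real-data ingestion is supported through the CSV schemas and validators,
  but no human dataset ships with the package.
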
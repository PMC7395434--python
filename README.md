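# crdgame

Simulator and analysis pipeline for the **collective-risk social dilemma**:
a threshold public-goods game in which a group must jointly reach an
investment target to avert a probabilistic collective loss, framed as
climate-change mitigation.  The package is aimed at researchers in
experimental/behavioral game theory who want to simulate gameplay under
explicit behavioral assumptions, characterize what random play would look
like, and run the full group- and player-level statistical analysis chain
on either synthetic or real gameplay data.

## The game

A group of `n ∈ {3, 7, 11}` players (always odd, so majority votes cannot
tie) plays `T = 10` rounds.  Each player starts with an endowment of 40
capital units and invests `x ∈ {0, 2, 4}` units per round into a common
pool.  The group succeeds iff the pooled total reaches the target

```
target = 2 · T · n        (60 / 140 / 220 units for n = 3 / 7 / 11)
```

— the total reached when everyone plays the *fair share* of 2 units every
round.  On success, each player converts savings to money (¥2 per unit plus
a ¥15 show-up fee, so payouts span ¥15–¥95); on failure, a lottery wipes
all savings with probability 1/2.  Treatment groups additionally answer up
to five scheduled yes/no questions between rounds (Q1/Q2 from round 1,
Q3/Q4 from round 2, Q5 from round 6) and see only the group majority's
answer per question.

## What the package provides

- **`crdgame.engine`** — exact mechanics: configuration, surplus/deficit
  accounting `S_r = Σ investments − 2·n·r`, success flag, payout settlement.
- **`crdgame.agents`** — three calibrated behavioral types whose expected
  investment is linear in the round, `m(r) = a + b·r`, realized on the
  {0,2,4} menu as `2·Binomial(2, m/4)` (so the mean is exactly `m(r)`):
  cooperators (population mean 1.96, slope 0.080), free riders (0.77,
  −0.022) and altruists (2.96, 0.152); plus a uniform random-play null
  agent and Bernoulli questionnaire policies.
- **`crdgame.synthetic`** — full synthetic experiments with the study
  design (11/8/8 control and 10/8/8 treatment groups of sizes 3/7/11,
  prosocial prevalence 57.5% vs 42.5%), deterministic per seed.
- **`crdgame.envelope`** — the exact distribution of the random-play group
  total by convolution, its success probability, and Monte-Carlo
  *significance envelopes*: the per-round 5th-percentile surplus of
  eventually-failing random groups, used to flag groups that "gave up".
- **`crdgame.loglinear`** — the arm × success × size contingency table and
  all nine hierarchical log-linear models, fitted by iterative proportional
  fitting; model selection by parsimony among models with deviance
  p > 0.05.
- **`crdgame.behavior`** — behavioral-type clustering (Ward tree +
  latent-class trajectory EM), per-type trend estimates and ANCOVA, two-way
  investment ANOVA, a multinomial choice model with the fair share as
  reference outcome, and the exact binomial test for the Q5 risk question.
- **`crdgame.mca`** — multiple correspondence analysis of the Q1–Q4
  indicator matrix from first principles (SVD of standardized residuals),
  with category maps and type centroids.
- **`crdgame.io` / `crdgame.cli`** — CSV/JSON schemas with validation,
  seed fan-out, run manifests, and a thin `crdgame` command
  (`simulate | envelope | analyze | cluster | mca | report`).

## Worked example

```
$ python examples/03_synthetic_experiment.py
successful groups / total (arm x size):
size         3    7    11
arm
control    2/11  0/8  1/8
treatment  0/10  2/8  2/8

selected log-linear model: [arm][success][size]

recovered type counts: {'free_rider': 190, 'cooperator': 109, 'altruist': 52}
agreement with planted types: 0.917

per-type mean investment and round slope:
            n_players   mean  slope
type
altruist           52  3.008  0.148
cooperator        109  1.950  0.108
free_rider        190  0.788 -0.043
```

The clustering recovers 91.7% of the planted types on this seed, and the
per-type means straddle the calibration (1.96 / 0.77 / 2.96).  Note that a
single 53-group experiment carries little information about the success
table: here the selected log-linear model is mutual independence, because
the synthetic arm effect at this scale is small (see `docs/methods.md`).

```
$ python examples/04_questionnaire_mca.py
total inertia: 1.0000 (identity: 8 categories / 4 questions - 1 = 1)
principal inertias: [0.3869 0.221  0.2053 0.1868]
...
Q5: 533/870 yes (61.3%); exact binomial tail vs chance: 1.58e-11
```

Prosocial types (cooperators, altruists) sit on the Q1-yes/Q4-yes side of
the first MCA dimension — optimistic about the target and demanding more
action — while free riders sit opposite; and the pooled Q5 yes-rate
exceeds the 50% that a known loss probability would warrant.

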
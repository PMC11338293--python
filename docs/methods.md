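# Methods

## The model

`matesearch` treats human mate search as a two-sided multi-armed bandit
problem. Every agent in a mating market faces the opposite-sex members of that
market as bandit arms: pursuing ("observing") mate *m* on a trial returns a
noisy draw of that mate's true mate value, and pursuit opportunities are
finite. Mate value is a similarity score: for focal agent *i* with
16-dimensional ideal-preference vector **p**ᵢ and mate *j* with trait vector
**t**ⱼ (both on the questionnaire's 0–10 scale),

    mv(i, j) = 10 · (1 − ‖pᵢ − tⱼ‖ / 40),

where 40 = √16·10 is the diameter of the bounded rating space, so a perfect
preference-trait match scores 10 and the worst possible match scores 0. The
linear rescale is one of many strictly decreasing maps of distance; since all
choice rules below are rank-based in mate value, any such map induces the same
behavior, and the linear form keeps the ceiling at the scale maximum.

Observation noise is Gaussian and calibrated by a single interpretable
parameter, the noise fraction *p*: with *V* the pooled variance of all true
mate values in the market, the noise SD is σ = √(V·p/(1−p)), which makes the
share of perception variance due to noise exactly *p*. Observations are not
clipped to [0, 10]; clipping would bias learning near the scale edges.

### Full information: the resource allocation model (RAM)

The reference model of mate choice under perfect perception. Every agent has
a budget of 10 investment units (dynamics are scale-invariant in the budget).
Initial allocation is proportional to mate value. On each of 50 subsequent
steps every agent reweights each mate by the product
(resources sent) × (resources received back) and re-normalizes to the budget;
the product rewards mutual investment and annihilates unreciprocated pursuit,
and the market typically freezes onto mutually investing pairs well within 50
steps. (Sum and geometric-mean weight rules are available as configuration
alternatives; product is the default.) Agents then pair with their
most-invested mate iff that mate is most invested in them (ties broken
randomly); everyone else is single. Fully stalled agents (all-zero weights)
keep their previous allocation so the map stays total.

### Partial information: seven search models

All learners start optimistic — every estimate (or Thompson prior mean) at the
scale maximum 10 — so every arm is worth a first look.

- **nonlearning** — one observation per mate, then RAM on the perceived
  matrix. At zero noise this reproduces the full-information pairing exactly.
- **eg** — ε-greedy: pursue the highest-estimate mate with probability 1−ε,
  a uniformly random mate otherwise; estimates are incremental means (the
  first observation replaces the optimistic initialization).
- **ucb** — UCB1: pursue argmax of estimate + c·√(ln t / N(m)), where t is
  the trial index and N(m) the pursuit count; unvisited mates score +∞.
- **ts** — Thompson sampling: per-mate Gaussian beliefs updated by the
  conjugate normal-normal rule with known observation SD (agents use the true
  calibrated noise SD; an "assumed SD" override exists); each trial the agent
  draws one belief per mate and pursues the argmax.
- **rweg / rwucb / rwts** — the same three rules with the score multiplied by
  the reciprocity weight obs(m→i)/obs(i→m): the ratio of pursuits received
  from mate m to pursuits sent to m. Counts carry a +1 virtual mutual pursuit
  so the ratio starts at the neutral value 1 and is always defined; a mate who
  never reciprocates drives the weight — and pursuit — toward zero.

Tuned parameter defaults: ε = 0.2, c = 1.5, prior SD = 0.2 for the plain
learners; ε = 0.15, c = 0.2, prior SD = 0.25 for the reciprocity-weighted
ones. The couple-generation and human-data experiments use prior SD = 0.10
for the reciprocity-weighted Thompson sampler.

All agents of both sexes search synchronously: choices on a trial use the
counts as they stood after the previous trial, then all updates apply
jointly. This removes within-trial order effects; it also lets the search
loop be fully vectorized across agents with a single seeded generator per
run, so results are reproducible and independent of agent iteration order by
construction. Trials run in blocks (default 1,000); at each block end a
provisional pairing snapshot pairs each agent with its cumulatively
most-pursued mate iff that pursuit is mutually plural. Pairing snapshots
never remove agents from the market.

## Evaluation: couple simulation

A candidate model is scored by how much of a reference pairing it reproduces:

- *end-state accuracy* — percent of agents in the same end state (same
  partner, or single in both outcomes); used when candidate and reference
  cover the same agents, e.g. against full-information RAM choices.
- *couple recovery* — percent of reference couples re-formed intact; used
  against real dyads or model-generated couple populations.

Confidence intervals: normal approximation over units for single runs,
percentile bootstrap over couples (default 10,000 resamples) for the noise
sweep, and a normal-approximation interval across replicate samples for the
proof-of-concept cells (whose printed intervals are correspondingly narrow).

Three experiments are packaged:

1. **Model selection** (`run_model_selection`): all seven models against the
   full-information RAM reference on one market, accuracy per block, averaged
   over 10 independent repetitions by default.
2. **Proof of concept** (`run_proof_of_concept`): one population is generated
   and cloned; couples form in each clone under a different true model
   (non-learning vs rwts, 30 observation opportunities per potential mate,
   p = 0.5). Candidate models re-run on repeated couple samples (each sample
   re-housed in a fresh market) and are scored by couple recovery. A usable
   evaluation method should show the true model recovering its own couples
   best; recovery is well below 100% even for the matched model because
   sampled markets offer different competition than the original ones.
3. **Noise sweep** (`run_noise_sweep`): both candidate models against a fixed
   reference across noise fractions (default grid 0.001, 0.25, 0.5, 0.75,
   30 observations per potential mate).

`grid_search` runs the model comparison at reduced scale over a parameter
grid and reports mean final-block accuracy per point — the same procedure
used to pick the defaults above.

## Synthetic populations

Agent populations are generated per sex in three steps: resample each of the
32 dimensions (16 preferences + 16 traits) independently with replacement
from per-dimension value pools — or draw Gaussians when no pools are supplied
— then standardize columns and multiply by the Cholesky factor of the target
32×32 correlation matrix, then rescale every column to the target mean and
SD. The final rescaling is empirical, so sample moments match the targets
exactly while correlations match up to Monte-Carlo error (≤0.1 at n ≥ 2000).
Values are not clipped to [0, 10]. Near-PSD correlation matrices (smallest
eigenvalue ≥ −1e−8) are repaired with diagonal jitter; anything worse is
rejected with the offending eigenvalue named.

The default synthetic statistics place means in [4, 8] and SDs in [1, 2] on
the 0–10 scale and draw the correlation matrix from a random two-factor
structure plus a shared positive trait loading (a mild general-desirability
factor), giving moderate positive trait intercorrelations like those seen in
mate-preference questionnaires. What the generator does not emulate: discrete
Likert responses (values are continuous), missing data, measurement error in
the reported preferences themselves, and any dyadic dependence between real
partners' traits. Passing tests on synthetic markets therefore demonstrate
the *mechanics* of search and evaluation, not model fit to human data.

## Human data

The questionnaire reader expects one CSV row per participant, two per
romantic dyad: ideal-partner and self ratings on 31 items (15 two-item
dimensions averaged into composites, plus age). Ideal age is rated on the
0–10 binned scale directly; self age in years is mapped onto that scale by a
configurable linear transform anchored at 20 years → 0 and 75 years → 10
(6-year bins between), clamped outside. This anchoring is a documented
default, not a claim about how age must be commensurated. Incomplete dyads
are dropped listwise with a logged count (no imputation); partner ratings are
read but unused unless explicitly selected as the trait source. All agents
form one market, and dyad membership defines the reference pairing.

## Problem sizes and numerical choices

The packaged experiment defaults are full scale
(500-agent markets, 10,000 trials in blocks of 1,000; 50 markets × 500 agents
with 100 samples of 500 for the proof of concept; 30 observations per
potential mate). The test suite and the acceptance script run the same
pipelines at desk scale — 100–200-agent markets, 3,000 trials, 5 markets × 100
agents with 20 samples of 100, and 3 replicates per noise-sweep cell (replicate
averaging estimates expected recovery, since single runs on ~50 reference
couples are dominated by Monte-Carlo noise). At these scales reciprocity-
weighted models retain their qualitative advantage, but two full-scale
phenomena do not transfer: the reciprocity-weighted Thompson sampler
overtakes reciprocity-weighted ε-greedy only after roughly 6,000 trials
(its early uniform-exploration phase scales with absolute trial count, not
market size), and the plain-UCB model's intermediate performance on
250-mate markets does not appear on 50-mate markets.

Other numerical choices: argmax ties are always broken uniformly at random;
UCB's unvisited-arm score is +∞ (standard first-visit forcing); the Thompson
update floors the observation SD at 1e−9 so the zero-noise limit stays
defined; incremental-mean learners replace (rather than blend with) the
optimistic initial estimate at the first observation, so the optimism only
orders first visits; reciprocity counts start at the +1 virtual mutual
pursuit. Budgets must divide evenly into blocks. All randomness flows from a
single integer seed per run through numpy Generators; derived child seeds
stay below 2³¹.

## Known limitations

- Markets are strictly two-sex and opposite-sex; no non-binary structure.
- Mate values are stationary; preference/trait change over time is out of
  scope, as are trait-by-trait learning rates and pool expansion during
  search.
- Couple recovery against a reference generated by a stochastic model is
  capped by that model's run-to-run self-consistency (two independent
  reciprocity-weighted Thompson runs at p = 0.5 agree on roughly a third of
  couples), so recovery rates near that cap indicate matched dynamics, not
  failure.
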
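# Methods

`attune` is a proof-of-concept pipeline for *implicit value learning*: an
agent observes the behavior of members of a cultural group in a simple
cooperative game, infers a reward function by inverse reinforcement
learning (IRL), and reuses the inferred reward — directly on spatial
variants of the game, and in abstracted form on a structurally different
decision problem. This note records the models, the synthetic data they
are exercised on, and the numerical choices, in enough detail to
reimplement them.

## The two-kitchen cooking game

Two chefs occupy the left and right halves of a grid kitchen separated by
a wall with a single **cooperation bridge** cell. A soup requires three
onions in the pot; after a fixed cook time (default 5 ticks) the soup is
collected with a bowl and delivered for exactly 10 points. The right
kitchen is laid out so that fetching an onion takes 11 moves against the
left kitchen's 3, so the left chef can relieve a real asymmetry by
leaving onions on the bridge — at a time cost to its own score. Movement
is 4-neighborhood; moving into a non-floor cell turns the chef in place;
`interact` acts on the faced cell. The step function is deterministic,
and the two sides are disjoint except for the bridge, so simultaneous
actions cannot conflict (bridge interacts resolve left-chef-first).

Seven layouts ship with the package: the original, three variants
(`v1`-`v3`) in which the left chef's path to the bridge is shorter than
its path to the stove, two (`v4`, `v5`) in which it is longer, and one
(`v6`) in which the two are equal. The variant geometries are our own
reconstructions satisfying those path-length relations; no pixel-exact
maps were available.

## Synthetic cohort

No human dataset is available, so a generator stands in for it, and all
group-level claims about the pipeline are claims about this generator.
Each synthetic participant has a **sharing propensity** pi in [0, 1] — the
expected number of onions shared per delivered soup — drawn from a Beta
distribution moment-matched to the group calibration: mean 0.24,
SD 0.28 ("latino" group, n = 110) and mean 0.14, SD 0.21 ("white" group,
n = 190). Infeasible moment pairs (SD^2 >= mean(1-mean)) are clipped to
98% of the feasible variance with a warning.

A participant plays one episode on the left side against a scripted
help-seeking right chef. The policy cooks in cycles; each time a soup
starts cooking it shares one onion with probability pi during the cook
wait. Because the sharing trip strictly precedes that soup's delivery, a
share cut off by the episode clock also cuts the delivery, so the
realized ratio shared/delivered is an unbiased draw with mean pi for
every participant who delivers at all (measured bias +0.002 at n = 1000).
Participants with zero deliveries have an undefined ratio and are
excluded from group means. With probability `noise` (default 0.01 per
move) a planned move is replaced by a random legal move; larger values
make sharing episodes overrun the clock disproportionately often, which
selectively removes sharers from the included set and biases group means
low, so the default is deliberately small.

The episode horizon is 180 ticks: one 60-second round at roughly three
player actions per second. This rate was calibrated so a participant
completes about three soup cycles and therefore contributes ~12
onion-delivering traces, matching the per-participant trace volume the
study conditions describe (~2960 traces from 300 participants); it also
brings the realized per-participant ratio SD (~0.33) close to the
calibrated group SDs. At one action per second (horizon 60) a
participant finishes only one soup and the ratio degenerates to a single
Bernoulli draw.

Rollouts are segmented into **onion-delivering traces**: from the tick
whose interact picks an onion from the store to the tick whose interact
drops it at the bridge (label *altruistic*) or the own pot
(*non-altruistic*). A trace step pairs an action with its resulting
state, so the first state holds the onion and the last state shows it
deposited. Compaction merges consecutive steps whose states share the
agent position, keeping each run's last state and action. Four datasets
are formed: all altruistic traces, all non-altruistic traces, and the
per-group collections. Everything is reproducible: one `SeedSequence`
per cohort spawns one child generator per participant, so output files
are byte-identical across runs with the same config.

What the generator does **not** emulate: within-episode learning or
fatigue, behavioral accommodation across rounds (a propensity boost
after receiving help exists behind a config flag but is off by default
and excluded from IRL training), response-time structure, and any
demographic structure beyond the group tag. Passing tests therefore
show that the pipeline recovers the altruism gradient *it was fed*, not
that the gradient exists in people.

## Features

A game state is encoded for the left chef as an 18-vector: three
(row, col) offsets of the onion store, bridge, and stove relative to the
agent (sign convention object − agent, origin top-left); a 4-way
orientation one-hot; a 4-slot one-hot marking the agent's position along
the store-front→stove-front shortest path while carrying an onion
(all-zero when empty-handed or off the path; when several shortest paths
exist the lexicographically smallest is fixed per layout); and four
binary flags — onion on bridge, pot non-empty, agent has onion, other
chef has onion. "Onions in pot" is encoded as pot-non-empty rather than
a count, keeping the block one-dimensional.

## Maximum-entropy deep IRL

The reward network is linear(18→200) → ELU → linear(200→1), implemented
in NumPy with analytic gradients (verified against finite differences to
1e-5 relative). The maximum-entropy gradient with respect to the
per-state reward is the visitation mismatch mu_D − E[mu], backpropagated
through the network.

The forward problem is solved exactly rather than by sampled policy
gradients: the left chef's decision problem is abstracted to
position × orientation × holding × pot-non-empty × bridge-onion ×
other-has-onion (~1280 states for the original layout). The chef's own
dynamics are deterministic; the right chef appears only through two
exogenous Bernoulli events per tick (a waiting bridge onion is collected
with p = 0.2 and then appears in the other chef's hands; a held onion is
consumed with p = 0.3). Finite-horizon soft value iteration at
temperature 1 yields the time-varying stochastic policy, and expected
visitation counts come from forward dynamic programming, so the training
loop is deterministic given the weight-init seed. The solver horizon
defaults to (mean demonstration length − 1) and the expected counts are
rescaled to carry the same total mass as the empirical ones
(demonstrations are variable-length). The start distribution is the
empirical distribution of demonstration start states.

Optimizer: plain gradient ascent, learning rate 0.001 with exponential
decay (gamma 0.999 per iteration) and a decay hyperparameter of 0.9.
Whether that 0.9 denotes an L2 coefficient or a momentum coefficient is
genuinely ambiguous; both are implemented (`decay_mode="l2"`, the
default, and `"momentum"`). Under the L2 reading the stationary point
caps the reward scale (theta* = grad/0.9), which is adequate for the
kitchen datasets; the momentum reading converges much faster and is the
right choice for reward-recovery experiments that must match a target
policy closely. Default 200 iterations (~6 s on one CPU for the full
cohort); convergence is monitored by the visitation gap and by the
trajectory-MSE policy-similarity diagnostic.

## ART and the Sharing Ratio

The Average Reward of a Trajectory is the mean of min-max-normalized
per-step rewards; a degenerate span (all steps equal, including
single-step trajectories) maps every step to the neutral 0.5, keeping
ART in [0, 1]. The Sharing Ratio is mean sharing-trajectory ART over
mean cooking-trajectory ART, evaluated on canonical shortest-path
trajectory pairs built per layout (store front to bridge front / stove
front, ending with the deposit state).

The phrase "min-max normalization applied per trajectory step" admits
two readings, and the package implements both. Normalizing each
trajectory in isolation makes ART a pure *shape* statistic — it is
invariant to which trajectory's rewards sit higher, which discards
exactly the information the ratio is meant to compare, and empirically
destroys the cross-layout orderings once the reward is evaluated off its
training layout. The default therefore pools the min-max over all steps
of the two compared trajectory sets, making the ratio sensitive to
reward *levels* while remaining bounded and affine-invariant;
`normalization="per_trajectory"` retains the literal per-trajectory
reading for sensitivity analysis. Feature attributions are ablation
differences (flip one binary feature across a reference state set,
average the reward change), min-max scaled so the largest magnitude is 1.

## The Keep-or-Donate problem

Second-order generalization maps "onions in pot" to "I have the
resource" and "other chef has onion" to "the other agent has the
resource", and transfers the learned weights to a donation game: the AI
agent (balance X, start 5) and a poorer agent (balance Y, start 2) each
lose 1 unit per tick with probability 0.8 or 2 with probability 0.2
(floored at 0); the AI draws a salary of 5/10/15 units every 6/8/10
ticks (uniform, first payday at t = 6, interval and amount resampled at
each payday) while the other agent receives 2 at the same paydays. Each
tick the AI keeps or donates one unit. Reward:
w_self·[X>0] + w_other·[Y>0] − 1·[X=0], with (w_other, w_self) =
(0, 1), (0.08, 1), (0.27, 1), (1, 1) for the non-altruistic, white,
latino, and fully-altruistic agents. The −1 penalty applies to the
decision-maker's own balance on every tick spent at zero (a config
switch extends it to Y). Episodes last 100 ticks; discount 0.99
(episodic horizon, unstated upstream; configurable).

Policies are learned by tabular epsilon-greedy Q-learning on the (X, Y)
pair: learning rate 0.5 halved every 5000 episodes, epsilon 1 minus
0.00002 per episode floored at 0.1, donate masked whenever X = 0,
100 000 episodes by default. `QLearnConfig.scaled(n)` compresses the
epsilon anneal proportionally for desk-scale runs; the package's own
evaluations use 20 000 episodes.

Two estimator details matter because keep and donate have *nearly
identical* true values whenever X is comfortably positive (the reward
sees only the X>0 indicator, so the only true difference is a small
discounted ruin-risk term favoring keep). First, over the final half of
training a Polyak-Ruppert running average of each Q estimate (with a
Welford variance) is maintained; the returned table is built from these
averages rather than the noisy last iterate. Second, the greedy readout
is significance-gated: donate is preferred only where its averaged
advantage exceeds twice its nominal standard error, and in states where
either action went unsampled during the averaging window no comparison
exists and the agent keeps. Without these, residual update noise breaks
the value ties essentially at random and the learned donation rates of
the four agent types are dominated by that noise rather than by their
w_other weights. Both are estimator/readout choices; the update rule
itself is standard Q-learning.

Evaluation runs the greedy policy for 100 seeded episodes and reports
the mean donate fraction, the per-tick cumulative donate(+1)/keep(−1)
curve with its across-episode SD band, and per-episode balance/action
traces. A parameter sweep re-trains and re-evaluates every agent type
over a config grid (e.g. horizons 50/100/200) to re-check orderings.

Note the income/expense balance: expected expenses are 1.2 units per
tick against expected salary 10/8 = 1.25, so sustained donation is
budget-limited for every agent type; even the fully altruistic agent's
donate fraction sits well below one half.

## Problem sizes used by the shipped tests

The test suite and acceptance script run the full 300-participant
cohort, four 200-iteration IRL trainings on it, Monte-Carlo checks with
1e5 rollouts, and four 20 000-episode Q-learning runs. These sizes were
chosen so the whole pipeline re-runs from scratch in a few minutes on a
single CPU while keeping every statistical check comfortably powered.

## Known limitations

- The cohort realizes each participant's propensity with ~3 Bernoulli
  opportunities, so realized group SDs (~0.33/~0.27) sit slightly above
  the calibrated 0.28/0.21 and absolute trace counts match the study
  volume only approximately (the altruistic-trace *fraction* is lower
  than the study's because every non-shared onion contributes a
  non-altruistic trace).
- The IRL abstraction fixes the right chef to two Bernoulli events;
  rewards conditioned on richer opponent behavior are out of reach by
  construction.
- Sharing Ratios on variant layouts inherit the reward network's
  extrapolation over relative-position features it never saw in
  training; orderings are reproducible but absolute values should not be
  over-read.
- Q-learning on (X, Y) ignores payday phase, which is genuinely part of
  the environment state; the learned values average over it.
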
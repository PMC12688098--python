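# attune

Learning culturally-attuned altruistic values from behavior, end to end:
a cooperative two-kitchen cooking game, a synthetic behavioral cohort
whose group-level sharing statistics are calibrated to published values,
maximum-entropy deep inverse reinforcement learning (IRL) over
hand-designed game features, interpretable sharing metrics, and transfer
of the learned reward weights to a different altruistic decision problem.

The package is aimed at computational behavioral scientists who want a
small, fully inspectable testbed for *implicit value learning*: instead
of asking people what they value, an agent watches what they do — here,
whether a player passes onions over a "cooperation bridge" to a
disadvantaged partner or keeps cooking for points — and infers a reward
function whose soft-optimal behavior reproduces those choices.

## The model in brief

A demonstration is an *onion-delivering trace* tau: the left chef picks
up an onion and carries it either to its own pot (non-altruistic) or to
the bridge (altruistic). Each game state maps to an 18-dimensional
feature vector f (relative positions of store/bridge/stove, orientation,
progress along the cook path, and four binary flags such as *onion on
bridge* and *other agent has onion*). A two-layer network
r = W2·ELU(W1·f + b1) + b2 is trained by MaxEnt IRL: with mu_D the
empirical state-visitation counts of the demonstrations and E[mu_theta]
the expected counts of the current soft-optimal policy (computed exactly
by soft value iteration and dynamic programming on a factored
abstraction of the kitchen),

    dL/dr(s) = mu_D(s) - E[mu_theta(s)]

is backpropagated through the network. Learned rewards are compared via
the Sharing Ratio SR = ART_S / ART_C, where ART(tau, r) is the mean of
min-max-normalized per-step rewards along a trajectory, evaluated on
canonical sharing/cooking trajectory pairs; SR > 1 means the reward
values giving an onion away above cooking it. Finally, the weights
learned for "other agent has onion" / "onions in pot" transfer as
"other agent has the resource" / "I have the resource" to a stochastic
Keep-or-Donate balance game solved by tabular Q-learning.

## Worked example

```python
from attune import demos, environment as env, irl, metrics

# 1. simulate the 300-participant cohort (110 latino + 190 white)
cohort = demos.generate_cohort(demos.CohortConfig(seed=1))
print(demos.group_sharing_stats(cohort.manifest).round(3))

# 2. train one reward function per dataset
kitchen = irl.KitchenMdp(env.builtin_layout("original"))
models = {}
for name in ("altruistic", "latino", "white", "non_altruistic"):
    traces = kitchen.traces_to_demos(cohort.datasets[name])
    models[name], _ = irl.train_irl(traces, kitchen.mdp,
                                    irl.IRLHyper(n_iters=200), seed=0)

# 3. sharing ratios on all seven layouts, no retraining
layouts = {n: env.builtin_layout(n) for n in env.BUILTIN_LAYOUTS}
print(metrics.layout_generalization_sweep(models, layouts).round(3))
```

This prints the cohort calibration,

```
         mean    std    n     se
group
latino  0.297  0.359  110  0.034
white   0.116  0.216  190  0.016
```

(group means near the calibrated 0.24 / 0.14 onions shared per delivered
soup, within sampling error of a 110/190-participant draw), and the
Sharing-Ratio table,

```
          altruistic  latino  white  non_altruistic
original       4.012   0.199  0.136           0.099
v1             1.524   0.448  0.438           0.432
v2             1.417   0.172  0.120           0.088
v3             1.498   0.257  0.188           0.143
v4             2.957   1.097  1.058           1.034
v5             3.444   0.626  0.606           0.596
v6             3.700   0.615  0.585           0.568
```

in which every layout preserves the ordering fully-altruistic >
latino-trained > white-trained > non-altruistic: the reward learned from
the more altruistic group consistently values sharing more, including on
six spatial variants it never saw during training.

The same pipeline is scriptable from the shell (`attune gen-cohort`,
`attune train-irl`, `attune sweep-layouts`, `attune donate-train`, ...);
every command writes a `manifest.json` from which its outputs can be
regenerated exactly.

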
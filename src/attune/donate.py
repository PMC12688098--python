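"""The "Keep or Donate" problem: second-order generalization testbed.

A resource-rich AI agent (balance X) and a resource-poor other agent
(balance Y) face stochastic expenses of 1 unit (p = 0.8) or 2 units
(p = 0.2) every time step, balances floored at zero.  The AI agent draws
a salary of 5, 10 or 15 units every 6, 8 or 10 steps (uniform; first
payday at t = 6) while the other agent receives 2 units at the same
paydays.  Each step the AI agent chooses to keep its balance or donate
one unit.  An episode starts at (X, Y) = (5, 2) and lasts 100 steps.

The per-step reward transfers the generalized reward-feature weights
learned in the kitchen game — "I have the resource" and "the other agent
has the resource" —

    r = w_self * [X > 0] + w_other * [Y > 0] - 1 * [X = 0],

with (w_other, w_self) per agent type: non-altruistic (0, 1),
white (0.08, 1), latino (0.27, 1), fully altruistic (1, 1).  Policies
are learned by tabular epsilon-greedy Q-learning on the (X, Y) state with
the schedules: initial learning rate 0.5 halved every 5000 episodes;
epsilon starting at 1, reduced by 0.00002 per episode and floored at 0.1.

Because keep and donate are near value-ties over much of the state space,
the returned Q-table is a Polyak-averaged, evidence-gated readout (see
:class:`QLearnConfig`) and headline donation rates are reported as means
over independent training replicates
(:func:`replicate_donation_rates`).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

KEEP, DONATE = 0, 1
ACTION_NAMES = ("keep", "donate")

#: (w_other, w_self) per agent type: the "other agent has the resource"
#: weight rises from the non-altruistic through the white- and
#: latino-trained agents to the fully altruistic one
AGENT_WEIGHTS: Mapping[str, tuple[float, float]] = {
    "non_altruistic": (0.0, 1.0),
    "white": (0.08, 1.0),
    "latino": (0.27, 1.0),
    "fully_altruistic": (1.0, 1.0),
}


class IllegalActionError(ValueError):
    """Donating with an empty balance."""


@dataclass(frozen=True)
class DonateState:
    x: int                 # AI agent balance
    y: int                 # other agent balance
    t: int                 # step within the episode
    next_payday: int
    pending_salary: int    # S_X to be paid at the next payday (S_Y is fixed)

    @property
    def key(self) -> tuple[int, int]:
        """Q-table key: the learner only observes the balances."""
        return (self.x, self.y)


@dataclass(frozen=True)
class DonateConfig:
    start_x: int = 5
    start_y: int = 2
    horizon: int = 100
    expense_values: tuple[int, ...] = (1, 2)
    expense_probs: tuple[float, ...] = (0.8, 0.2)
    salaries_x: tuple[int, ...] = (5, 10, 15)
    payday_intervals: tuple[int, ...] = (6, 8, 10)
    salary_y: int = 2
    first_payday: int = 6
    zero_penalty: float = 1.0
    penalize_other_zero: bool = False   # sensitivity switch: extend -1 to Y = 0
    donation: int = 1
    discount: float = 0.99

    def __post_init__(self):
        if abs(sum(self.expense_probs) - 1.0) > 1e-9:
            raise ValueError("expense probabilities must sum to 1")
        if len(self.expense_probs) != len(self.expense_values):
            raise ValueError("expense values/probs length mismatch")


@dataclass(frozen=True)
class QLearnConfig:
    """Schedules follow the stated arithmetic: the learning rate starts at
    0.5 and halves every 5000 episodes; epsilon starts at 1, loses 0.00002
    per episode and is floored at 0.1.

    ``tail_average_frac`` enables Polyak-Ruppert averaging: over the final
    fraction of episodes a running average of each Q estimate is kept, and
    the averaged values form the returned table.  Because keep and donate
    have nearly identical values whenever the balance is comfortably
    positive, the raw last-iterate Q breaks these ties with residual
    update noise; the tail average resolves them by the true (tiny) value
    difference instead.  Set to 0 for plain last-iterate Q-learning.
    """
    n_episodes: int = 100_000
    lr0: float = 0.5
    lr_halve_every: int = 5_000
    eps0: float = 1.0
    eps_decrement: float = 0.00002
    eps_floor: float = 0.1
    tail_average_frac: float = 0.5
    min_tail_samples: int = 50

    @classmethod
    def scaled(cls, n_episodes: int) -> "QLearnConfig":
        """A desk-scale run: same learning-rate arithmetic, with the epsilon
        anneal compressed so exploration still reaches its floor within the
        shorter run."""
        return cls(n_episodes=n_episodes,
                   eps_decrement=0.00002 * (100_000 / n_episodes))


def learning_rate(episode: int, qc: QLearnConfig = QLearnConfig()) -> float:
    return qc.lr0 * 0.5 ** (episode // qc.lr_halve_every)


def epsilon(episode: int, qc: QLearnConfig = QLearnConfig()) -> float:
    return max(qc.eps_floor, qc.eps0 - qc.eps_decrement * episode)


@lru_cache(maxsize=64)
def _cum_probs(probs: tuple[float, ...]) -> tuple[float, ...]:
    out, acc = [], 0.0
    for p in probs:
        acc += p
        out.append(acc)
    return tuple(out)


def _draw(values: Sequence[int], cum_probs: Sequence[float], u: float) -> int:
    for v, c in zip(values, cum_probs):
        if u < c:
            return v
    return values[-1]


def _uniform_pick(values: Sequence[int], u: float) -> int:
    return values[min(int(u * len(values)), len(values) - 1)]


def initial_donate_state(config: DonateConfig, rng) -> DonateState:
    """``rng`` needs only a ``.random()`` method (``random.Random`` or a
    NumPy generator both work)."""
    return DonateState(x=config.start_x, y=config.start_y, t=0,
                       next_payday=config.first_payday,
                       pending_salary=_uniform_pick(config.salaries_x, rng.random()))


def donate_step(state: DonateState, action: int, config: DonateConfig,
                weights: tuple[float, float], rng) -> tuple[DonateState, float]:
    """One tick of the Markov dynamics.

    Event order: (1) the donation transfers one unit if chosen; (2) each
    agent's independent expense is deducted with balances floored at 0;
    (3) if the new step index is a payday both salaries arrive and the
    next payday interval and salary are resampled.  The reward is
    evaluated on the resulting state.  ``rng`` needs only ``.random()``.
    """
    if action not in (KEEP, DONATE):
        raise ValueError(f"invalid action {action}")
    x, y = state.x, state.y
    if action == DONATE:
        if x < config.donation:
            raise IllegalActionError("cannot donate with an empty balance")
        x -= config.donation
        y += config.donation
    cum = _cum_probs(config.expense_probs)
    ex = _draw(config.expense_values, cum, rng.random())
    ey = _draw(config.expense_values, cum, rng.random())
    x = max(0, x - ex)
    y = max(0, y - ey)
    t = state.t + 1
    next_payday, pending = state.next_payday, state.pending_salary
    if t == next_payday:
        x += pending
        y += config.salary_y
        next_payday = t + _uniform_pick(config.payday_intervals, rng.random())
        pending = _uniform_pick(config.salaries_x, rng.random())
    w_other, w_self = weights
    reward = w_self * (x > 0) + w_other * (y > 0) - config.zero_penalty * (x == 0)
    if config.penalize_other_zero:
        reward -= config.zero_penalty * (y == 0)
    return DonateState(x=x, y=y, t=t, next_payday=next_payday,
                       pending_salary=pending), float(reward)


# ---------------------------------------------------------------------------
# Q-learning
# ---------------------------------------------------------------------------

QTable = dict  # (x, y) -> [q_keep, q_donate]


def _q_values(q: QTable, key: tuple[int, int]) -> list[float]:
    v = q.get(key)
    if v is None:
        v = [0.0, 0.0]
        q[key] = v
    return v


def _legal_max(qv: Sequence[float], x: int) -> float:
    return qv[KEEP] if x == 0 else max(qv)


def train_q(config: DonateConfig, agent_type: str, seed: int = 0,
            qlearn: QLearnConfig = QLearnConfig()) -> tuple[QTable, pd.DataFrame]:
    """Tabular epsilon-greedy Q-learning of the donation policy.

    The donate action is masked (never selected, never bootstrapped from)
    whenever X = 0.  Returns the Q-table and a sparse training log of
    per-episode returns.
    """
    if agent_type not in AGENT_WEIGHTS:
        raise ValueError(f"unknown agent type {agent_type!r}")
    weights = AGENT_WEIGHTS[agent_type]
    rng = random.Random(seed)   # hot loop: stdlib rng is several-fold faster
    gamma = config.discount
    q: QTable = {}
    qbar: dict = {}
    nbar: dict = {}
    tail_start = int(qlearn.n_episodes * (1.0 - qlearn.tail_average_frac))
    log = []
    log_every = max(1, qlearn.n_episodes // 100)
    for episode in range(qlearn.n_episodes):
        lr = learning_rate(episode, qlearn)
        eps = epsilon(episode, qlearn)
        in_tail = episode >= tail_start and qlearn.tail_average_frac > 0
        state = initial_donate_state(config, rng)
        ep_return = 0.0
        while state.t < config.horizon:
            key = state.key
            qv = _q_values(q, key)
            if state.x == 0:
                action = KEEP
            elif rng.random() < eps:
                action = KEEP if rng.random() < 0.5 else DONATE
            else:
                action = DONATE if qv[DONATE] > qv[KEEP] else KEEP
            nxt, reward = donate_step(state, action, config, weights, rng)
            if not np.isfinite(reward):
                raise RuntimeError(f"non-finite reward at episode {episode}")
            if nxt.t >= config.horizon:
                target = reward
            else:
                target = reward + gamma * _legal_max(_q_values(q, nxt.key), nxt.x)
            qv[action] += lr * (target - qv[action])
            if not np.isfinite(qv[action]):
                raise RuntimeError(f"non-finite Q-update at episode {episode}")
            if in_tail:
                bv = qbar.setdefault(key, [0.0, 0.0])
                nv = nbar.setdefault(key, [0, 0])
                nv[action] += 1
                bv[action] += (qv[action] - bv[action]) / nv[action]
            ep_return += reward
            state = nxt
        if episode % log_every == 0 or episode == qlearn.n_episodes - 1:
            log.append({"episode": episode, "lr": lr, "epsilon": eps,
                        "return": ep_return})
    if qlearn.tail_average_frac > 0:
        out: QTable = {}
        for key in q:
            nv = nbar.get(key, (0, 0))
            if min(nv) >= qlearn.min_tail_samples:
                out[key] = list(qbar[key])
            else:
                # no reliable comparison was formed in the averaging window:
                # never prefer a barely-estimated action over keeping
                out[key] = [0.0, -1.0]
        q = out
    return q, pd.DataFrame(log)


def greedy_policy(q: QTable) -> Callable[[DonateState], int]:
    """Greedy policy from a Q-table; ties and unseen states keep."""
    def policy(state: DonateState) -> int:
        if state.x == 0:
            return KEEP
        qv = q.get(state.key)
        if qv is None:
            return KEEP
        return DONATE if qv[DONATE] > qv[KEEP] else KEEP
    return policy


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class DonationEval:
    donate_fraction: float                  # mean over episodes
    episode_fractions: np.ndarray           # [n_episodes]
    cumulative_mean: np.ndarray             # [horizon] mean of cumsum(+1/-1)
    cumulative_sd: np.ndarray               # [horizon]
    traces: list[pd.DataFrame]              # per-episode (t, x, y, action)


def evaluate_donation(policy: Callable[[DonateState], int] | QTable,
                      config: DonateConfig, agent_type: str = "latino",
                      n_episodes: int = 100, seed: int = 0,
                      n_traces: int = 4) -> DonationEval:
    """Greedy-policy evaluation over full episodes.

    Reports the mean fraction of donate actions, the per-step cumulative
    donate(+1)/keep(-1) curve with its across-episode SD band, and a few
    per-episode balance/action traces.
    """
    if n_episodes <= 0:
        raise ValueError("n_episodes must be positive")
    if isinstance(policy, dict):
        policy = greedy_policy(policy)
    weights = AGENT_WEIGHTS[agent_type]
    rng = random.Random(seed)
    fractions = np.zeros(n_episodes)
    cumsums = np.zeros((n_episodes, config.horizon))
    traces: list[pd.DataFrame] = []
    for ep in range(n_episodes):
        state = initial_donate_state(config, rng)
        acts = np.zeros(config.horizon, dtype=int)
        rows = []
        for t in range(config.horizon):
            action = policy(state)
            if state.x == 0:
                action = KEEP
            rows.append({"t": t, "x": state.x, "y": state.y, "action": action})
            acts[t] = action
            state, _ = donate_step(state, action, config, weights, rng)
        fractions[ep] = acts.mean()
        cumsums[ep] = np.cumsum(np.where(acts == DONATE, 1, -1))
        if ep < n_traces:
            traces.append(pd.DataFrame(rows))
    return DonationEval(
        donate_fraction=float(fractions.mean()),
        episode_fractions=fractions,
        cumulative_mean=cumsums.mean(axis=0),
        cumulative_sd=cumsums.std(axis=0),
        traces=traces,
    )


def replicate_donation_rates(config: DonateConfig,
                             agent_types: Sequence[str] | None = None,
                             seed: int = 0, n_replicates: int = 3,
                             qlearn: QLearnConfig = QLearnConfig(),
                             n_eval_episodes: int = 100) -> pd.DataFrame:
    """Mean donate fraction per agent type over independent training runs.

    A single Q-learning run's greedy donate fraction carries seed-level
    noise comparable to the between-agent differences (keep and donate are
    near value-ties over much of the state space), so the package's
    headline donation rates average ``n_replicates`` runs seeded
    ``seed, seed+1, ...``.  Returns one row per agent type with the mean
    and the per-replicate fractions.
    """
    if agent_types is None:
        agent_types = list(AGENT_WEIGHTS)
    rows = []
    for agent in agent_types:
        fractions = []
        for r in range(n_replicates):
            q, _ = train_q(config, agent, seed=seed + r, qlearn=qlearn)
            ev = evaluate_donation(q, config, agent_type=agent,
                                   n_episodes=n_eval_episodes, seed=seed)
            fractions.append(ev.donate_fraction)
        rows.append({"agent": agent,
                     "donate_fraction": float(np.mean(fractions)),
                     **{f"replicate_{r}": f for r, f in enumerate(fractions)}})
    return pd.DataFrame(rows).set_index("agent")


def parameter_sweep(base: DonateConfig, grid: Mapping[str, Sequence],
                    agent_types: Sequence[str], seed: int = 0,
                    n_train_episodes: int = 20_000,
                    n_eval_episodes: int = 100) -> pd.DataFrame:
    """Re-train and re-evaluate every agent type on every grid cell.

    ``grid`` maps :class:`DonateConfig` field names to value lists; the
    result table has one row per (cell, agent type) with the evaluated
    donate fraction, so ordering properties can be re-checked under
    parameter variations.
    """
    keys = list(grid)
    rows = []
    for combo in product(*(grid[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)))
        for agent in agent_types:
            q, _ = train_q(cfg, agent, seed=seed,
                           qlearn=QLearnConfig(n_episodes=n_train_episodes))
            ev = evaluate_donation(q, cfg, agent_type=agent,
                                   n_episodes=n_eval_episodes, seed=seed)
            row = dict(zip(keys, combo))
            row.update({"agent": agent, "donate_fraction": ev.donate_fraction})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_qtable(q: QTable, path) -> None:
    with open(path, "w") as fh:
        json.dump({f"{x},{y}": v for (x, y), v in q.items()}, fh)


def load_qtable(path) -> QTable:
    with open(path) as fh:
        raw = json.load(fh)
    out: QTable = {}
    for k, v in raw.items():
        x, y = k.split(",")
        out[(int(x), int(y))] = list(v)
    return out
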
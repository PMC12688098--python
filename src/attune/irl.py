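"""Maximum-entropy deep inverse reinforcement learning.

Learns a reward function r = NN(f; theta) over the 18 hand-designed
features such that the soft-optimal policy under r reproduces the
state-visitation statistics of the demonstration traces.  The gradient of
the maximum-entropy demonstration likelihood with respect to the
per-state rewards is the difference between the empirical and the
expected state-visitation counts,

    dL/dr(s) = mu_D(s) - E[mu(s)],

which is backpropagated through the reward network (a linear 18 -> 200
layer, ELU, linear 200 -> 1; implemented here in plain NumPy with
analytic gradients).

The forward policy-optimization step is exact finite-horizon soft value
iteration on a factored abstraction of the left chef's decision problem
(:class:`KitchenMdp`): position x orientation x holding-an-onion x
pot-non-empty x onion-on-bridge x other-chef-has-onion.  The abstraction
is small enough (~1000 states) that expected visitation counts come from
dynamic programming rather than sampled rollouts, so training is
deterministic given the seed.  The solver sits behind a plain contract
(rewards in, stochastic policy out), so a sampled policy-gradient backend
could be substituted without touching the training loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import logsumexp, softmax

from . import environment as env
from .demos import Trace
from .features import FeatureExtractor, StateCore, core_from_state, N_FEATURES


# ---------------------------------------------------------------------------
# Reward network
# ---------------------------------------------------------------------------

class RewardNet:
    """Two-layer reward network: linear(in, hidden) -> ELU -> linear(hidden, 1)."""

    def __init__(self, in_dim: int = N_FEATURES, hidden: int = 200,
                 seed: int = 0, init_scale: float = 0.05):
        rng = np.random.default_rng(seed)
        self.in_dim = in_dim
        self.hidden = hidden
        self.W1 = rng.uniform(-init_scale, init_scale, size=(in_dim, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.uniform(-init_scale, init_scale, size=hidden)
        self.b2 = 0.0

    # ELU with alpha = 1
    @staticmethod
    def _elu(z: np.ndarray) -> np.ndarray:
        return np.where(z > 0, z, np.expm1(np.clip(z, None, 30.0)))

    @staticmethod
    def _elu_grad(z: np.ndarray) -> np.ndarray:
        return np.where(z > 0, 1.0, np.exp(np.clip(z, None, 30.0)))

    def forward(self, F: np.ndarray) -> np.ndarray:
        """Scalar reward for each row of the feature matrix ``F``."""
        F = np.atleast_2d(np.asarray(F, dtype=float))
        if F.shape[1] != self.in_dim:
            raise ValueError(f"feature dimension {F.shape[1]} != {self.in_dim}")
        Z = F @ self.W1 + self.b1
        return self._elu(Z) @ self.W2 + self.b2

    def reward(self, f: np.ndarray) -> float:
        return float(self.forward(np.atleast_2d(f))[0])

    def grads(self, F: np.ndarray, g: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of ``sum_s g[s] * r(F[s])`` with respect to the weights."""
        F = np.atleast_2d(np.asarray(F, dtype=float))
        g = np.asarray(g, dtype=float)
        Z = F @ self.W1 + self.b1
        H = self._elu(Z)
        dW2 = H.T @ g
        db2 = float(g.sum())
        delta = (g[:, None] * self.W2[None, :]) * self._elu_grad(Z)
        dW1 = F.T @ delta
        db1 = delta.sum(axis=0)
        return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {"architecture": [self.in_dim, self.hidden, 1], "activation": "ELU",
                "W1": self.W1.tolist(), "b1": self.b1.tolist(),
                "W2": self.W2.tolist(), "b2": self.b2}

    @classmethod
    def from_dict(cls, d: dict) -> "RewardNet":
        in_dim, hidden, _ = d["architecture"]
        net = cls(in_dim=in_dim, hidden=hidden, seed=0, init_scale=0.0)
        net.W1 = np.asarray(d["W1"], dtype=float)
        net.b1 = np.asarray(d["b1"], dtype=float)
        net.W2 = np.asarray(d["W2"], dtype=float)
        net.b2 = float(d["b2"])
        return net

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "RewardNet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Tabular MDP container
# ---------------------------------------------------------------------------

@dataclass
class TabularMdp:
    """Finite MDP with per-action sparse transition matrices and a feature
    matrix ``features[s]`` feeding the reward network."""

    transitions: list[sp.csr_matrix]      # one [S, S] row-stochastic matrix per action
    features: np.ndarray                  # [S, n_features]
    state_vectors: np.ndarray             # [S, k] numeric encoding for trajectory MSE

    @property
    def n_states(self) -> int:
        return self.features.shape[0]

    @property
    def n_actions(self) -> int:
        return len(self.transitions)

    def validate(self) -> None:
        for a, T in enumerate(self.transitions):
            rows = np.asarray(T.sum(axis=1)).ravel()
            if not np.allclose(rows, 1.0):
                raise ValueError(f"transition matrix for action {a} is not row-stochastic")


# ---------------------------------------------------------------------------
# Soft value iteration and visitation counts
# ---------------------------------------------------------------------------

def solve_soft_policy(rewards: np.ndarray, mdp: TabularMdp, horizon: int,
                      temperature: float = 1.0) -> list[np.ndarray]:
    """Finite-horizon soft value iteration.

    Returns the time-varying stochastic policy ``policies[t][s, a]`` for
    t = 0..horizon-1.  At temperature 1 the policy is
    pi(a|s) proportional to exp(Q_soft(s, a)); as temperature -> 0 it
    approaches the argmax policy.  Rewards are state-based and collected
    on every visited state including the last.
    """
    r = np.asarray(rewards, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite rewards passed to the soft solver")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    V = r.copy()
    policies: list[np.ndarray] = []
    for _ in range(horizon):
        Q = np.stack([T @ V for T in mdp.transitions], axis=1)
        if temperature == 0.0:
            pol = np.zeros_like(Q)
            pol[np.arange(len(Q)), Q.argmax(axis=1)] = 1.0
            V = r + Q.max(axis=1)
        else:
            pol = softmax(Q / temperature, axis=1)
            V = r + temperature * logsumexp(Q / temperature, axis=1)
        policies.append(pol)
    policies.reverse()
    return policies


def expected_svf(policies: Sequence[np.ndarray], mdp: TabularMdp,
                 start_dist: np.ndarray) -> np.ndarray:
    """Expected state-visitation counts by forward dynamic programming.

    ``d_{t+1}(s') = sum_{s,a} d_t(s) pi_t(a|s) T(s'|s,a)``; the returned
    counts sum to ``horizon + 1`` (every trajectory visits horizon + 1
    states, start included).
    """
    d = np.asarray(start_dist, dtype=float).copy()
    mu = d.copy()
    for pol in policies:
        d = sum((mdp.transitions[a].T @ (d * pol[:, a]))
                for a in range(mdp.n_actions))
        mu += d
    return mu


def empirical_svf(demos: Sequence[Sequence[int]], n_states: int) -> np.ndarray:
    """Per-state visit counts averaged over demonstration trajectories."""
    demos = list(demos)
    if not demos:
        raise ValueError("empty demonstration set")
    mu = np.zeros(n_states)
    for demo in demos:
        for s in demo:
            mu[s] += 1.0
    return mu / len(demos)


def start_distribution(demos: Sequence[Sequence[int]], n_states: int) -> np.ndarray:
    d = np.zeros(n_states)
    for demo in demos:
        d[demo[0]] += 1.0
    return d / d.sum()


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IRLHyper:
    """Optimizer settings for the reward network.

    ``weight_decay`` is the decay hyperparameter handed to the gradient
    method; with ``decay_mode="l2"`` it shrinks weights by
    ``lr * weight_decay * theta`` per step, with ``decay_mode="momentum"``
    it is the momentum coefficient.  The learning rate decays by
    ``lr_gamma`` per iteration (exponential schedule).
    """
    learning_rate: float = 0.001
    weight_decay: float = 0.9
    decay_mode: str = "l2"           # or "momentum"
    lr_gamma: float = 0.999
    n_iters: int = 200
    temperature: float = 1.0
    horizon: int | None = None       # default: mean demonstration length - 1

    def __post_init__(self):
        if self.learning_rate <= 0 or not (0 < self.lr_gamma <= 1):
            raise ValueError("learning_rate must be positive and lr_gamma in (0, 1]")
        if self.decay_mode not in ("l2", "momentum"):
            raise ValueError("decay_mode must be 'l2' or 'momentum'")


def train_irl(demos: Sequence[Sequence[int]], mdp: TabularMdp,
              hyper: IRLHyper = IRLHyper(), seed: int = 0,
              start_dist: np.ndarray | None = None,
              net: RewardNet | None = None) -> tuple[RewardNet, pd.DataFrame]:
    """Fit the reward network to demonstrations by MaxEnt IRL.

    ``demos`` are trajectories as sequences of state indices into ``mdp``.
    Returns the trained network and a per-iteration diagnostic log
    (gradient norm of the visitation mismatch and mean demo-state reward).
    """
    demos = [list(d) for d in demos if len(d) > 0]
    if not demos:
        raise ValueError("empty demonstration set")
    mu_D = empirical_svf(demos, mdp.n_states)
    if start_dist is None:
        start_dist = start_distribution(demos, mdp.n_states)
    mean_len = np.mean([len(d) for d in demos])
    horizon = hyper.horizon if hyper.horizon is not None else max(1, round(mean_len) - 1)
    if net is None:
        net = RewardNet(in_dim=mdp.features.shape[1], seed=seed)
    lr = hyper.learning_rate
    velocity = {k: np.zeros_like(v) if isinstance(v, np.ndarray) else 0.0
                for k, v in (("W1", net.W1), ("b1", net.b1), ("W2", net.W2), ("b2", net.b2))}
    log = []
    for it in range(hyper.n_iters):
        r = net.forward(mdp.features)
        if not np.all(np.isfinite(r)):
            raise RuntimeError(f"IRL diverged: non-finite rewards at iteration {it}")
        policies = solve_soft_policy(r, mdp, horizon, hyper.temperature)
        mu = expected_svf(policies, mdp, start_dist)
        # rescale so both visitation profiles carry the same mass: demos are
        # variable-length, the DP rollout is fixed-horizon
        mu = mu * (mu_D.sum() / mu.sum())
        g = mu_D - mu
        grads = net.grads(mdp.features, g)
        for name, param in (("W1", net.W1), ("b1", net.b1), ("W2", net.W2)):
            update = grads[name]
            if hyper.decay_mode == "l2":
                step_vec = lr * (update - hyper.weight_decay * param)
            else:
                velocity[name] = hyper.weight_decay * velocity[name] + update
                step_vec = lr * velocity[name]
            param += step_vec
        if hyper.decay_mode == "l2":
            net.b2 += lr * (grads["b2"] - hyper.weight_decay * net.b2)
        else:
            velocity["b2"] = hyper.weight_decay * velocity["b2"] + grads["b2"]
            net.b2 += lr * velocity["b2"]
        demo_reward = float((mu_D * r).sum() / max(mu_D.sum(), 1e-12))
        log.append({"iteration": it, "lr": lr,
                    "svf_gap": float(np.linalg.norm(g)),
                    "mean_demo_state_reward": demo_reward})
        lr *= hyper.lr_gamma
    return net, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# Policy similarity (trajectory MSE)
# ---------------------------------------------------------------------------

def rollout_policy(policies: Sequence[np.ndarray], mdp: TabularMdp, start: int,
                   length: int, rng: np.random.Generator) -> list[int]:
    """Sample a state trajectory of ``length`` states from the policy."""
    s = start
    out = [s]
    for t in range(length - 1):
        pol = policies[min(t, len(policies) - 1)]
        a = int(rng.choice(mdp.n_actions, p=pol[s]))
        row = mdp.transitions[a].getrow(s)
        nxt = rng.choice(row.indices, p=row.data) if row.nnz else s
        s = int(nxt)
        out.append(s)
    return out


def policy_similarity(policies: Sequence[np.ndarray], mdp: TabularMdp,
                      demos: Sequence[Sequence[int]], seed: int = 0) -> float:
    """Mean squared error between policy-generated and demonstrated
    state trajectories.

    For each demonstration, one trajectory is rolled out from the demo's
    start state; squared distance between the numeric state encodings is
    averaged over aligned steps (truncated to the shorter trajectory) and
    then over demonstrations.  Identical trajectories give 0.
    """
    demos = [list(d) for d in demos if len(d) > 0]
    if not demos:
        raise ValueError("empty demonstration set")
    rng = np.random.default_rng(seed)
    errs = []
    for demo in demos:
        roll = rollout_policy(policies, mdp, demo[0], len(demo), rng)
        n = min(len(roll), len(demo))
        a = mdp.state_vectors[np.asarray(roll[:n])]
        b = mdp.state_vectors[np.asarray(demo[:n])]
        errs.append(float(((a - b) ** 2).sum(axis=1).mean()))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# The kitchen abstraction MDP
# ---------------------------------------------------------------------------

ORIENT_INDEX = {o: i for i, o in enumerate(env.ORIENTATIONS)}


class KitchenMdp:
    """Factored single-agent MDP of the left chef's onion-routing decision.

    States are :class:`~attune.features.StateCore` tuples over the left
    kitchen's floor cells.  The chef's own dynamics (moving, picking up an
    onion, depositing it at pot or bridge) are deterministic; the other
    chef is folded into two exogenous Bernoulli events per tick: a waiting
    bridge onion is collected with probability ``p_bridge_pickup`` (it
    then appears in the other chef's hands) and a held onion is consumed
    into their pot with probability ``p_other_consume``.
    """

    def __init__(self, layout: env.Layout, p_bridge_pickup: float = 0.2,
                 p_other_consume: float = 0.3):
        self.layout = layout
        self.extractor = FeatureExtractor.for_layout(layout)
        self.p_bridge_pickup = p_bridge_pickup
        self.p_other_consume = p_other_consume

        cells = sorted(layout.floor_cells("left"))
        self.states: list[StateCore] = [
            StateCore(pos, o, h, p, b, q)
            for pos in cells for o in env.ORIENTATIONS
            for h in (0, 1) for p in (0, 1) for b in (0, 1) for q in (0, 1)]
        self.index: dict[StateCore, int] = {s: i for i, s in enumerate(self.states)}
        n = len(self.states)

        F = np.array([self.extractor.extract_core(s) for s in self.states])
        vecs = np.array([[s.pos[0], s.pos[1], ORIENT_INDEX[s.orient], s.holding,
                          s.pot_nonempty, s.bridge_onion, s.other_has_onion]
                         for s in self.states], dtype=float)

        transitions = []
        for a in env.ACTIONS:
            rows, cols, vals = [], [], []
            for i, s in enumerate(self.states):
                for j, p in self._successors(s, a):
                    rows.append(i)
                    cols.append(j)
                    vals.append(p)
            T = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
            transitions.append(T)
        self.mdp = TabularMdp(transitions=transitions, features=F, state_vectors=vecs)
        self.mdp.validate()

    # -- dynamics ---------------------------------------------------------

    def _agent_step(self, s: StateCore, action: str) -> StateCore:
        layout = self.layout
        if action in env.MOVE_ACTIONS:
            orient = env.MOVE_TO_ORIENT[action]
            dr, dc = env.ORIENT_DELTAS[orient]
            target = (s.pos[0] + dr, s.pos[1] + dc)
            pos = target if (layout.is_floor(target)
                             and layout.side_of(target) == "left") else s.pos
            return s._replace(pos=pos, orient=orient)
        if action == env.INTERACT:
            dr, dc = env.ORIENT_DELTAS[s.orient]
            target = (s.pos[0] + dr, s.pos[1] + dc)
            if not layout.in_bounds(target):
                return s
            kind = layout.cell(target)
            if kind == env.ONION_STORE and not s.holding:
                return s._replace(holding=1)
            if kind == env.STOVE and s.holding and target == self.extractor.stove:
                return s._replace(holding=0, pot_nonempty=1)
            if kind == env.BRIDGE:
                if s.holding and not s.bridge_onion:
                    return s._replace(holding=0, bridge_onion=1)
                if not s.holding and s.bridge_onion:
                    return s._replace(holding=1, bridge_onion=0)
        return s

    def _successors(self, s: StateCore, action: str) -> list[tuple[int, float]]:
        base = self._agent_step(s, action)
        pick_opts = ([(True, self.p_bridge_pickup), (False, 1 - self.p_bridge_pickup)]
                     if base.bridge_onion else [(False, 1.0)])
        cons_opts = ([(True, self.p_other_consume), (False, 1 - self.p_other_consume)]
                     if base.other_has_onion else [(False, 1.0)])
        out: dict[int, float] = {}
        for pick, pp in pick_opts:
            for cons, pc in cons_opts:
                bridge = 0 if pick else base.bridge_onion
                other = 1 if pick else (0 if cons else base.other_has_onion)
                nxt = base._replace(bridge_onion=bridge, other_has_onion=other)
                j = self.index[nxt]
                out[j] = out.get(j, 0.0) + pp * pc
        return list(out.items())

    # -- mapping demonstrations into the abstraction ----------------------

    def core_index(self, core: StateCore) -> int:
        return self.index[core]

    def trace_to_indices(self, trace: Trace) -> list[int]:
        out = []
        for state, _ in trace.steps:
            core = core_from_state(state, self.layout)
            out.append(self.index[core])
        return out

    def traces_to_demos(self, traces: Iterable[Trace]) -> list[list[int]]:
        return [self.trace_to_indices(t) for t in traces]
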
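"""Synthetic behavioral cohort: onion-delivering demonstration traces.

No human dataset accompanies the study conditions, so this module emulates
them.  Each synthetic participant plays one Round-1 episode on the left
side of the kitchen against the scripted help-seeking right chef.  A
participant's altruism is summarized by a single *sharing propensity*
pi in [0, 1]: the expected number of onions the participant passes over
the cooperation bridge per soup they deliver.  Propensities are drawn from
a Beta distribution moment-matched to each group's calibration
(mean 0.24, SD 0.28 for the "latino" group; mean 0.14, SD 0.21 for the
"white" group), so a large cohort's group-mean onions-per-soup converges
to the calibrated mean.

Behaviorally, pi is realized as follows: each time a soup goes up to
cook, the participant shares one onion with probability pi during the
cook wait, before collecting and delivering that soup.  Because the
sharing trip strictly precedes the soup's delivery, an episode clock that
cuts the share also cuts the delivery, so the per-participant ratio
shared-onions / delivered-soups is an unbiased realization of pi for
every participant with at least one delivery.

Episode rollouts are segmented into *traces*: a trace starts the moment
the participant has picked up an onion and ends when the onion is dropped
at the bridge (label ``altruistic``) or the participant's own pot (label
``non_altruistic``).  Traces are compacted by removing steps where the
participant did not change position.  The four training datasets are the
altruistic traces, the non-altruistic traces, and the per-group trace
collections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import environment as env
from .environment import (GameConfig, GameState, Layout, scripted_bot)

LABEL_ALTRUISTIC = "altruistic"
LABEL_NON_ALTRUISTIC = "non_altruistic"

GROUPS = ("latino", "white", "fully_altruistic", "fully_selfish")


@dataclass(frozen=True)
class GroupSpec:
    """Calibration of one participant group's sharing-propensity distribution."""
    name: str
    n: int
    mean: float
    sd: float


#: group calibrations used throughout: the study cohort (110 + 190
#: participants) plus the two degenerate reference behaviors
DEFAULT_GROUPS = (
    GroupSpec("latino", 110, 0.24, 0.28),
    GroupSpec("white", 190, 0.14, 0.21),
)
EXTREME_GROUPS = (
    GroupSpec("fully_altruistic", 1, 1.0, 0.0),
    GroupSpec("fully_selfish", 1, 0.0, 0.0),
)


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    #: one 60-second round at ~3 player actions per second; calibrated so a
    #: participant completes ~3 soup cycles (~12 onion traces), matching the
    #: study's per-participant trace volume
    horizon: int = 180
    cook_time: int = 5
    noise: float = 0.01
    #: multiplicative propensity boost emulating behavioral accommodation
    #: after receiving help in an earlier round; the default 1.0 (off)
    #: reproduces the baseline round used for reward learning
    accommodation_boost: float = 1.0
    seed: int = 0

    def game_config(self) -> GameConfig:
        return GameConfig(cook_time=self.cook_time, horizon=self.horizon)


@dataclass
class Trace:
    """One onion-delivering state-action segment of the left chef.

    Each step pairs an action with the state it produced, so the first
    step's state has the onion freshly in hand and the last step's state
    shows the onion deposited (on the bridge or in the pot).
    """
    steps: list[tuple[GameState, str]]
    label: str
    group: str
    participant_id: int

    def __len__(self) -> int:
        return len(self.steps)

    def positions(self) -> list[tuple[int, int]]:
        return [s.agents[0].pos for s, _ in self.steps]


# ---------------------------------------------------------------------------
# Propensity sampling
# ---------------------------------------------------------------------------

def beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta(a, b) for a given mean and SD on [0, 1].

    The variance of a Beta with this mean cannot exceed mean*(1-mean); a
    calibration requesting more spread is clipped to just inside that
    bound with a warning.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1) to moment-match a Beta, got {mean}")
    var = sd * sd
    vmax = mean * (1.0 - mean)
    if var >= vmax:
        warnings.warn(
            f"sd={sd} infeasible for a Beta with mean={mean}; clipping variance "
            f"to {0.98 * vmax:.4f}", stacklevel=2)
        var = 0.98 * vmax
    nu = vmax / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_participant_propensity(group: GroupSpec, rng: np.random.Generator) -> float:
    """Draw one participant's sharing propensity from the group calibration."""
    if group.sd == 0.0 or group.mean in (0.0, 1.0):
        return float(min(1.0, max(0.0, group.mean)))
    a, b = beta_params(group.mean, group.sd)
    return float(rng.beta(a, b))


# ---------------------------------------------------------------------------
# Participant policy
# ---------------------------------------------------------------------------

class ParticipantPolicy:
    """Scripted left chef whose sharing is driven by a propensity.

    Cooks soups in cycles (3 onions -> pot, bowl, deliver).  Each time a
    soup starts cooking the participant flips a pi-coin and, on success,
    uses the cook wait to carry one extra onion to the bridge before
    fetching the bowl.  Because the sharing trip strictly precedes that
    soup's delivery, a share cut off by the clock also cuts the delivery,
    which keeps shared-onions/delivered-soups an unbiased realization of
    pi for every participant with at least one delivery.  With
    probability ``noise`` a planned move is replaced by a random legal
    move (an occasional detour), emulating imperfect human play.
    """

    def __init__(self, layout: Layout, propensity: float,
                 rng: np.random.Generator, noise: float = 0.01):
        if not 0.0 <= propensity <= 1.0:
            raise ValueError(f"propensity must be in [0, 1], got {propensity}")
        self.layout = layout
        self.propensity = propensity
        self.rng = rng
        self.noise = noise
        self.objs = env._side_objects(layout, "left", layout.left_start)
        self.sharing = False        # current onion is destined for the bridge
        self._prev_cooking = False
        self._prev_held = env.NOTHING

    def _planned(self, state: GameState) -> str:
        layout = self.layout
        agent = state.agents[0]
        stove_pos = self.objs[env.STOVE]
        pot = state.stove_at(stove_pos)
        if agent.held == env.SOUP:
            return env._route_action(layout, agent, self.objs[env.DELIVERY], "left")
        if agent.held == env.BOWL:
            if pot.cook_state == env.READY:
                return env._route_action(layout, agent, stove_pos, "left")
            act = env._route_action(layout, agent, stove_pos, "left")
            return env.STAY if act == env.INTERACT else act
        if agent.held == env.ONION:
            if self.sharing:
                if state.bridge_onion:
                    # bridge occupied: wait at its front until the right
                    # chef collects
                    act = env._route_action(layout, agent, layout.bridge, "left")
                    return env.STAY if act == env.INTERACT else act
                return env._route_action(layout, agent, layout.bridge, "left")
            return env._route_action(layout, agent, stove_pos, "left")
        # empty-handed
        pot_full = (pot.onion_count == env.ONIONS_PER_SOUP
                    or pot.cook_state in (env.COOKING, env.READY))
        if pot_full and not self.sharing:
            return env._route_action(layout, agent, self.objs[env.BOWL_STORE], "left")
        return env._route_action(layout, agent, self.objs[env.ONION_STORE], "left")

    def __call__(self, state: GameState) -> str:
        # a soup just went up to cook: decide whether to share during the wait
        cooking = state.stove_at(self.objs[env.STOVE]).cook_state != env.IDLE
        if cooking and not self._prev_cooking:
            self.sharing = bool(self.rng.random() < self.propensity)
        self._prev_cooking = cooking
        held = state.agents[0].held
        if (self.sharing and self._prev_held == env.ONION and held == env.NOTHING
                and env.front_cell(state.agents[0]) == self.layout.bridge):
            # sharing trip completed: the onion was dropped facing the bridge
            self.sharing = False
        self._prev_held = held
        act = self._planned(state)
        if act in env.MOVE_ACTIONS and self.rng.random() < self.noise:
            agent = state.agents[0]
            legal = [m for m in env.MOVE_ACTIONS
                     if self.layout.is_floor(
                         (agent.pos[0] + env.ORIENT_DELTAS[env.MOVE_TO_ORIENT[m]][0],
                          agent.pos[1] + env.ORIENT_DELTAS[env.MOVE_TO_ORIENT[m]][1]))
                     and self.layout.side_of(
                         (agent.pos[0] + env.ORIENT_DELTAS[env.MOVE_TO_ORIENT[m]][0],
                          agent.pos[1] + env.ORIENT_DELTAS[env.MOVE_TO_ORIENT[m]][1])) == "left"]
            if legal:
                act = legal[int(self.rng.integers(len(legal)))]
        return act


# ---------------------------------------------------------------------------
# Trace construction
# ---------------------------------------------------------------------------

def extract_traces(states: Sequence[GameState], actions: Sequence[tuple[str, str]],
                   layout: Layout, group: str, participant_id: int) -> list[Trace]:
    """Segment a rollout into the left chef's onion-delivering traces.

    A trace opens on the tick whose interact picks an onion up from the
    store and closes on the tick whose interact drops it at the bridge or
    the pot; each step stores the post-action state.
    """
    traces: list[Trace] = []
    open_start: int | None = None
    for i, joint in enumerate(actions):
        before, after = states[i], states[i + 1]
        held_b, held_a = before.agents[0].held, after.agents[0].held
        if held_b == env.NOTHING and held_a == env.ONION:
            front = env.front_cell(before.agents[0])
            if layout.in_bounds(front) and layout.cell(front) == env.ONION_STORE:
                open_start = i
            else:
                open_start = None  # picked back up from the bridge: not a new trace
        elif held_b == env.ONION and held_a == env.NOTHING and open_start is not None:
            front = env.front_cell(before.agents[0])
            kind = layout.cell(front) if layout.in_bounds(front) else None
            if kind in (env.BRIDGE, env.STOVE):
                label = LABEL_ALTRUISTIC if kind == env.BRIDGE else LABEL_NON_ALTRUISTIC
                steps = [(states[j + 1], actions[j][0]) for j in range(open_start, i + 1)]
                traces.append(Trace(steps=steps, label=label, group=group,
                                    participant_id=participant_id))
            open_start = None
    return traces


def compact_trace(trace: Trace) -> Trace:
    """Remove steps where the participant did not move.

    Consecutive steps whose states share the agent position collapse to a
    single step keeping the run's last state and last action, so the
    terminal drop-off (same cell as the preceding arrival) survives as the
    deposited state.
    """
    if not trace.steps:
        return Trace(steps=[], label=trace.label, group=trace.group,
                     participant_id=trace.participant_id)
    runs: list[list[tuple[GameState, str]]] = []
    for state, action in trace.steps:
        pos = state.agents[0].pos
        if runs and runs[-1][-1][0].agents[0].pos == pos:
            runs[-1].append((state, action))
        else:
            runs.append([(state, action)])
    steps = [run[-1] for run in runs]
    return Trace(steps=steps, label=trace.label, group=trace.group,
                 participant_id=trace.participant_id)


def onion_start_state(layout: Layout, sharing: bool = False) -> GameState:
    """A state in which the left chef has just picked up an onion."""
    state = env.initial_state(layout)
    store = env._left_object(layout, env.ONION_STORE)
    fronts = layout.adjacent_floors(store, "left")
    pos = fronts[0]
    delta = (store[0] - pos[0], store[1] - pos[1])
    orient = env.MOVE_TO_ORIENT[env.DELTA_TO_MOVE[delta]]
    agents = (env.AgentState(pos=pos, orient=orient, held=env.ONION), state.agents[1])
    return env.GameState(agents=agents, stoves=state.stoves, bridge_onion=False,
                         scores=(0, 0), t=0)


def generate_trace(layout: Layout, propensity: float, rng: np.random.Generator,
                   noise: float = 0.01, config: GameConfig | None = None) -> Trace:
    """One standalone onion-delivering trace.

    With probability ``propensity`` the onion goes to the bridge
    (label ``altruistic``), otherwise into the pot.  The right chef idles,
    so the trace isolates the left chef's decision.
    """
    if not 0.0 <= propensity <= 1.0:
        raise ValueError(f"propensity must be in [0, 1], got {propensity}")
    if not layout.adjacent_floors(layout.bridge, "left"):
        raise env.LayoutError("bridge unreachable from the left kitchen")
    if config is None:
        config = GameConfig(horizon=10_000)
    share = bool(rng.random() < propensity)
    policy = ParticipantPolicy(layout, propensity=1.0 if share else 0.0,
                               rng=rng, noise=noise)
    policy.sharing = share
    state = onion_start_state(layout)
    states = [state]
    acts: list[tuple[str, str]] = []
    while state.agents[0].held == env.ONION and state.t < config.horizon:
        joint = (policy(state), env.STAY)
        state = env.step(state, layout, joint, config)
        acts.append(joint)
        states.append(state)
    # the synthetic start state stands in for the pickup interact
    steps = [(states[0], env.INTERACT)]
    for j, joint in enumerate(acts):
        steps.append((states[j + 1], joint[0]))
        if states[j + 1].agents[0].held == env.NOTHING:
            break
    return Trace(steps=steps,
                 label=LABEL_ALTRUISTIC if share else LABEL_NON_ALTRUISTIC,
                 group="", participant_id=-1)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    datasets: dict[str, list[Trace]]
    manifest: pd.DataFrame
    config: CohortConfig


def simulate_participant(layout: Layout, propensity: float, rng: np.random.Generator,
                         config: CohortConfig, group: str, participant_id: int
                         ) -> tuple[list[Trace], dict]:
    """Roll out one Round-1 episode and extract this participant's traces."""
    effective = min(1.0, propensity * config.accommodation_boost)
    policy = ParticipantPolicy(layout, effective, rng, noise=config.noise)
    bot = lambda s: scripted_bot("right_helpseeker", s, layout)
    states, actions = env.rollout(layout, policy, bot, config.game_config())
    traces = [compact_trace(t) for t in
              extract_traces(states, actions, layout, group, participant_id)]
    shared = sum(t.label == LABEL_ALTRUISTIC for t in traces)
    soups = states[-1].scores[0] // env.SOUP_SCORE
    record = {
        "participant_id": participant_id,
        "group": group,
        "propensity": propensity,
        "onions_shared": shared,
        "soups_delivered": soups,
        "onions_per_soup": shared / soups if soups > 0 else float("nan"),
        "n_traces": len(traces),
        "n_altruistic": shared,
    }
    return traces, record


def generate_cohort(config: CohortConfig = CohortConfig(),
                    layout: Layout | None = None) -> CohortResult:
    """Simulate the full cohort and bin traces into the four datasets.

    Participants who deliver no soup are kept in the manifest but their
    onions-per-soup is undefined (NaN) and excluded from group means.
    Reproducible: the same config (including seed) yields byte-identical
    serialized traces.
    """
    if layout is None:
        layout = env.builtin_layout("original")
    root = np.random.SeedSequence(config.seed)
    datasets: dict[str, list[Trace]] = {LABEL_ALTRUISTIC: [], LABEL_NON_ALTRUISTIC: []}
    records = []
    pid = 0
    for group in config.groups:
        datasets.setdefault(group.name, [])
        children = root.spawn(group.n)
        for k in range(group.n):
            rng = np.random.default_rng(children[k])
            propensity = sample_participant_propensity(group, rng)
            traces, record = simulate_participant(
                layout, propensity, rng, config, group.name, pid)
            records.append(record)
            for t in traces:
                datasets[t.label].append(t)
                datasets[group.name].append(t)
            pid += 1
    manifest = pd.DataFrame.from_records(records)
    return CohortResult(datasets=datasets, manifest=manifest, config=config)


def group_sharing_stats(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean/SD/SE of onions shared per delivered soup.

    Participants with zero delivered soups (undefined ratio) are excluded.
    """
    ok = manifest.dropna(subset=["onions_per_soup"])
    g = ok.groupby("group")["onions_per_soup"]
    out = g.agg(["mean", "std", "count"]).rename(columns={"count": "n"})
    out["se"] = out["std"] / np.sqrt(out["n"])
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def trace_to_dict(trace: Trace) -> dict:
    return {
        "participant_id": trace.participant_id,
        "group": trace.group,
        "label": trace.label,
        "steps": [{"state": env.state_to_dict(s), "action": a} for s, a in trace.steps],
    }


def trace_from_dict(d: dict) -> Trace:
    steps = [(env.dict_to_state(e["state"]), e["action"]) for e in d["steps"]]
    return Trace(steps=steps, label=d["label"], group=d["group"],
                 participant_id=d["participant_id"])


def write_traces_jsonl(path, traces: Iterable[Trace]) -> None:
    with open(path, "w") as fh:
        for t in traces:
            fh.write(json.dumps(trace_to_dict(t), sort_keys=True) + "\n")


def read_traces_jsonl(path) -> list[Trace]:
    with open(path) as fh:
        return [trace_from_dict(json.loads(line)) for line in fh if line.strip()]
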
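"""Two-kitchen cooperative cooking gridworld.

Two chefs, confined to the left and right halves of a kitchen, cook and
deliver onion soups: put three onions in the pot on your stove, wait for
them to cook, collect the soup with a bowl and carry it to the delivery
cell.  Each delivered soup is worth 10 points.  A single "cooperation
bridge" cell in the dividing wall lets the left chef pass an onion to the
right chef, whose kitchen is laid out so that fetching onions takes much
longer.  Sharing an onion is therefore an altruistic act: it costs the
helper time that could have gone into cooking their own soups.

The module is deterministic: identical ``(state, actions)`` pairs always
produce identical successors, which makes rollouts reproducible and lets
demonstration traces be regenerated byte-for-byte from a seed.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Callable, Mapping, Sequence

Coord = tuple[int, int]

# Cell kinds
WALL = "wall"
FLOOR = "floor"
ONION_STORE = "onion_store"
STOVE = "stove"
BOWL_STORE = "bowl_store"
DELIVERY = "delivery"
BRIDGE = "bridge"

CHAR_TO_CELL = {
    "X": WALL,
    ".": FLOOR,
    "O": ONION_STORE,
    "P": STOVE,
    "B": BOWL_STORE,
    "D": DELIVERY,
    "G": BRIDGE,
    "1": FLOOR,  # left start cell
    "2": FLOOR,  # right start cell
}

# Held items
NOTHING = "nothing"
ONION = "onion"
BOWL = "bowl"
SOUP = "soup"

# Actions
UP, DOWN, LEFT, RIGHT, STAY, INTERACT = "up", "down", "left", "right", "stay", "interact"
ACTIONS = (UP, DOWN, LEFT, RIGHT, STAY, INTERACT)
MOVE_ACTIONS = (UP, DOWN, LEFT, RIGHT)

ORIENTATIONS = ("N", "E", "S", "W")
ORIENT_DELTAS = {"N": (-1, 0), "E": (0, 1), "S": (1, 0), "W": (0, -1)}
MOVE_TO_ORIENT = {UP: "N", RIGHT: "E", DOWN: "S", LEFT: "W"}
DELTA_TO_MOVE = {(-1, 0): UP, (1, 0): DOWN, (0, -1): LEFT, (0, 1): RIGHT}

# Cook state
IDLE, COOKING, READY = "idle", "cooking", "ready"

#: sentinel returned by :func:`shortest_path_steps` for disconnected cells
UNREACHABLE = float("inf")

SOUP_SCORE = 10
ONIONS_PER_SOUP = 3

BUILTIN_LAYOUTS = (
    "original", "v1", "v2", "v3", "v4", "v5", "v6",
)


class LayoutError(ValueError):
    """Raised for malformed or invalid kitchen layouts."""


class EpisodeOver(RuntimeError):
    """Raised when :func:`step` is called past the episode horizon."""


@dataclass(frozen=True)
class Layout:
    """Static kitchen map.

    ``grid[r][c]`` is a cell kind; ``side_boundary`` is the column index of
    the dividing wall that holds the single bridge cell.  Columns strictly
    left of the boundary belong to the left kitchen, columns strictly right
    of it to the right kitchen.
    """

    name: str
    grid: tuple[tuple[str, ...], ...]
    left_start: Coord
    right_start: Coord
    side_boundary: int

    # -- geometry helpers -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.grid)

    @property
    def n_cols(self) -> int:
        return len(self.grid[0])

    def cell(self, pos: Coord) -> str:
        r, c = pos
        return self.grid[r][c]

    def in_bounds(self, pos: Coord) -> bool:
        r, c = pos
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def side_of(self, pos: Coord) -> str:
        c = pos[1]
        if c < self.side_boundary:
            return "left"
        if c > self.side_boundary:
            return "right"
        return "boundary"

    def cells_of_kind(self, kind: str, side: str | None = None) -> tuple[Coord, ...]:
        out = []
        for r, row in enumerate(self.grid):
            for c, k in enumerate(row):
                if k == kind and (side is None or self.side_of((r, c)) == side):
                    out.append((r, c))
        return tuple(out)

    @property
    def bridge(self) -> Coord:
        return self.cells_of_kind(BRIDGE)[0]

    def floor_cells(self, side: str | None = None) -> tuple[Coord, ...]:
        return self.cells_of_kind(FLOOR, side)

    def is_floor(self, pos: Coord) -> bool:
        return self.in_bounds(pos) and self.cell(pos) == FLOOR

    def adjacent_floors(self, pos: Coord, side: str | None = None) -> tuple[Coord, ...]:
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            q = (pos[0] + dr, pos[1] + dc)
            if self.is_floor(q) and (side is None or self.side_of(q) == side):
                out.append(q)
        return tuple(sorted(out))


def load_layout(text: str, name: str = "layout") -> Layout:
    """Parse an ASCII kitchen grid into a validated :class:`Layout`.

    Legend: ``X`` wall/counter, ``.`` floor, ``O`` onion store, ``P`` stove
    (pot), ``B`` bowl store, ``D`` delivery, ``G`` cooperation bridge,
    ``1``/``2`` start cells of the left and right chef.
    """
    lines = [ln for ln in (l.rstrip("\n") for l in text.splitlines()) if ln.strip()]
    if not lines:
        raise LayoutError("empty layout text")
    width = len(lines[0])
    rows: list[tuple[str, ...]] = []
    left_start = right_start = None
    for r, ln in enumerate(lines):
        if len(ln) != width:
            raise LayoutError(f"row {r} has length {len(ln)}, expected {width}: {ln!r}")
        row = []
        for c, ch in enumerate(ln):
            if ch not in CHAR_TO_CELL:
                raise LayoutError(f"row {r}: unknown legend character {ch!r}")
            row.append(CHAR_TO_CELL[ch])
            if ch == "1":
                if left_start is not None:
                    raise LayoutError("multiple left start cells")
                left_start = (r, c)
            elif ch == "2":
                if right_start is not None:
                    raise LayoutError("multiple right start cells")
                right_start = (r, c)
        rows.append(tuple(row))
    if left_start is None or right_start is None:
        raise LayoutError("layout must contain exactly one '1' and one '2' start cell")

    grid = tuple(rows)
    bridges = [(r, c) for r, row in enumerate(grid) for c, k in enumerate(row) if k == BRIDGE]
    if len(bridges) != 1:
        raise LayoutError(f"layout must contain exactly one bridge cell, found {len(bridges)}")
    boundary = bridges[0][1]

    layout = Layout(name=name, grid=grid, left_start=left_start,
                    right_start=right_start, side_boundary=boundary)
    _validate(layout)
    return layout


def _validate(layout: Layout) -> None:
    # the dividing column is solid wall except for the bridge
    for r in range(layout.n_rows):
        kind = layout.grid[r][layout.side_boundary]
        if kind not in (WALL, BRIDGE):
            raise LayoutError(
                f"dividing column {layout.side_boundary} must be wall except the "
                f"bridge; found {kind} at row {r}")
    for side, start in (("left", layout.left_start), ("right", layout.right_start)):
        if layout.cell(start) != FLOOR or layout.side_of(start) != side:
            raise LayoutError(f"{side} start cell must be a floor cell on its own side")
        for kind in (ONION_STORE, STOVE, BOWL_STORE, DELIVERY):
            if not layout.cells_of_kind(kind, side):
                raise LayoutError(f"{side} kitchen lacks a {kind} cell")
        # bridge must be reachable (the start can walk to a cell facing it)
        fronts = layout.adjacent_floors(layout.bridge, side)
        if not fronts or all(
                shortest_path_steps(layout, start, f) is UNREACHABLE for f in fronts):
            raise LayoutError(f"bridge unreachable from the {side} kitchen")
        for kind in (ONION_STORE, STOVE, BOWL_STORE, DELIVERY):
            for pos in layout.cells_of_kind(kind, side):
                if not layout.adjacent_floors(pos, side):
                    raise LayoutError(f"{kind} at {pos} has no adjacent floor on side {side}")


def builtin_layout(name: str) -> Layout:
    """Load one of the seven shipped layouts (``original``, ``v1`` .. ``v6``)."""
    if name not in BUILTIN_LAYOUTS:
        raise LayoutError(f"unknown builtin layout {name!r}; choose from {BUILTIN_LAYOUTS}")
    text = resources.files("attune.layouts").joinpath(f"layout_{name}.txt").read_text()
    return load_layout(text, name=name)


# ---------------------------------------------------------------------------
# Path finding
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _dist_map(layout: Layout, sources: tuple[Coord, ...]) -> Mapping[Coord, int]:
    """Multi-source BFS distances over floor cells (4-neighborhood)."""
    dist: dict[Coord, int] = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        pos = queue.popleft()
        d = dist[pos]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            q = (pos[0] + dr, pos[1] + dc)
            if layout.is_floor(q) and q not in dist:
                dist[q] = d + 1
                queue.append(q)
    return dist


def shortest_path_steps(layout: Layout, frm: Coord, to: Coord) -> float:
    """Minimum number of move actions between two floor cells.

    Returns :data:`UNREACHABLE` when no floor path connects them.
    """
    for pos in (frm, to):
        if not layout.is_floor(pos):
            raise ValueError(f"{pos} is not a floor cell")
    return _dist_map(layout, (to,)).get(frm, UNREACHABLE)


def shortest_path_cells(layout: Layout, frm: Coord, to: Coord) -> tuple[Coord, ...]:
    """The lexicographically-smallest shortest floor path, endpoints included."""
    dist = _dist_map(layout, (to,))
    if frm not in dist:
        raise ValueError(f"no path from {frm} to {to}")
    path = [frm]
    pos = frm
    while pos != to:
        nxt = min(q for q in layout.adjacent_floors(pos) if dist.get(q, UNREACHABLE) == dist[pos] - 1)
        path.append(nxt)
        pos = nxt
    return tuple(path)


def steps_between_objects(layout: Layout, obj_a: Coord, obj_b: Coord,
                          side: str | None = None) -> float:
    """BFS moves between the closest floor cells facing two (non-floor) objects."""
    best = UNREACHABLE
    for fa in layout.adjacent_floors(obj_a, side):
        for fb in layout.adjacent_floors(obj_b, side):
            best = min(best, shortest_path_steps(layout, fa, fb))
    return best


def share_and_cook_steps(layout: Layout) -> tuple[float, float]:
    """Left chef's path lengths (store front -> bridge front, store front -> stove front).

    The ratio of these two distances is what the spatial layout variants
    manipulate: sharing is cheap when the first number is small relative to
    the second.
    """
    store = _left_object(layout, ONION_STORE)
    stove = _left_object(layout, STOVE)
    share = steps_between_objects(layout, store, layout.bridge, "left")
    cook = steps_between_objects(layout, store, stove, "left")
    return share, cook


def _left_object(layout: Layout, kind: str) -> Coord:
    """The left kitchen's instance of a cell kind (nearest to the left start)."""
    cells = layout.cells_of_kind(kind, "left")
    if not cells:
        raise LayoutError(f"no {kind} in the left kitchen")
    start = layout.left_start

    def key(pos: Coord):
        fronts = layout.adjacent_floors(pos, "left")
        d = min((shortest_path_steps(layout, start, f) for f in fronts), default=UNREACHABLE)
        return (d, pos)

    return min(cells, key=key)


# ---------------------------------------------------------------------------
# Game state and dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentState:
    pos: Coord
    orient: str
    held: str = NOTHING


@dataclass(frozen=True)
class StoveState:
    onion_count: int = 0
    cook_state: str = IDLE
    timer: int = 0


@dataclass(frozen=True)
class GameConfig:
    """Tunable rules: cooking takes `cook_time` steps; an episode lasts
    `horizon` steps (one action per second of the 60-second round)."""
    cook_time: int = 5
    horizon: int = 60


@dataclass(frozen=True)
class GameState:
    """Dynamic state of the two-chef kitchen; hashable and immutable."""
    agents: tuple[AgentState, AgentState]
    stoves: tuple[tuple[Coord, StoveState], ...]
    bridge_onion: bool
    scores: tuple[int, int]
    t: int
    help_flag: bool = False

    def stove_at(self, pos: Coord) -> StoveState:
        for p, st in self.stoves:
            if p == pos:
                return st
        raise KeyError(f"no stove at {pos}")


def initial_state(layout: Layout) -> GameState:
    agents = []
    for idx, (start, side) in enumerate(
            ((layout.left_start, "left"), (layout.right_start, "right"))):
        orient = "S"
        for o, (dr, dc) in ORIENT_DELTAS.items():
            q = (start[0] + dr, start[1] + dc)
            if layout.in_bounds(q) and layout.cell(q) == STOVE:
                orient = o  # face the stove when starting next to it
                break
        agents.append(AgentState(pos=start, orient=orient))
    stoves = tuple((pos, StoveState()) for pos in sorted(layout.cells_of_kind(STOVE)))
    return GameState(agents=(agents[0], agents[1]), stoves=stoves,
                     bridge_onion=False, scores=(0, 0), t=0)


def front_cell(agent: AgentState) -> Coord:
    dr, dc = ORIENT_DELTAS[agent.orient]
    return (agent.pos[0] + dr, agent.pos[1] + dc)


def step(state: GameState, layout: Layout,
         actions: Sequence[str], config: GameConfig = GameConfig()) -> GameState:
    """Advance the kitchen by one tick given one action per chef.

    Interactions are resolved left chef first (the only shared resource is
    the bridge, so this rule makes simultaneous bridge conflicts
    deterministic).  Item flows are conserved except at the infinite stores
    and the delivery cell.
    """
    if state.t >= config.horizon:
        raise EpisodeOver(f"episode horizon {config.horizon} reached at t={state.t}")
    if len(actions) != 2:
        raise ValueError("exactly one action per chef required")
    for a in actions:
        if a not in ACTIONS:
            raise ValueError(f"invalid action {a!r}; choose from {ACTIONS}")

    stoves = {pos: st for pos, st in state.stoves}
    # cooking progresses at the start of the tick so a pot that begins
    # cooking this tick waits the full cook_time
    for pos, st in stoves.items():
        if st.cook_state == COOKING:
            timer = st.timer - 1
            if timer <= 0:
                stoves[pos] = StoveState(onion_count=st.onion_count, cook_state=READY, timer=0)
            else:
                stoves[pos] = replace(st, timer=timer)

    agents = list(state.agents)
    scores = list(state.scores)
    bridge_onion = state.bridge_onion
    help_flag = False
    sides = ("left", "right")

    for idx in (0, 1):
        agent = agents[idx]
        action = actions[idx]
        if action == STAY:
            continue
        if action in MOVE_ACTIONS:
            orient = MOVE_TO_ORIENT[action]
            dr, dc = ORIENT_DELTAS[orient]
            target = (agent.pos[0] + dr, agent.pos[1] + dc)
            other = agents[1 - idx]
            blocked = (not layout.is_floor(target)
                       or layout.side_of(target) != sides[idx]
                       or target == other.pos)
            new_pos = agent.pos if blocked else target
            agent = replace(agent, pos=new_pos, orient=orient)
            agents[idx] = agent
            # the right chef "calls for help" whenever it moves past the
            # bridge empty-handed
            if idx == 1 and agent.held == NOTHING and not blocked:
                br, bc = layout.bridge
                if abs(agent.pos[0] - br) + abs(agent.pos[1] - bc) == 1:
                    help_flag = True
            continue
        # interact
        target = front_cell(agent)
        if not layout.in_bounds(target):
            continue
        kind = layout.cell(target)
        held = agent.held
        if kind == ONION_STORE and held == NOTHING:
            agents[idx] = replace(agent, held=ONION)
        elif kind == BOWL_STORE and held == NOTHING:
            agents[idx] = replace(agent, held=BOWL)
        elif kind == STOVE:
            st = stoves[target]
            if held == ONION and st.cook_state == IDLE and st.onion_count < ONIONS_PER_SOUP:
                count = st.onion_count + 1
                if count == ONIONS_PER_SOUP:
                    stoves[target] = StoveState(onion_count=count, cook_state=COOKING,
                                                timer=config.cook_time)
                else:
                    stoves[target] = StoveState(onion_count=count)
                agents[idx] = replace(agent, held=NOTHING)
            elif held == BOWL and st.cook_state == READY:
                stoves[target] = StoveState()
                agents[idx] = replace(agent, held=SOUP)
        elif kind == DELIVERY and held == SOUP:
            scores[idx] += SOUP_SCORE
            agents[idx] = replace(agent, held=NOTHING)
        elif kind == BRIDGE:
            if held == ONION and not bridge_onion:
                bridge_onion = True
                agents[idx] = replace(agent, held=NOTHING)
            elif held == NOTHING and bridge_onion:
                bridge_onion = False
                agents[idx] = replace(agent, held=ONION)

    return GameState(agents=(agents[0], agents[1]),
                     stoves=tuple(sorted(stoves.items())),
                     bridge_onion=bridge_onion,
                     scores=(scores[0], scores[1]),
                     t=state.t + 1,
                     help_flag=help_flag)


# ---------------------------------------------------------------------------
# Scripted bot policies
# ---------------------------------------------------------------------------

BOT_ROLES = ("right_helpseeker", "left_altruistic", "left_selfish")


def _route_action(layout: Layout, agent: AgentState, target: Coord, side: str) -> str:
    """Move toward (and finally interact with) a non-floor target cell."""
    fronts = layout.adjacent_floors(target, side)
    if not fronts:
        return STAY
    if agent.pos in fronts:
        delta = (target[0] - agent.pos[0], target[1] - agent.pos[1])
        move = DELTA_TO_MOVE[delta]
        if MOVE_TO_ORIENT[move] == agent.orient:
            return INTERACT
        return move  # turn in place: the target cell is not walkable
    dist = _dist_map(layout, tuple(sorted(fronts)))
    here = dist.get(agent.pos)
    if here is None:
        return STAY
    candidates = [q for q in layout.adjacent_floors(agent.pos, side)
                  if dist.get(q, UNREACHABLE) == here - 1]
    if not candidates:
        return STAY
    nxt = min(candidates)
    return DELTA_TO_MOVE[(nxt[0] - agent.pos[0], nxt[1] - agent.pos[1])]


def _move_toward_cell(layout: Layout, agent: AgentState, goal: Coord, side: str) -> str:
    if agent.pos == goal:
        return STAY
    dist = _dist_map(layout, (goal,))
    here = dist.get(agent.pos)
    if here is None:
        return STAY
    candidates = [q for q in layout.adjacent_floors(agent.pos, side)
                  if dist.get(q, UNREACHABLE) == here - 1]
    if not candidates:
        return STAY
    nxt = min(candidates)
    return DELTA_TO_MOVE[(nxt[0] - agent.pos[0], nxt[1] - agent.pos[1])]


def _side_objects(layout: Layout, side: str, start: Coord):
    def nearest(kind: str) -> Coord:
        cells = layout.cells_of_kind(kind, side)

        def key(pos: Coord):
            fronts = layout.adjacent_floors(pos, side)
            d = min((shortest_path_steps(layout, start, f) for f in fronts),
                    default=UNREACHABLE)
            return (d, pos)

        return min(cells, key=key)

    return {kind: nearest(kind) for kind in (ONION_STORE, STOVE, BOWL_STORE, DELIVERY)}


def scripted_bot(role: str, state: GameState, layout: Layout) -> str:
    """Deterministic policy of one of the three scripted chefs.

    * ``right_helpseeker`` cooks greedily, collects a bridge onion when one
      is waiting, and routes to its distant onion store via the bridge
      front (the environment raises the help flag on those empty-handed
      passes).
    * ``left_altruistic`` puts an onion on the bridge whenever the bridge
      is free, otherwise cooks.
    * ``left_selfish`` only ever cooks.
    """
    if role not in BOT_ROLES:
        raise ValueError(f"unknown bot role {role!r}; choose from {BOT_ROLES}")
    idx = 1 if role == "right_helpseeker" else 0
    side = "right" if idx == 1 else "left"
    agent = state.agents[idx]
    start = layout.right_start if idx == 1 else layout.left_start
    objs = _side_objects(layout, side, start)
    stove_pos = objs[STOVE]
    pot = state.stove_at(stove_pos)

    if agent.held == SOUP:
        return _route_action(layout, agent, objs[DELIVERY], side)
    if agent.held == BOWL:
        if pot.cook_state == READY:
            return _route_action(layout, agent, stove_pos, side)
        if pot.cook_state == COOKING:
            act = _route_action(layout, agent, stove_pos, side)
            return STAY if act == INTERACT else act
        return STAY  # holding a bowl with an empty pot: wait (should not occur)
    if agent.held == ONION:
        # the altruistic chef alternates: feed its own pot first, then give
        # the next onion away whenever the bridge is free
        if (role == "left_altruistic" and not state.bridge_onion
                and pot.onion_count >= 1 and pot.cook_state == IDLE):
            return _route_action(layout, agent, layout.bridge, side)
        if pot.cook_state == IDLE and pot.onion_count < ONIONS_PER_SOUP:
            return _route_action(layout, agent, stove_pos, side)
        act = _route_action(layout, agent, stove_pos, side)
        return STAY if act == INTERACT else act
    # empty-handed
    pot_full = pot.onion_count == ONIONS_PER_SOUP or pot.cook_state in (COOKING, READY)
    if pot_full:
        return _route_action(layout, agent, objs[BOWL_STORE], side)
    if idx == 1 and state.bridge_onion:
        return _route_action(layout, agent, layout.bridge, side)
    store = objs[ONION_STORE]
    if idx == 1:
        # head to the store via the bridge front while still on the far side
        bridge_fronts = layout.adjacent_floors(layout.bridge, side)
        store_fronts = layout.adjacent_floors(store, side)
        d_store = _dist_map(layout, tuple(sorted(store_fronts)))
        here = d_store.get(agent.pos, UNREACHABLE)
        via = min((d_store.get(f, UNREACHABLE) for f in bridge_fronts), default=UNREACHABLE)
        if here > via:
            goal = min(f for f in bridge_fronts if d_store.get(f, UNREACHABLE) == via)
            act = _move_toward_cell(layout, agent, goal, side)
            if act != STAY:
                return act
    return _route_action(layout, agent, store, side)


# ---------------------------------------------------------------------------
# Rollouts and serialization
# ---------------------------------------------------------------------------

Policy = Callable[[GameState], str]


def rollout(layout: Layout, left_policy: Policy, right_policy: Policy,
            config: GameConfig = GameConfig(),
            state: GameState | None = None) -> tuple[list[GameState], list[tuple[str, str]]]:
    """Run an episode to the horizon; returns states ``s_0..s_T`` and the
    joint actions taken at each of the ``T`` ticks."""
    if state is None:
        state = initial_state(layout)
    states = [state]
    actions: list[tuple[str, str]] = []
    while state.t < config.horizon:
        joint = (left_policy(state), right_policy(state))
        state = step(state, layout, joint, config)
        actions.append(joint)
        states.append(state)
    return states, actions


def state_to_dict(state: GameState) -> dict:
    return {
        "t": state.t,
        "positions": [list(a.pos) for a in state.agents],
        "orientations": [a.orient for a in state.agents],
        "held": [a.held for a in state.agents],
        "pot": [{"pos": list(pos), "onion_count": st.onion_count,
                 "cook_state": st.cook_state, "timer": st.timer}
                for pos, st in state.stoves],
        "bridge": state.bridge_onion,
        "scores": list(state.scores),
        "help_flag": state.help_flag,
    }


def dict_to_state(d: dict) -> GameState:
    agents = tuple(
        AgentState(pos=tuple(p), orient=o, held=h)
        for p, o, h in zip(d["positions"], d["orientations"], d["held"]))
    stoves = tuple(sorted(
        (tuple(e["pos"]),
         StoveState(onion_count=e["onion_count"], cook_state=e["cook_state"],
                    timer=e["timer"]))
        for e in d["pot"]))
    return GameState(agents=agents, stoves=stoves, bridge_onion=d["bridge"],
                     scores=tuple(d["scores"]), t=d["t"],
                     help_flag=d.get("help_flag", False))


def write_rollout_jsonl(path, states: Sequence[GameState],
                        actions: Sequence[tuple[str, str]]) -> None:
    """One step per line: the state at t plus the joint action taken at t."""
    with open(path, "w") as fh:
        for i, state in enumerate(states):
            rec = state_to_dict(state)
            rec["actions"] = list(actions[i]) if i < len(actions) else None
            fh.write(json.dumps(rec) + "\n")
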
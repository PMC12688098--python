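"""Hand-designed 18-dimensional feature vector for the left (learning) chef.

The reward network never sees raw game states; it sees this compact,
interpretable encoding:

====================================================  ====
agent position relative to the onion store (dr, dc)     2
agent position relative to the bridge (dr, dc)          2
agent position relative to the stove (dr, dc)           2
agent orientation (one-hot N/E/S/W)                     4
agent on the store-front -> stove-front shortest path
while holding an onion (one-hot over 4 path cells)      4
onion on bridge                                         1
onions in pot (pot non-empty)                           1
agent has onion                                         1
other agent has onion                                   1
====================================================  ====

Relative positions use the sign convention ``object - agent`` in
(row, col), rows increasing downward from the top-left origin.  The path
one-hot is all zeros whenever the agent is off the path or empty-handed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import environment as env
from .environment import Coord, GameState, Layout

N_FEATURES = 18
N_PATH_SLOTS = 4

FEATURE_NAMES = (
    "rel_onion_store_dr", "rel_onion_store_dc",
    "rel_bridge_dr", "rel_bridge_dc",
    "rel_stove_dr", "rel_stove_dc",
    "orient_N", "orient_E", "orient_S", "orient_W",
    "path_0", "path_1", "path_2", "path_3",
    "onion_on_bridge", "onions_in_pot", "agent_has_onion", "other_agent_has_onion",
)

#: the Table-3 style binary flags, addressable by name for attribution
BINARY_FEATURES = {
    "onion_on_bridge": 14,
    "onions_in_pot": 15,
    "agent_has_onion": 16,
    "other_agent_has_onion": 17,
}


class StateCore(NamedTuple):
    """The left chef's factored view of the game used by features and IRL.

    ``holding`` is 1 when the chef carries an onion.  Everything else a
    game state contains (the right chef's exact position, bowl/soup
    carrying, timers, scores) is irrelevant to the reward features.
    """

    pos: Coord
    orient: str
    holding: int
    pot_nonempty: int
    bridge_onion: int
    other_has_onion: int


def core_from_state(state: GameState, layout: Layout) -> StateCore:
    agent, other = state.agents
    stove_pos = env._left_object(layout, env.STOVE)
    pot = state.stove_at(stove_pos)
    return StateCore(
        pos=agent.pos,
        orient=agent.orient,
        holding=int(agent.held == env.ONION),
        pot_nonempty=int(pot.onion_count > 0 or pot.cook_state != env.IDLE),
        bridge_onion=int(state.bridge_onion),
        other_has_onion=int(other.held == env.ONION),
    )


@dataclass(frozen=True)
class FeatureExtractor:
    """Maps game states of one layout to the 18-vector.

    Construction fails with :class:`~attune.environment.LayoutError` if the
    layout lacks an onion store, stove or bridge for the left chef.  The
    store-front -> stove-front path is fixed per layout as the
    lexicographically smallest (row-major) shortest path, so extraction is
    a pure function of ``(state, layout)``.
    """

    layout: Layout
    onion_store: Coord
    stove: Coord
    bridge: Coord
    path_cells: tuple[Coord, ...]

    @classmethod
    def for_layout(cls, layout: Layout) -> "FeatureExtractor":
        store = env._left_object(layout, env.ONION_STORE)
        stove = env._left_object(layout, env.STOVE)
        bridge = layout.bridge
        store_fronts = layout.adjacent_floors(store, "left")
        stove_fronts = layout.adjacent_floors(stove, "left")
        if not store_fronts or not stove_fronts:
            raise env.LayoutError("onion store or stove unreachable in the left kitchen")
        best = None
        for fa in store_fronts:
            for fb in stove_fronts:
                d = env.shortest_path_steps(layout, fa, fb)
                if d is not env.UNREACHABLE and (best is None or (d, fa, fb) < best):
                    best = (d, fa, fb)
        if best is None:
            raise env.LayoutError("no path between store front and stove front")
        _, fa, fb = best
        path = env.shortest_path_cells(layout, fa, fb)
        return cls(layout=layout, onion_store=store, stove=stove, bridge=bridge,
                   path_cells=path)

    def extract_core(self, core: StateCore) -> np.ndarray:
        f = np.zeros(N_FEATURES)
        r, c = core.pos
        f[0] = self.onion_store[0] - r
        f[1] = self.onion_store[1] - c
        f[2] = self.bridge[0] - r
        f[3] = self.bridge[1] - c
        f[4] = self.stove[0] - r
        f[5] = self.stove[1] - c
        f[6 + env.ORIENTATIONS.index(core.orient)] = 1.0
        if core.holding and core.pos in self.path_cells:
            slot = min(self.path_cells.index(core.pos), N_PATH_SLOTS - 1)
            f[10 + slot] = 1.0
        f[14] = core.bridge_onion
        f[15] = core.pot_nonempty
        f[16] = core.holding
        f[17] = core.other_has_onion
        return f

    def extract(self, state: GameState) -> np.ndarray:
        return self.extract_core(core_from_state(state, self.layout))


def extract_features(state: GameState, layout: Layout) -> np.ndarray:
    """Convenience one-shot extraction (builds the extractor each call)."""
    return FeatureExtractor.for_layout(layout).extract(state)
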
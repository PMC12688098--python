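"""Kitchen gridworld: layouts, dynamics, path finding, scripted chefs."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path as csgraph_shortest_path

from attune import environment as env

SIMPLE = """\
XXPXXXXXXXPXX
X.1..X....2.X
X....X......B
O....G......X
B....X.XXXXXX
X....X......X
XDXXXXXXXOXDX
"""


def scipy_bfs_steps(layout, frm, to):
    """Independent shortest-path oracle via scipy's csgraph."""
    cells = sorted(layout.floor_cells())
    idx = {c: i for i, c in enumerate(cells)}
    rows, cols = [], []
    for c in cells:
        for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            q = (c[0] + d[0], c[1] + d[1])
            if q in idx:
                rows.append(idx[c])
                cols.append(idx[q])
    g = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(cells),) * 2)
    dist = csgraph_shortest_path(g, unweighted=True, indices=idx[frm])
    return dist[idx[to]]


# ---------------------------------------------------------------------------
# Layout loading and validation
# ---------------------------------------------------------------------------

class TestLayout:
    def test_original_has_single_bridge_and_required_cells(self):
        lay = env.load_layout(SIMPLE, "simple")
        assert len(lay.cells_of_kind(env.BRIDGE)) == 1
        for side in ("left", "right"):
            for kind in (env.ONION_STORE, env.STOVE, env.BOWL_STORE, env.DELIVERY):
                assert lay.cells_of_kind(kind, side), f"{side} missing {kind}"
            start = lay.left_start if side == "left" else lay.right_start
            assert lay.cell(start) == env.FLOOR and lay.side_of(start) == side

    def test_two_bridges_rejected(self):
        bad = SIMPLE.replace("O....G......X", "O.G..G......X")
        with pytest.raises(env.LayoutError):
            env.load_layout(bad)

    def test_missing_cell_kind_rejected(self):
        bad = SIMPLE.replace("B....X.XXXXXX", "X....X.XXXXXX")  # drop left bowl store
        with pytest.raises(env.LayoutError, match="bowl_store"):
            env.load_layout(bad)

    def test_ragged_grid_names_offending_row(self):
        bad = "XXX\nXX\nXXX"
        with pytest.raises(env.LayoutError, match="row 1"):
            env.load_layout(bad)

    def test_unknown_character_rejected(self):
        with pytest.raises(env.LayoutError, match="legend"):
            env.load_layout(SIMPLE.replace("O", "Q", 1))

    def test_original_left_store_closer_to_stove_than_right(self, original):
        left = env.steps_between_objects(
            original, env._left_object(original, env.ONION_STORE),
            env._left_object(original, env.STOVE), "left")
        rs = original.cells_of_kind(env.ONION_STORE, "right")[0]
        rp = original.cells_of_kind(env.STOVE, "right")[0]
        right = env.steps_between_objects(original, rs, rp, "right")
        assert left < right

    @pytest.mark.parametrize("name,relation", [
        ("v1", "lt"), ("v2", "lt"), ("v3", "lt"),
        ("v4", "gt"), ("v5", "gt"), ("v6", "eq"),
    ])
    def test_variant_share_vs_cook_path_relations(self, name, relation):
        share, cook = env.share_and_cook_steps(env.builtin_layout(name))
        if relation == "lt":
            assert share < cook
        elif relation == "gt":
            assert share > cook
        else:
            assert abs(share - cook) <= 1

    def test_all_builtin_layouts_load_and_validate(self, all_layouts):
        for name, lay in all_layouts.items():
            assert len(lay.cells_of_kind(env.BRIDGE)) == 1
            assert lay.adjacent_floors(lay.bridge, "left")
            assert lay.adjacent_floors(lay.bridge, "right")


# ---------------------------------------------------------------------------
# Path finding
# ---------------------------------------------------------------------------

class TestShortestPath:
    def test_adjacent_cells_one_step(self, original):
        assert env.shortest_path_steps(original, (1, 1), (1, 2)) == 1

    def test_same_cell_zero_steps(self, original):
        assert env.shortest_path_steps(original, (3, 1), (3, 1)) == 0

    def test_matches_independent_scipy_oracle(self, original):
        cells = sorted(original.floor_cells("left"))
        for frm in cells[::3]:
            for to in cells[::4]:
                assert env.shortest_path_steps(original, frm, to) == \
                    scipy_bfs_steps(original, frm, to)

    def test_non_floor_cell_rejected(self, original):
        with pytest.raises(ValueError):
            env.shortest_path_steps(original, (0, 0), (1, 1))

    def test_path_cells_are_a_shortest_path(self, original):
        path = env.shortest_path_cells(original, (3, 1), (1, 2))
        assert path[0] == (3, 1) and path[-1] == (1, 2)
        assert len(path) == env.shortest_path_steps(original, (3, 1), (1, 2)) + 1
        for a, b in zip(path, path[1:]):
            assert abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1


# ---------------------------------------------------------------------------
# Game dynamics
# ---------------------------------------------------------------------------

def agent_at(state, idx, **kw):
    agents = list(state.agents)
    agents[idx] = env.AgentState(**{**agents[idx].__dict__, **kw})
    return env.GameState(agents=tuple(agents), stoves=state.stoves,
                         bridge_onion=state.bridge_onion, scores=state.scores,
                         t=state.t, help_flag=state.help_flag)


class TestStep:
    def test_move_into_wall_turns_in_place(self, original):
        s0 = env.initial_state(original)
        s1 = env.step(s0, original, (env.LEFT, env.STAY))
        s2 = env.step(s1, original, (env.LEFT, env.STAY))
        assert s2.agents[0].pos[1] == s1.agents[0].pos[1] - 1 or \
            s2.agents[0].pos == s1.agents[0].pos
        blocked = env.step(s0, original, (env.UP, env.STAY))  # stove above start
        assert blocked.agents[0].pos == s0.agents[0].pos
        assert blocked.agents[0].orient == "N"

    def test_third_onion_starts_cooking(self, original):
        stove_pos = env._left_object(original, env.STOVE)
        s = env.initial_state(original)
        s = agent_at(s, 0, pos=(1, 2), orient="N", held=env.ONION)
        for expect_count in (1, 2):
            s = env.step(s, original, (env.INTERACT, env.STAY))
            assert s.stove_at(stove_pos).onion_count == expect_count
            assert s.stove_at(stove_pos).cook_state == env.IDLE
            s = agent_at(s, 0, held=env.ONION)
        s = env.step(s, original, (env.INTERACT, env.STAY))
        assert s.stove_at(stove_pos).onion_count == 3
        assert s.stove_at(stove_pos).cook_state == env.COOKING
        assert s.agents[0].held == env.NOTHING

    def test_cooking_completes_after_cook_time(self, original):
        config = env.GameConfig(cook_time=3)
        stove_pos = env._left_object(original, env.STOVE)
        s = env.initial_state(original)
        s = agent_at(s, 0, pos=(1, 2), orient="N", held=env.ONION)
        for _ in range(3):
            s = agent_at(s, 0, held=env.ONION)
            s = env.step(s, original, (env.INTERACT, env.STAY), config)
        assert s.stove_at(stove_pos).cook_state == env.COOKING
        for _ in range(3):
            assert s.stove_at(stove_pos).cook_state != env.READY
            s = env.step(s, original, (env.STAY, env.STAY), config)
        assert s.stove_at(stove_pos).cook_state == env.READY

    def test_soup_collection_and_delivery_scores_ten(self, original):
        stove_pos = env._left_object(original, env.STOVE)
        s = env.initial_state(original)
        stoves = tuple((p, env.StoveState(3, env.READY, 0) if p == stove_pos else st)
                       for p, st in s.stoves)
        s = env.GameState(agents=s.agents, stoves=stoves, bridge_onion=False,
                          scores=(0, 0), t=0)
        s = agent_at(s, 0, pos=(1, 2), orient="N", held=env.BOWL)
        s = env.step(s, original, (env.INTERACT, env.STAY))
        assert s.agents[0].held == env.SOUP
        assert s.stove_at(stove_pos).onion_count == 0
        s = agent_at(s, 0, pos=(5, 1), orient="S", held=env.SOUP)
        s = env.step(s, original, (env.INTERACT, env.STAY))
        assert s.scores[0] == 10
        assert s.agents[0].held == env.NOTHING

    def test_bridge_deposit_and_pickup(self, original):
        s = env.initial_state(original)
        s = agent_at(s, 0, pos=(3, 4), orient="E", held=env.ONION)
        s = env.step(s, original, (env.INTERACT, env.STAY))
        assert s.bridge_onion and s.agents[0].held == env.NOTHING
        # a second onion cannot be deposited while one waits
        s2 = agent_at(s, 0, held=env.ONION)
        s2 = env.step(s2, original, (env.INTERACT, env.STAY))
        assert s2.bridge_onion and s2.agents[0].held == env.ONION
        # the right chef picks it up empty-handed
        s3 = agent_at(s, 1, pos=(3, 6), orient="W", held=env.NOTHING)
        s3 = env.step(s3, original, (env.STAY, env.INTERACT))
        assert not s3.bridge_onion and s3.agents[1].held == env.ONION

    def test_invalid_action_rejected(self, original):
        with pytest.raises(ValueError, match="invalid action"):
            env.step(env.initial_state(original), original, ("jump", env.STAY))

    def test_step_past_horizon_rejected(self, original):
        config = env.GameConfig(horizon=2)
        s = env.initial_state(original)
        s = env.step(s, original, (env.STAY, env.STAY), config)
        s = env.step(s, original, (env.STAY, env.STAY), config)
        with pytest.raises(env.EpisodeOver):
            env.step(s, original, (env.STAY, env.STAY), config)

    def test_step_is_deterministic(self, original, rng):
        s = env.initial_state(original)
        for _ in range(30):
            joint = tuple(rng.choice(env.ACTIONS, size=2))
            assert env.step(s, original, joint) == env.step(s, original, joint)
            s = env.step(s, original, joint)

    def test_side_confinement_and_score_invariants(self, original, rng):
        s = env.initial_state(original)
        prev_scores = (0, 0)
        for _ in range(59):
            joint = tuple(rng.choice(env.ACTIONS, size=2))
            s = env.step(s, original, joint)
            assert s.agents[0].pos[1] < original.side_boundary
            assert s.agents[1].pos[1] > original.side_boundary
            for sc, prev in zip(s.scores, prev_scores):
                assert sc >= prev and sc % 10 == 0
            prev_scores = s.scores


class TestItemConservation:
    def test_non_store_steps_conserve_items(self, original, rng):
        """Held/bridge/pot item deltas balance except at stores and delivery."""
        def onion_census(state, layout):
            stove_pos = env._left_object(layout, env.STOVE)
            n = sum(st.onion_count for _, st in state.stoves)
            n += int(state.bridge_onion)
            n += sum(a.held == env.ONION for a in state.agents)
            return n

        s = env.initial_state(original)
        for _ in range(59):
            joint = tuple(rng.choice(env.ACTIONS, size=2))
            before = onion_census(s, original)
            fronts = [env.front_cell(a) for a in s.agents]
            kinds = [original.cell(f) if original.in_bounds(f) else None for f in fronts]
            s2 = env.step(s, original, joint)
            after = onion_census(s2, original)
            touching_source = any(
                k in (env.ONION_STORE, env.STOVE) and a == env.INTERACT
                for k, a in zip(kinds, joint))
            if not touching_source:
                assert after == before
            s = s2


# ---------------------------------------------------------------------------
# Scripted chefs
# ---------------------------------------------------------------------------

class TestScriptedBots:
    def test_selfish_chef_never_uses_bridge(self, original):
        states, _ = env.rollout(
            original,
            lambda s: env.scripted_bot("left_selfish", s, original),
            lambda s: env.scripted_bot("right_helpseeker", s, original))
        assert not any(s.bridge_onion for s in states)
        assert states[-1].scores[0] >= 10  # it does cook

    def test_altruistic_chef_deposits_on_bridge(self, original):
        states, _ = env.rollout(
            original,
            lambda s: env.scripted_bot("left_altruistic", s, original),
            lambda s: env.scripted_bot("right_helpseeker", s, original))
        deposits = sum(1 for a, b in zip(states, states[1:])
                       if not a.bridge_onion and b.bridge_onion)
        assert deposits >= 1
        assert deposits >= states[-1].scores[0] // 10  # shares at least one per own soup

    def test_helpseeker_raises_help_flag_passing_bridge(self, original):
        s = env.initial_state(original)
        s = agent_at(s, 1, pos=(2, 6), orient="S", held=env.NOTHING)
        s2 = env.step(s, original, (env.STAY, env.DOWN))  # moves to (3,6), bridge-adjacent
        assert s2.agents[1].pos == (3, 6)
        assert s2.help_flag
        # carrying something: no call for help
        s3 = agent_at(s, 1, held=env.ONION)
        assert not env.step(s3, original, (env.STAY, env.DOWN)).help_flag

    def test_helpseeker_collects_bridge_onion(self, original):
        s = env.initial_state(original)
        s = env.GameState(agents=s.agents, stoves=s.stoves, bridge_onion=True,
                          scores=(0, 0), t=0)
        for _ in range(20):
            a = env.scripted_bot("right_helpseeker", s, original)
            s = env.step(s, original, (env.STAY, a))
            if not s.bridge_onion:
                break
        assert not s.bridge_onion
        assert s.agents[1].held == env.ONION

    def test_helpseeker_cooks_and_delivers(self, original):
        states, _ = env.rollout(
            original,
            lambda s: env.STAY,
            lambda s: env.scripted_bot("right_helpseeker", s, original),
            env.GameConfig(horizon=200))
        assert states[-1].scores[1] >= 10

    def test_unknown_role_rejected(self, original):
        with pytest.raises(ValueError):
            env.scripted_bot("chaotic_neutral", env.initial_state(original), original)


class TestSerialization:
    def test_state_round_trip(self, original, rng):
        s = env.initial_state(original)
        for _ in range(15):
            s = env.step(s, original, tuple(rng.choice(env.ACTIONS, size=2)))
        assert env.dict_to_state(env.state_to_dict(s)) == s

    def test_rollout_jsonl(self, original, tmp_path):
        states, actions = env.rollout(
            original, lambda s: env.STAY,
            lambda s: env.scripted_bot("right_helpseeker", s, original),
            env.GameConfig(horizon=5))
        path = tmp_path / "roll.jsonl"
        env.write_rollout_jsonl(path, states, actions)
        lines = path.read_text().splitlines()
        assert len(lines) == 6  # horizon + 1 states
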
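"""Single-agent behaviors and the batch motion kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from queencourt import (
    AgentState,
    BehaviorParams,
    PatchGrid,
    WorkerState,
    orient_chemotaxis,
    orient_thermotaxis,
    random_turn,
    try_move,
    update_taxis_threshold,
)
from queencourt.agents import resolve_moves


@pytest.fixture
def params():
    return BehaviorParams()


def temp_grid_warm_east():
    """Cool field with a unique warmest patch east of the centre patch (5, 5)."""
    grid = PatchGrid(11, 11, values=np.zeros((11, 11)))
    grid.values[6, 5] = 0.9  # east neighbour, still below theta_temp
    return grid


class TestThermotaxis:
    def test_no_turn_when_already_warm(self, params, rng):
        grid = PatchGrid(11, 11, values=np.full((11, 11), 1.5))
        agent = AgentState((5.5, 5.5), heading=123.0)
        for _ in range(20):
            assert orient_thermotaxis(agent, grid, params, rng).heading == 123.0

    def test_forced_turn_toward_unique_warmest_east(self, rng):
        forced = BehaviorParams(p_thermotaxis=1.0)
        agent = AgentState((5.5, 5.5), heading=200.0)
        out = orient_thermotaxis(agent, temp_grid_warm_east(), forced, rng)
        assert out.heading == pytest.approx(0.0)

    def test_zero_probability_never_turns(self, rng):
        off = BehaviorParams(p_thermotaxis=0.0)
        agent = AgentState((5.5, 5.5), heading=77.0)
        for _ in range(50):
            assert orient_thermotaxis(agent, temp_grid_warm_east(), off, rng).heading == 77.0


class TestChemotaxis:
    @staticmethod
    def pher_grid(base):
        """Constant field with a unique maximum east and minimum west of (5, 5)."""
        grid = PatchGrid(11, 11, values=np.full((11, 11), base))
        grid.values[6, 5] = base + 5.0
        grid.values[4, 5] = max(base - 1.0, 0.0)
        return grid

    def test_positive_response_turns_uphill(self, params):
        w = WorkerState((5.5, 5.5), heading=200.0, taxis_threshold=3.0)
        out = orient_chemotaxis(w, self.pher_grid(3.0), params)  # P = 3.0 >= thr
        assert out.responded_positively
        assert out.heading == pytest.approx(0.0)  # east = uphill

    def test_habituated_but_sensing_turns_downhill(self, params):
        w = WorkerState((5.5, 5.5), heading=200.0, taxis_threshold=9.0)
        out = orient_chemotaxis(w, self.pher_grid(3.0), params)  # P = 3.0 in [2.5, 9)
        assert not out.responded_positively
        assert out.heading == pytest.approx(180.0)  # west = downhill

    def test_below_sensory_threshold_no_turn(self, params):
        w = WorkerState((5.5, 5.5), heading=200.0, taxis_threshold=9.0)
        out = orient_chemotaxis(w, self.pher_grid(1.0), params)  # P = 1.0 < 2.5
        assert not out.responded_positively
        assert out.heading == 200.0

    def test_sensory_threshold_gates_positive_branch_too(self, params):
        # pheromone below Theta_min is not sensed even by a fully sensitised worker
        w = WorkerState((5.5, 5.5), heading=200.0, taxis_threshold=0.0)
        out = orient_chemotaxis(w, self.pher_grid(1.0), params)  # P >= thr but < 2.5
        assert not out.responded_positively
        assert out.heading == 200.0


class TestRandomTurn:
    def test_zero_probability_keeps_heading(self, rng):
        agent = AgentState((1, 1), heading=10.0)
        p = BehaviorParams(p_turn=0.0)
        for _ in range(50):
            assert random_turn(agent, p, rng).heading == 10.0

    def test_forced_turn_bounded_by_half_width(self, rng):
        p = BehaviorParams(p_turn=1.0)
        agent = AgentState((1, 1), heading=0.0)
        for _ in range(500):
            h = random_turn(agent, p, rng).heading
            dev = min(h, 360.0 - h)
            assert dev <= 15.0 + 1e-9

    def test_forced_turn_sampler_is_centred(self, rng):
        p = BehaviorParams(p_turn=1.0)
        agent = AgentState((1, 1), heading=180.0)
        devs = np.array([random_turn(agent, p, rng).heading - 180.0 for _ in range(10_000)])
        se = 15.0 / math.sqrt(3) / math.sqrt(devs.size)  # SE of Uniform(+-15) mean
        assert abs(devs.mean()) < 3 * se


class TestTryMove:
    arena = (20.0, 20.0)

    def test_free_path_translocates_by_worker_speed(self, rng):
        p = BehaviorParams(p_move=1.0)
        agent = AgentState((5.0, 5.0), heading=0.0)
        out, moved = try_move(agent, [], self.arena, p, rng)
        assert moved
        assert out.position[0] == pytest.approx(5.6)
        assert out.position[1] == pytest.approx(5.0)

    def test_queen_moves_at_queen_speed(self, rng):
        p = BehaviorParams(p_move=1.0)
        queen = AgentState((5.0, 5.0), heading=90.0, body_radius=0.9, role="queen")
        out, moved = try_move(queen, [], self.arena, p, rng)
        assert moved and out.position[1] == pytest.approx(5.9)

    def test_occupied_target_patch_blocks(self, rng):
        p = BehaviorParams(p_move=1.0)
        agent = AgentState((5.5, 5.5), heading=0.0)
        blocker = AgentState((6.2, 5.5), heading=0.0)  # holds patch (6, 5)
        out, moved = try_move(agent, [blocker], self.arena, p, rng)
        assert not moved and out.position == (5.5, 5.5)

    def test_same_patch_wiggle_is_free(self, rng):
        p = BehaviorParams(p_move=1.0, v_worker=0.3)
        agent = AgentState((5.1, 5.5), heading=0.0)
        blocker = AgentState((6.5, 5.5), heading=0.0)
        out, moved = try_move(agent, [blocker], self.arena, p, rng)
        assert moved and out.position[0] == pytest.approx(5.4)

    def test_other_side_does_not_block(self, rng):
        p = BehaviorParams(p_move=1.0)
        agent = AgentState((5.5, 5.5), heading=0.0, side="A")
        blocker = AgentState((6.2, 5.5), heading=0.0, side="B")
        _, moved = try_move(agent, [blocker], self.arena, p, rng)
        assert moved

    def test_arena_boundary_blocks(self, rng):
        p = BehaviorParams(p_move=1.0)
        agent = AgentState((19.5, 10.0), heading=0.0, body_radius=0.55)
        out, moved = try_move(agent, [], self.arena, p, rng)
        assert not moved

    def test_zero_probability_never_moves(self, rng):
        p = BehaviorParams(p_move=0.0)
        agent = AgentState((5.0, 5.0), heading=0.0)
        for _ in range(30):
            _, moved = try_move(agent, [], self.arena, p, rng)
            assert not moved


class TestThresholdUpdate:
    def test_positive_response_habituates(self, params):
        w = WorkerState((1, 1), 0.0, taxis_threshold=5.0, responded_positively=True)
        assert update_taxis_threshold(w, 5.0, params).taxis_threshold == pytest.approx(5.005)

    def test_dishabituation_clamps_at_zero(self, params):
        w = WorkerState((1, 1), 0.0, taxis_threshold=0.02, responded_positively=False)
        assert update_taxis_threshold(w, 0.0, params).taxis_threshold == 0.0

    def test_habituation_clamps_at_ten(self, params):
        w = WorkerState((1, 1), 0.0, taxis_threshold=10.0, responded_positively=True)
        assert update_taxis_threshold(w, 5.0, params).taxis_threshold == 10.0

    def test_sensed_but_not_responding_is_frozen_by_default(self, params):
        w = WorkerState((1, 1), 0.0, taxis_threshold=5.0, responded_positively=False)
        out = update_taxis_threshold(w, 3.0, params)  # 2.5 <= P < thr
        assert out.taxis_threshold == 5.0

    def test_alternative_reading_dishabituates_whenever_not_responding(self, params):
        w = WorkerState((1, 1), 0.0, taxis_threshold=5.0, responded_positively=False)
        out = update_taxis_threshold(w, 3.0, params, dishabituate_when_not_responding=True)
        assert out.taxis_threshold == pytest.approx(4.95)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        thr0=st.floats(0.0, 10.0),
        events=st.lists(st.tuples(st.booleans(), st.floats(0.0, 12.0)), max_size=60),
    )
    def test_threshold_never_leaves_bounds(self, thr0, events):
        params = BehaviorParams()
        w = WorkerState((1, 1), 0.0, taxis_threshold=thr0)
        for responded, p_local in events:
            w = WorkerState(
                (1, 1), 0.0, taxis_threshold=w.taxis_threshold, responded_positively=responded
            )
            w = update_taxis_threshold(w, p_local, params)
            assert 0.0 <= w.taxis_threshold <= 10.0


class TestResolveMovesKernel:
    def test_kernel_matches_sequential_single_agent_semantics(self):
        """The batch kernel must reproduce try_move applied agent by agent in
        the same order against current positions."""
        rng = np.random.default_rng(5)
        n = 15
        arena = (12.0, 12.0)
        # start from a valid state: one agent per patch
        patches = rng.choice(10 * 10, size=n, replace=False)
        x = (patches % 10) + 1 + rng.uniform(0.1, 0.9, n)
        y = (patches // 10) + 1 + rng.uniform(0.1, 0.9, n)
        heading = rng.uniform(0, 360, n)
        params = BehaviorParams(p_move=1.0)

        # reference: sequential try_move with rng that always moves
        class AlwaysMove:
            def random(self):
                return 0.0

        ref_agents = [
            AgentState((x[i], y[i]), heading[i], body_radius=0.55) for i in range(n)
        ]
        order = rng.permutation(n)
        ref_moved = np.zeros(n, dtype=bool)
        for i in order:
            others = [ref_agents[j] for j in range(n) if j != i]
            ref_agents[i], ref_moved[i] = try_move(
                ref_agents[i], others, arena, params, AlwaysMove()
            )

        kx, ky = x.copy(), y.copy()
        moved = resolve_moves(
            kx,
            ky,
            heading.copy(),
            np.zeros(n, dtype=np.int8),
            np.full(n, 0.55),
            np.full(n, params.v_worker),
            np.ones(n, dtype=bool),
            order,
            arena,
        )
        np.testing.assert_array_equal(moved, ref_moved)
        np.testing.assert_allclose(kx, [a.position[0] for a in ref_agents], rtol=1e-12)
        np.testing.assert_allclose(ky, [a.position[1] for a in ref_agents], rtol=1e-12)
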
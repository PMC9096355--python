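"""Behavioral repertoire of the queen and the court (worker) bees.

Each agent is a disc in continuous 2D space with a heading in degrees
(0 = +x/east, counterclockwise positive). Per time step an agent may

* turn toward the warmest neighbouring patch (thermotaxis, all agents),
* turn up or down the pheromone gradient (chemotaxis, workers only),
* make a small correlated random turn, and
* attempt a forward move that succeeds only if the target is free
  (physical blocking).

Workers additionally carry an adaptive response threshold Theta_taxis in
[0, 10] pheromone units. While a worker responds positively to the queen
pheromone the threshold creeps up by lambda_habituation = 0.005 per step
(habituation); once the worker no longer senses pheromone above the sensory
threshold Theta_min it relaxes back down by lambda_dishabituation = 0.05
per step (dishabituation). The opposite signs relative to the classical
threshold-reinforcement model are what produce the rhythmic on/off court
attendance: attend, habituate, stray away, resensitise, return.

The functions here are the single-agent reference semantics; the engine
runs a vectorised equivalent (plus a numba kernel for the sequential
blocking loop) over all agents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from numba import njit

from .fields import PatchGrid, neighbor_extreme, sense_patch

__all__ = [
    "AgentState",
    "WorkerState",
    "BehaviorParams",
    "orient_thermotaxis",
    "orient_chemotaxis",
    "random_turn",
    "try_move",
    "update_taxis_threshold",
    "heading_toward_patch",
    "resolve_moves",
]

THRESHOLD_MIN = 0.0
THRESHOLD_MAX = 10.0


@dataclass(frozen=True)
class BehaviorParams:
    """Per-step behavioral parameters (defaults are the model's published set)."""

    p_thermotaxis: float = 0.125
    theta_temp: float = 1.0  # model temperature units (~30-32 C)
    theta_min: float = 2.5  # minimum sensory threshold, pheromone units
    p_turn: float = 0.6
    turn_half_width: float = 15.0  # degrees
    p_move: float = 0.3
    v_queen: float = 0.9  # cm per step
    v_worker: float = 0.6  # cm per step
    lambda_habituation: float = 0.005  # pheromone units per step
    lambda_dishabituation: float = 0.05  # pheromone units per step

    def __post_init__(self) -> None:
        for name in ("p_thermotaxis", "p_turn", "p_move"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("v_queen", "v_worker", "lambda_habituation", "lambda_dishabituation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AgentState:
    """Position (cm), heading (deg in [0, 360)), comb side, body disc, role."""

    position: tuple[float, float]
    heading: float
    side: str = "A"
    body_radius: float = 0.55
    role: str = "worker"

    def __post_init__(self) -> None:
        object.__setattr__(self, "heading", self.heading % 360.0)


@dataclass(frozen=True)
class WorkerState(AgentState):
    taxis_threshold: float = 5.0
    responded_positively: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if not THRESHOLD_MIN <= self.taxis_threshold <= THRESHOLD_MAX:
            raise ValueError("taxis_threshold outside [0, 10]")


def heading_toward_patch(from_patch: tuple[int, int], to_patch: tuple[int, int]) -> float:
    """Compass heading (deg) from one patch centre to a neighbouring patch centre."""
    dx = to_patch[0] - from_patch[0]
    dy = to_patch[1] - from_patch[1]
    return math.degrees(math.atan2(dy, dx)) % 360.0


def orient_thermotaxis(
    agent: AgentState,
    temp_field: PatchGrid,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> AgentState:
    """Turn toward the warmest Moore neighbour with probability p_thermotaxis,
    but only while the local temperature is below theta_temp (outside the
    warm brood core). Applies to queen and workers alike."""
    local_t = sense_patch(temp_field, agent.position)
    if local_t >= params.theta_temp:
        return agent
    if rng.random() >= params.p_thermotaxis:
        return agent
    patch = temp_field.patch_of(*agent.position)
    warmest = neighbor_extreme(temp_field, patch, "max")
    return replace(agent, heading=heading_toward_patch(patch, warmest))


def orient_chemotaxis(
    worker: WorkerState, pher_field: PatchGrid, params: BehaviorParams
) -> WorkerState:
    """Chemotactic turn decision (workers only; the queen ignores her own plume).

    The sensory threshold gates the whole response: pheromone below
    Theta_min is not sensed and triggers no chemotactic turn. Above it, the
    adaptive threshold Theta_taxis decides the sign:

    P < Theta_min                      -> no chemotactic turn (not sensed)
    P >= Theta_min and P >= Theta_taxis -> uphill turn, positive response
    P >= Theta_min and P < Theta_taxis  -> downhill turn (habituated)
    """
    p_local = sense_patch(pher_field, worker.position)
    if p_local < params.theta_min:
        return replace(worker, responded_positively=False)
    patch = pher_field.patch_of(*worker.position)
    if p_local >= worker.taxis_threshold:
        target = neighbor_extreme(pher_field, patch, "max")
        return replace(
            worker,
            heading=heading_toward_patch(patch, target),
            responded_positively=True,
        )
    target = neighbor_extreme(pher_field, patch, "min")
    return replace(
        worker,
        heading=heading_toward_patch(patch, target),
        responded_positively=False,
    )


def random_turn(
    agent: AgentState, params: BehaviorParams, rng: np.random.Generator
) -> AgentState:
    """Correlated-random-walk turn: with probability p_turn deviate the heading
    by Uniform(-turn_half_width, +turn_half_width) degrees."""
    if rng.random() >= params.p_turn:
        return agent
    delta = rng.uniform(-params.turn_half_width, params.turn_half_width)
    return replace(agent, heading=(agent.heading + delta) % 360.0)


def try_move(
    agent: AgentState,
    others: Iterable[AgentState],
    arena_size: tuple[float, float],
    params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[AgentState, bool]:
    """Attempt one forward translocation.

    With probability p_move the agent targets position + v * (cos h, sin h),
    v = v_queen or v_worker by role. The move succeeds only if the target
    stays inside the arena (body radius margin) and the 1 x 1 cm patch it
    falls on is not already occupied by another agent on the same comb side
    — each patch holds at most one agent, which is what produces physical
    blocking and crowding. Moves within the agent's own patch are free.
    Returns the (new) state and a did_translocate flag.
    """
    if rng.random() >= params.p_move:
        return agent, False
    v = params.v_queen if agent.role == "queen" else params.v_worker
    h = math.radians(agent.heading)
    tx = agent.position[0] + v * math.cos(h)
    ty = agent.position[1] + v * math.sin(h)
    r = agent.body_radius
    w, hgt = arena_size
    if not (r <= tx <= w - r and r <= ty <= hgt - r):
        return agent, False
    target_patch = (math.floor(tx), math.floor(ty))
    own_patch = (math.floor(agent.position[0]), math.floor(agent.position[1]))
    if target_patch != own_patch:
        for other in others:
            if other.side != agent.side:
                continue
            opatch = (math.floor(other.position[0]), math.floor(other.position[1]))
            if opatch == target_patch:
                return agent, False
    return replace(agent, position=(tx, ty)), True


def update_taxis_threshold(
    worker: WorkerState,
    local_pheromone: float,
    params: BehaviorParams,
    dishabituate_when_not_responding: bool = False,
) -> WorkerState:
    """Inverse threshold-reinforcement update, clamped to [0, 10].

    Positive response this step raises the threshold (habituation); sensing
    no pheromone above Theta_min lowers it (dishabituation). In the default
    reading the intermediate regime (sensed but not responding positively)
    changes nothing, which forces workers to leave the plume before they
    resensitise; ``dishabituate_when_not_responding=True`` switches to the
    alternative reading where any non-positive step dishabituates.
    """
    thr = worker.taxis_threshold
    if worker.responded_positively:
        thr += params.lambda_habituation
    elif dishabituate_when_not_responding or local_pheromone < params.theta_min:
        thr -= params.lambda_dishabituation
    thr = min(max(thr, THRESHOLD_MIN), THRESHOLD_MAX)
    return replace(worker, taxis_threshold=thr)


# ---------------------------------------------------------------------------
# batch motion kernel (engine hot path)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _resolve_moves_kernel(
    x, y, heading_deg, side, radii, speeds, move_mask, order,
    arena_w, arena_h, two_sided, band_lo, band_hi, did_translocate,
):  # pragma: no cover - exercised through resolve_moves
    n = x.shape[0]
    w = int(arena_w)
    h_patches = int(arena_h)
    # occupancy index: agent id + 1 per (side, patch), 0 = free
    occ = np.zeros((2, w, h_patches), dtype=np.int64)
    for i in range(n):
        occ[side[i], int(x[i]), int(y[i])] = i + 1
    for k in range(n):
        i = order[k]
        if not move_mask[i]:
            continue
        h = heading_deg[i] * math.pi / 180.0
        tx = x[i] + speeds[i] * math.cos(h)
        ty = y[i] + speeds[i] * math.sin(h)
        r = radii[i]
        if tx < r or tx > arena_w - r or ty < r or ty > arena_h - r:
            continue
        dest_side = side[i]
        if two_sided:
            was_in_band = band_lo <= y[i] <= band_hi
            now_in_band = band_lo <= ty <= band_hi
            if now_in_band and not was_in_band:
                dest_side = 1 - dest_side
        tix = int(tx)
        tiy = int(ty)
        holder = occ[dest_side, tix, tiy]
        if holder != 0 and holder != i + 1:
            continue
        occ[side[i], int(x[i]), int(y[i])] = 0
        side[i] = dest_side
        x[i] = tx
        y[i] = ty
        occ[dest_side, tix, tiy] = i + 1
        did_translocate[i] = True


def resolve_moves(
    x: np.ndarray,
    y: np.ndarray,
    heading_deg: np.ndarray,
    side: np.ndarray,
    radii: np.ndarray,
    speeds: np.ndarray,
    move_mask: np.ndarray,
    order: np.ndarray,
    arena_size: tuple[float, float],
    two_sided: bool = False,
    crossing_band: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Sequentially resolve all motion attempts of one step, in the given order.

    Mutates ``x``, ``y`` (and ``side`` when two-sided crossing is enabled:
    entering the crossing band from outside flips the comb side) and returns
    the per-agent did_translocate flags. Occupancy (one agent per patch per
    side) is evaluated against the *current* positions, so earlier movers in
    the shuffled order can block or unblock later ones, exactly as in the
    single-agent semantics.
    """
    did = np.zeros(x.shape[0], dtype=np.bool_)
    _resolve_moves_kernel(
        x, y, heading_deg, side, radii, speeds,
        np.ascontiguousarray(move_mask), np.ascontiguousarray(order),
        float(arena_size[0]), float(arena_size[1]),
        two_sided, float(crossing_band[0]), float(crossing_band[1]), did,
    )
    return did
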
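"""Simulation clock, configuration and per-step scheduling.

A run owns a single seeded numpy random stream; identical seeds give
bitwise-identical runs. Each step executes, in order:

1. orientation — thermotaxis for all agents, then chemotaxis for workers;
2. correlated random turns;
3. motion attempts in a freshly shuffled agent order (blocking applies);
4. queen pheromone emission, then decay-and-diffusion of the field(s);
5. per-worker habituation/dishabituation threshold updates.

The arena is one comb side by default (the configuration the court
observations use); with ``two_sided=True`` a second, identical comb face is
simulated and an agent whose move enters the crossing band from outside
switches side with position and heading preserved. Pheromone fields are
per side and exchange no mass.

One time step corresponds to 0.25 s of real time by default (100,000 steps
~ 7 h), which converts all second-denominated observables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import yaml

from . import agents as _agents
from .agents import AgentState, BehaviorParams, WorkerState, resolve_moves
from .fields import (
    PatchGrid,
    PheromoneParams,
    TemperatureParams,
    build_temperature_field,
    neighbor_counts,
    neighbor_direction_maps,
    _decay_diffuse_inplace,
)

__all__ = ["SimConfig", "SimState", "initialize", "step", "run"]

QUEEN = 0  # agent index of the queen
SIDES = ("A", "B")


@dataclass(frozen=True)
class SimConfig:
    """Flat bag of every model parameter plus arena geometry and seeding."""

    # pheromone field dynamics
    e_pheromone: float = 10.0
    mu_pheromone: float = 0.05
    d_pheromone: float = 1.0
    # behavior
    p_thermotaxis: float = 0.125
    theta_temp: float = 1.0
    theta_min: float = 2.5
    p_turn: float = 0.6
    turn_half_width: float = 15.0
    p_move: float = 0.3
    v_queen: float = 0.9
    v_worker: float = 0.6
    lambda_habituation: float = 0.005
    lambda_dishabituation: float = 0.05
    dishabituate_when_not_responding: bool = False
    # temperature field (model units)
    temp_center: float = 2.0
    temp_rim: float = 0.0
    brood_radius: float = 8.0
    brood_center_x: float | None = None  # defaults to arena centre
    brood_center_y: float | None = None
    # population & geometry
    n_workers: int = 100
    arena_width: int = 40  # patches (= cm) per comb side
    arena_height: int = 30
    two_sided: bool = False
    crossing_band_lo: float = 14.5
    crossing_band_hi: float = 15.5
    worker_body_radius: float = 0.55
    queen_body_radius: float = 0.9
    queen_start_x: float | None = None  # defaults to brood centre
    queen_start_y: float | None = None
    init_threshold_lo: float = 0.0
    init_threshold_hi: float = 10.0
    # bookkeeping
    step_duration_s: float = 0.25
    seed: int = 0
    max_steps: int = 10_000
    court_radius: float = 2.5

    def __post_init__(self) -> None:
        if self.n_workers < 0:
            raise ValueError("n_workers must be >= 0")
        if self.step_duration_s <= 0:
            raise ValueError("step_duration_s must be > 0")
        if self.two_sided and not (
            0.0 <= self.crossing_band_lo <= self.crossing_band_hi <= self.arena_height
        ):
            raise ValueError("crossing band must lie inside the arena")
        # trigger validation of the derived parameter bundles
        self.behavior_params
        self.pheromone_params
        self.temperature_params

    # -- derived parameter bundles ---------------------------------------
    @property
    def behavior_params(self) -> BehaviorParams:
        return BehaviorParams(
            p_thermotaxis=self.p_thermotaxis,
            theta_temp=self.theta_temp,
            theta_min=self.theta_min,
            p_turn=self.p_turn,
            turn_half_width=self.turn_half_width,
            p_move=self.p_move,
            v_queen=self.v_queen,
            v_worker=self.v_worker,
            lambda_habituation=self.lambda_habituation,
            lambda_dishabituation=self.lambda_dishabituation,
        )

    @property
    def pheromone_params(self) -> PheromoneParams:
        return PheromoneParams(
            emission_rate=self.e_pheromone,
            decay_fraction=self.mu_pheromone,
            diffusion_coeff=self.d_pheromone,
        )

    @property
    def temperature_params(self) -> TemperatureParams:
        return TemperatureParams(
            center_model_value=self.temp_center,
            rim_model_value=self.temp_rim,
            threshold_model_value=self.theta_temp,
        )

    @property
    def brood_center(self) -> tuple[float, float]:
        return (
            self.arena_width / 2.0 if self.brood_center_x is None else self.brood_center_x,
            self.arena_height / 2.0 if self.brood_center_y is None else self.brood_center_y,
        )

    @property
    def queen_start(self) -> tuple[float, float]:
        bx, by = self.brood_center
        return (
            bx if self.queen_start_x is None else self.queen_start_x,
            by if self.queen_start_y is None else self.queen_start_y,
        )

    @property
    def arena_size(self) -> tuple[float, float]:
        return float(self.arena_width), float(self.arena_height)

    def steps_for_seconds(self, seconds: float) -> int:
        return int(round(seconds / self.step_duration_s))

    # -- text IO ----------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimState:
    """Mutable state of a running simulation (struct-of-arrays; index 0 = queen)."""

    config: SimConfig
    clock: int
    rng: np.random.Generator
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray  # degrees in [0, 360)
    side: np.ndarray  # int8: 0 = side A, 1 = side B
    radii: np.ndarray
    speeds: np.ndarray
    thresholds: np.ndarray  # per worker, indices into workers (len n_workers)
    responded: np.ndarray  # per worker bool, current step
    did_translocate: np.ndarray  # per agent bool, last step
    temp_field: PatchGrid
    pher: dict[int, np.ndarray]  # side index -> field values array
    temp_dir_map: np.ndarray  # static warmest-neighbour heading per patch
    n_neighbors: np.ndarray

    @property
    def n_agents(self) -> int:
        return self.x.shape[0]

    @property
    def n_workers(self) -> int:
        return self.n_agents - 1

    @property
    def queen_position(self) -> tuple[float, float]:
        return float(self.x[QUEEN]), float(self.y[QUEEN])

    def pher_grid(self, side: int = 0) -> PatchGrid:
        return PatchGrid(
            self.config.arena_width,
            self.config.arena_height,
            side=SIDES[side],
            values=self.pher[side].copy(),
        )

    def queen_agent(self) -> AgentState:
        return AgentState(
            position=self.queen_position,
            heading=float(self.heading[QUEEN]),
            side=SIDES[int(self.side[QUEEN])],
            body_radius=float(self.radii[QUEEN]),
            role="queen",
        )

    def worker_agents(self) -> list[WorkerState]:
        return [
            WorkerState(
                position=(float(self.x[i]), float(self.y[i])),
                heading=float(self.heading[i]),
                side=SIDES[int(self.side[i])],
                body_radius=float(self.radii[i]),
                role="worker",
                taxis_threshold=float(self.thresholds[i - 1]),
                responded_positively=bool(self.responded[i - 1]),
            )
            for i in range(1, self.n_agents)
        ]

    def agent_table(self):
        """Current agent states as a pandas DataFrame (serialisable log row set)."""
        import pandas as pd

        n = self.n_agents
        thr = np.full(n, np.nan)
        thr[1:] = self.thresholds
        return pd.DataFrame(
            {
                "step": self.clock,
                "agent_id": np.arange(n),
                "role": ["queen"] + ["worker"] * (n - 1),
                "side": [SIDES[s] for s in self.side],
                "x_cm": self.x.copy(),
                "y_cm": self.y.copy(),
                "heading_deg": self.heading.copy(),
                "taxis_threshold": thr,
                "did_translocate": self.did_translocate.copy(),
            }
        )


def initialize(config: SimConfig) -> SimState:
    """Build fields, place the queen and the workers, seed the random stream.

    The queen starts at the brood centre of side A; workers are placed
    uniformly at random (side A), at most one agent per 1 x 1 cm patch (the
    same occupancy rule that governs motion blocking), with headings uniform
    in [0, 360) and initial taxis thresholds uniform in the configured
    range. Raises a capacity error when placement fails repeatedly or the
    population exceeds the patch count.
    """
    temp_field = build_temperature_field(
        (config.arena_width, config.arena_height),
        config.temperature_params,
        config.brood_center,
        config.brood_radius,
    )
    temp_dir_map, _ = neighbor_direction_maps(temp_field.values)
    rng = np.random.default_rng(config.seed)

    n = config.n_workers
    n_agents = n + 1
    x = np.empty(n_agents)
    y = np.empty(n_agents)
    radii = np.full(n_agents, config.worker_body_radius)
    radii[QUEEN] = config.queen_body_radius
    speeds = np.full(n_agents, config.v_worker)
    speeds[QUEEN] = config.v_queen

    qx, qy = config.queen_start
    w, h = config.arena_size
    rq = config.queen_body_radius
    if not (rq <= qx <= w - rq and rq <= qy <= h - rq):
        raise ValueError("queen start position outside the arena")
    x[QUEEN], y[QUEEN] = qx, qy

    rw = config.worker_body_radius
    if w - 2 * rw <= 0 or h - 2 * rw <= 0:
        raise ValueError("arena too small for a worker body disc")
    if n_agents > config.arena_width * config.arena_height:
        raise ValueError(
            f"cannot place {n} workers plus the queen at one agent per patch "
            f"in a {config.arena_width} x {config.arena_height} patch arena"
        )
    occupied = {(int(qx), int(qy))}
    max_attempts = 1000 + 500 * n
    attempts = 0
    placed = 1
    while placed < n_agents:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} workers (one per patch) in a "
                f"{w} x {h} cm arena (capacity exceeded)"
            )
        cx = rng.uniform(rw, w - rw)
        cy = rng.uniform(rw, h - rw)
        patch = (int(cx), int(cy))
        if patch not in occupied:
            occupied.add(patch)
            x[placed], y[placed] = cx, cy
            placed += 1

    heading = rng.uniform(0.0, 360.0, n_agents)
    thresholds = rng.uniform(config.init_threshold_lo, config.init_threshold_hi, n)

    pher = {0: np.zeros((config.arena_width, config.arena_height))}
    if config.two_sided:
        pher[1] = np.zeros_like(pher[0])

    return SimState(
        config=config,
        clock=0,
        rng=rng,
        x=x,
        y=y,
        heading=heading,
        side=np.zeros(n_agents, dtype=np.int8),
        radii=radii,
        speeds=speeds,
        thresholds=thresholds,
        responded=np.zeros(n, dtype=bool),
        did_translocate=np.zeros(n_agents, dtype=bool),
        temp_field=temp_field,
        pher=pher,
        temp_dir_map=temp_dir_map,
        n_neighbors=neighbor_counts(config.arena_width, config.arena_height),
    )


def step(state: SimState) -> SimState:
    """Advance the simulation by one time step (mutates and returns ``state``)."""
    cfg = state.config
    rng = state.rng
    n_agents = state.n_agents
    n = n_agents - 1

    ix = np.floor(state.x).astype(np.intp)
    iy = np.floor(state.y).astype(np.intp)

    # (1a) thermotaxis: all agents, gated on local temperature below theta_temp
    t_local = state.temp_field.values[ix, iy]
    draws = rng.random(n_agents)
    mask = (t_local < cfg.theta_temp) & (draws < cfg.p_thermotaxis)
    if mask.any():
        state.heading[mask] = state.temp_dir_map[ix[mask], iy[mask]]

    # (1b) chemotaxis: workers only, on their own side's pheromone field
    p_sensed = np.zeros(n)
    if n:
        wix, wiy = ix[1:], iy[1:]
        wside = state.side[1:]
        for s, values in state.pher.items():
            on_side = wside == s
            if not on_side.any():
                continue
            max_dir, min_dir = neighbor_direction_maps(values)
            p_here = values[wix[on_side], wiy[on_side]]
            p_sensed[on_side] = p_here
            sensed = p_here >= cfg.theta_min  # Theta_min gates any response
            pos = sensed & (p_here >= state.thresholds[on_side])
            neg = sensed & ~pos
            idx = np.flatnonzero(on_side)
            up = idx[pos]
            down = idx[neg]
            state.heading[1 + up] = max_dir[wix[up], wiy[up]]
            state.heading[1 + down] = min_dir[wix[down], wiy[down]]
            state.responded[on_side] = pos

    # (2) correlated random turn
    draws = rng.random(n_agents)
    deltas = rng.uniform(-cfg.turn_half_width, cfg.turn_half_width, n_agents)
    turn = draws < cfg.p_turn
    state.heading[turn] = (state.heading[turn] + deltas[turn]) % 360.0

    # (3) motion attempts in a freshly shuffled order, with blocking
    move_mask = rng.random(n_agents) < cfg.p_move
    order = rng.permutation(n_agents)
    state.did_translocate = resolve_moves(
        state.x,
        state.y,
        state.heading,
        state.side,
        state.radii,
        state.speeds,
        move_mask,
        order,
        cfg.arena_size,
        cfg.two_sided,
        (cfg.crossing_band_lo, cfg.crossing_band_hi),
    )

    # (4) pheromone: queen emission, then decay and diffusion on every side
    qpatch = (
        int(state.x[QUEEN] // 1.0),
        int(state.y[QUEEN] // 1.0),
    )
    state.pher[int(state.side[QUEEN])][qpatch] += cfg.e_pheromone
    for values in state.pher.values():
        _decay_diffuse_inplace(
            values, cfg.mu_pheromone, cfg.d_pheromone, state.n_neighbors
        )

    # (5) habituation / dishabituation, driven by this step's sensed pheromone
    if n:
        state.thresholds[state.responded] += cfg.lambda_habituation
        if cfg.dishabituate_when_not_responding:
            dis = ~state.responded
        else:
            dis = ~state.responded & (p_sensed < cfg.theta_min)
        state.thresholds[dis] -= cfg.lambda_dishabituation
        np.clip(
            state.thresholds,
            _agents.THRESHOLD_MIN,
            _agents.THRESHOLD_MAX,
            out=state.thresholds,
        )

    state.clock += 1
    return state


def run(
    config: SimConfig,
    recorders: Sequence = (),
    max_steps: int | None = None,
) -> SimState:
    """Initialise and iterate ``step`` ``max_steps`` times, feeding every state
    (including the initial one) to each recorder. Recorders implement
    ``record(state)`` and optionally ``finalize(state)``."""
    state = initialize(config)
    steps = config.max_steps if max_steps is None else max_steps
    for rec in recorders:
        rec.record(state)
    for _ in range(steps):
        step(state)
        for rec in recorders:
            rec.record(state)
    for rec in recorders:
        fin = getattr(rec, "finalize", None)
        if fin is not None:
            fin(state)
    return state
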
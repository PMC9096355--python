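"""Model-side measurements: resting events, court sizes, time budgets, sweeps.

Definitions (all on the queen's per-step translocation flags):

* resting event — a maximal run of >= 5 consecutive steps without a forward
  translocation; it ends as soon as the queen moves forward in one step.
* court size — number of workers on the queen's comb side whose centre lies
  within 2.5 cm of the queen's centre (inclusive boundary); for event
  statistics it is sampled at the event midpoint step.
* displacement — steps belonging to runs of MORE than 5 consecutive
  translocations; everything else (full stops and short wiggles) counts as
  resting time.
* rest->walk transition — a resting event terminated by a forward move
  (an event truncated by the end of the series is not a transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import QUEEN, SimConfig, SimState, run

__all__ = [
    "RestingEvent",
    "TimeBudget",
    "SweepResult",
    "CourtSizeSummary",
    "annotate_court_sizes",
    "detect_resting_events",
    "court_size_at",
    "summarize_court_sizes",
    "queen_time_budget",
    "count_rest_walk_transitions",
    "sweep_worker_speed",
    "render_imprints",
    "QueenMotionRecorder",
    "CourtSizeRecorder",
    "AgentLogRecorder",
    "ImprintRecorder",
    "boolean_runs",
]


@dataclass
class RestingEvent:
    """Half-open step interval [start_step, end_step) of queen immobility."""

    start_step: int
    end_step: int
    court_size: int | None = None

    def __post_init__(self) -> None:
        if self.end_step - self.start_step < 5:
            raise ValueError("resting events last at least 5 steps")

    @property
    def midpoint_step(self) -> int:
        return (self.start_step + self.end_step) // 2

    @property
    def duration_steps(self) -> int:
        return self.end_step - self.start_step


@dataclass(frozen=True)
class TimeBudget:
    fraction_displacement: float
    fraction_resting_or_wiggling: float


@dataclass(frozen=True)
class SweepResult:
    v_w: float
    replicate: int
    seed: int
    mean_court_size: float
    rest_to_walk_transitions: int


@dataclass(frozen=True)
class CourtSizeSummary:
    mean: float
    median: float
    iqr: float
    histogram: np.ndarray  # counts for integer bins 0..max size
    n: int


def boolean_runs(flags: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of a boolean series as (start, end, value) half-open triples."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    edges = np.flatnonzero(np.diff(flags)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [flags.size]))
    return [(int(s), int(e), bool(flags[s])) for s, e in zip(starts, ends)]


def detect_resting_events(
    queen_translocation_series: np.ndarray, min_steps: int = 5
) -> list[RestingEvent]:
    """Maximal runs of >= ``min_steps`` consecutive non-translocation steps."""
    return [
        RestingEvent(s, e)
        for s, e, moved in boolean_runs(queen_translocation_series)
        if not moved and e - s >= min_steps
    ]


def annotate_court_sizes(
    events: list[RestingEvent], court_size_series: np.ndarray
) -> list[RestingEvent]:
    """Fill each event's ``court_size`` from a per-step court-size series that
    is index-aligned with the translocation series the events came from
    (sampling at the event midpoint step)."""
    sizes = np.asarray(court_size_series)
    for ev in events:
        ev.court_size = int(sizes[ev.midpoint_step])
    return events


def court_size_at(state: SimState, radius: float | None = None) -> int:
    """Workers on the queen's side within ``radius`` cm of her centre (inclusive)."""
    r = state.config.court_radius if radius is None else radius
    qx, qy = state.queen_position
    qside = state.side[QUEEN]
    d2 = (state.x[1:] - qx) ** 2 + (state.y[1:] - qy) ** 2
    return int(np.count_nonzero((state.side[1:] == qside) & (d2 <= r * r)))


def summarize_court_sizes(events) -> CourtSizeSummary:
    """Mean, median, IQR (linear-interpolation quartiles) and integer histogram
    of the court sizes of a non-empty collection of resting events (or a raw
    sequence of integer sizes)."""
    sizes = np.asarray(
        [e.court_size if isinstance(e, RestingEvent) else e for e in events],
        dtype=float,
    )
    if sizes.size == 0:
        raise ValueError("no events to summarize")
    if np.any(np.isnan(sizes)):
        raise ValueError("events missing court_size annotations")
    q1, q3 = np.percentile(sizes, [25, 75])
    hist = np.bincount(sizes.astype(int))
    return CourtSizeSummary(
        mean=float(sizes.mean()),
        median=float(np.median(sizes)),
        iqr=float(q3 - q1),
        histogram=hist,
        n=int(sizes.size),
    )


def queen_time_budget(
    queen_translocation_series: np.ndarray, min_run: int = 6
) -> TimeBudget:
    """Fraction of steps in displacement (runs of > 5 consecutive translocations)
    versus resting/wiggling (everything else)."""
    flags = np.asarray(queen_translocation_series, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty translocation series")
    displacement = sum(
        e - s for s, e, moved in boolean_runs(flags) if moved and e - s >= min_run
    )
    frac = displacement / flags.size
    return TimeBudget(frac, 1.0 - frac)


def count_rest_walk_transitions(
    queen_translocation_series: np.ndarray, min_steps: int = 5
) -> int:
    """Resting episodes terminated by a forward move. An episode still running
    at the end of the series has not transitioned and is not counted."""
    n = len(queen_translocation_series)
    return sum(
        1
        for ev in detect_resting_events(queen_translocation_series, min_steps)
        if ev.end_step < n
    )


# ---------------------------------------------------------------------------
# recorders
# ---------------------------------------------------------------------------


class QueenMotionRecorder:
    """Per-step queen positions and translocation flags.

    ``positions`` includes the initial state, so a run of k steps yields
    k + 1 positions; ``translocated`` has one flag per executed step.
    """

    def __init__(self) -> None:
        self._xs: list[float] = []
        self._ys: list[float] = []
        self._moved: list[bool] = []

    def record(self, state: SimState) -> None:
        qx, qy = state.queen_position
        self._xs.append(qx)
        self._ys.append(qy)
        if state.clock > 0:
            self._moved.append(bool(state.did_translocate[QUEEN]))

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self._xs, self._ys])

    @property
    def translocated(self) -> np.ndarray:
        return np.asarray(self._moved, dtype=bool)


class CourtSizeRecorder:
    """Per-step court size (workers within the court radius of the queen)."""

    def __init__(self, radius: float | None = None) -> None:
        self.radius = radius
        self._sizes: list[int] = []

    def record(self, state: SimState) -> None:
        if state.clock > 0:
            self._sizes.append(court_size_at(state, self.radius))

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(self._sizes, dtype=int)


class AgentLogRecorder:
    """Full agent table every ``every`` steps, concatenated as a DataFrame."""

    def __init__(self, every: int = 1) -> None:
        self.every = every
        self._chunks = []

    def record(self, state: SimState) -> None:
        if state.clock % self.every == 0:
            self._chunks.append(state.agent_table())

    def to_frame(self):
        import pandas as pd

        return pd.concat(self._chunks, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class ImprintRecorder:
    """Semi-transparent body-shape stamping onto a background raster.

    Every ``stamp_interval_s`` of simulated time, each eligible worker adds a
    low-alpha disc imprint at its position: eligible means within
    ``near_queen_radius`` cm of the queen (if set) and not having
    translocated for at least ``min_still_s`` seconds (if set). Dense marks
    therefore indicate long residence — the halo of a stable court.
    """

    def __init__(
        self,
        px_per_cm: int = 10,
        near_queen_radius: float | None = 2.5,
        stamp_interval_s: float = 5.0,
        min_still_s: float = 0.0,
        alpha: float = 0.03,
    ) -> None:
        self.px_per_cm = px_per_cm
        self.near_queen_radius = near_queen_radius
        self.stamp_interval_s = stamp_interval_s
        self.min_still_s = min_still_s
        self.alpha = alpha
        self._image: np.ndarray | None = None
        self._last_move: np.ndarray | None = None

    def _setup(self, state: SimState) -> None:
        w, h = state.config.arena_size
        self._image = np.zeros((int(h * self.px_per_cm), int(w * self.px_per_cm)))
        self._last_move = np.zeros(state.n_agents, dtype=int)
        self._interval_steps = max(
            1, state.config.steps_for_seconds(self.stamp_interval_s)
        )
        self._still_steps = state.config.steps_for_seconds(self.min_still_s)

    def _stamp(self, x: float, y: float, radius: float) -> None:
        img = self._image
        s = self.px_per_cm
        cx, cy, r = x * s, y * s, radius * s
        x0 = max(int(cx - r), 0)
        x1 = min(int(cx + r) + 1, img.shape[1])
        y0 = max(int(cy - r), 0)
        y1 = min(int(cy + r) + 1, img.shape[0])
        if x0 >= x1 or y0 >= y1:
            return
        xs = np.arange(x0, x1) + 0.5
        ys = np.arange(y0, y1) + 0.5
        disc = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= r * r
        img[y0:y1, x0:x1][disc] += self.alpha

    def record(self, state: SimState) -> None:
        if self._image is None:
            self._setup(state)
        if state.clock == 0:
            return
        self._last_move[state.did_translocate] = state.clock
        if state.clock % self._interval_steps != 0:
            return
        qx, qy = state.queen_position
        qside = state.side[QUEEN]
        for i in range(1, state.n_agents):
            if state.side[i] != qside:
                continue
            if state.clock - self._last_move[i] < self._still_steps:
                continue
            if self.near_queen_radius is not None:
                d2 = (state.x[i] - qx) ** 2 + (state.y[i] - qy) ** 2
                if d2 > self.near_queen_radius**2:
                    continue
            self._stamp(float(state.x[i]), float(state.y[i]), float(state.radii[i]))

    @property
    def image(self) -> np.ndarray:
        """Accumulated imprint raster, row 0 at the bottom of the arena."""
        if self._image is None:
            raise RuntimeError("recorder has not seen any state yet")
        return self._image

    def save_png(self, path) -> None:
        import imageio.v3 as iio

        img = self.image[::-1]
        hi = img.max()
        scaled = img / hi if hi > 0 else img
        iio.imwrite(path, (np.clip(scaled, 0, 1) * 255).astype(np.uint8))


def render_imprints(
    config: SimConfig,
    max_steps: int | None = None,
    near_queen_radius: float | None = 2.5,
    stamp_interval_s: float = 5.0,
    min_still_s: float = 0.0,
    alpha: float = 0.03,
    px_per_cm: int = 10,
) -> np.ndarray:
    """Run a simulation and return the accumulated body-imprint image."""
    rec = ImprintRecorder(
        px_per_cm=px_per_cm,
        near_queen_radius=near_queen_radius,
        stamp_interval_s=stamp_interval_s,
        min_still_s=min_still_s,
        alpha=alpha,
    )
    run(config, [rec], max_steps=max_steps)
    return rec.image


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------


def derive_seed(base_seed: int, v_index: int, replicate: int) -> int:
    """Deterministic per-run seed below 2**31."""
    return (base_seed * 1_000_003 + v_index * 10_007 + replicate * 101 + 7) % (2**31)


def sweep_worker_speed(
    base_config: SimConfig,
    v_w_values,
    replicates: int = 30,
    steps: int = 30_000,
) -> list[SweepResult]:
    """Replicated runs over worker speeds, recording per-run mean court size and
    rest->walk transition counts (independent seeded runs; seeds derived from
    the base config seed, the speed index and the replicate index)."""
    v_w_values = list(v_w_values)
    if not v_w_values:
        raise ValueError("v_w_values must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    results: list[SweepResult] = []
    for vi, v_w in enumerate(v_w_values):
        for rep in range(replicates):
            seed = derive_seed(base_config.seed, vi, rep)
            cfg = SimConfig(
                **{
                    **{
                        f: getattr(base_config, f)
                        for f in SimConfig.__dataclass_fields__
                    },
                    "v_worker": float(v_w),
                    "seed": seed,
                }
            )
            motion = QueenMotionRecorder()
            court = CourtSizeRecorder()
            run(cfg, [motion, court], max_steps=steps)
            results.append(
                SweepResult(
                    v_w=float(v_w),
                    replicate=rep,
                    seed=seed,
                    mean_court_size=float(court.sizes.mean()),
                    rest_to_walk_transitions=count_rest_walk_transitions(
                        motion.translocated
                    ),
                )
            )
    return results
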
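"""Synthetic inputs for testing the empirical-analysis pipeline.

Everything here is generated programmatically and deterministically from a
seed; no recorded data is required anywhere in the package. Trajectories are
scripted alternations of rest and walk segments sampled at the nominal
4-second frame interval (emulating tracked IR stills), with optional
Gaussian positional jitter and the exact rest intervals returned as ground
truth. Image stacks are abstract synthetic scenes — a static disc pattern
(standing in for the queen and a stable court) plus per-frame random
distractor blobs and Gaussian noise — with the static-pattern mask returned
for validating the median-stack procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .empirics import TrackedTrajectory

__all__ = [
    "TrajectorySegment",
    "TrajectoryScript",
    "ImageStackScript",
    "make_trajectory",
    "make_image_stack",
]


@dataclass(frozen=True)
class TrajectorySegment:
    mode: str  # "rest" | "walk"
    duration_s: float
    speed_px_s: float = 0.0
    heading_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("rest", "walk"):
            raise ValueError("mode must be 'rest' or 'walk'")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.mode == "rest" and self.speed_px_s != 0.0:
            raise ValueError("rest segments have speed 0 (jitter only)")


@dataclass(frozen=True)
class TrajectoryScript:
    segments: tuple[TrajectorySegment, ...]
    jitter_sd_px: float = 0.0
    frame_interval_s: float = 4.0
    start_px: tuple[float, float] = (500.0, 500.0)
    px_per_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("script needs at least one segment")


def make_trajectory(
    script: TrajectoryScript,
) -> tuple[TrackedTrajectory, list[tuple[float, float]]]:
    """Sample a scripted queen path every ``frame_interval_s`` seconds.

    The continuous path follows each segment's constant velocity; each
    sample gets independent Gaussian jitter of ``jitter_sd_px`` per axis.
    Returns the trajectory plus the exact (start_s, end_s) rest intervals as
    ground truth, so detector recall/precision are computable.
    """
    rng = np.random.default_rng(script.seed)
    boundaries = np.cumsum([seg.duration_s for seg in script.segments])
    total = boundaries[-1]
    times = np.arange(0.0, total + 1e-9, script.frame_interval_s)

    # integrate the piecewise-constant velocity at segment boundaries
    pos = np.array(script.start_px, dtype=float)
    seg_starts = np.concatenate(([0.0], boundaries[:-1]))
    seg_start_pos = []
    for seg in script.segments:
        seg_start_pos.append(pos.copy())
        h = np.radians(seg.heading_deg)
        pos = pos + seg.speed_px_s * seg.duration_s * np.array([np.cos(h), np.sin(h)])
    seg_start_pos = np.array(seg_start_pos)

    idx = np.clip(np.searchsorted(boundaries, times, side="right"), 0, len(script.segments) - 1)
    xs = np.empty_like(times)
    ys = np.empty_like(times)
    for k, seg in enumerate(script.segments):
        m = idx == k
        if not m.any():
            continue
        dt = times[m] - seg_starts[k]
        h = np.radians(seg.heading_deg)
        xs[m] = seg_start_pos[k, 0] + seg.speed_px_s * dt * np.cos(h)
        ys[m] = seg_start_pos[k, 1] + seg.speed_px_s * dt * np.sin(h)
    if script.jitter_sd_px > 0:
        xs = xs + rng.normal(0.0, script.jitter_sd_px, times.size)
        ys = ys + rng.normal(0.0, script.jitter_sd_px, times.size)

    truth = [
        (float(s), float(e))
        for seg, s, e in zip(script.segments, seg_starts, boundaries)
        if seg.mode == "rest"
    ]
    traj = TrackedTrajectory(
        times, xs, ys, frame_interval=script.frame_interval_s, px_per_mm=script.px_per_mm
    )
    return traj, truth


@dataclass(frozen=True)
class ImageStackScript:
    n_frames: int = 154  # a court event of ~10 min at 4 s per frame
    height: int = 400
    width: int = 400
    static_discs: tuple[tuple[float, float, float, float], ...] = (
        (200.0, 200.0, 18.0, 0.9),  # queen
        (200.0, 170.0, 10.0, 0.7),  # court bees, ring below/around
        (226.0, 185.0, 10.0, 0.7),
        (226.0, 215.0, 10.0, 0.7),
        (200.0, 230.0, 10.0, 0.7),
        (174.0, 215.0, 10.0, 0.7),
        (174.0, 185.0, 10.0, 0.7),
    )
    n_distractors: int = 8
    distractor_radius: float = 10.0
    distractor_intensity: float = 0.7
    background: float = 0.2
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        object.__setattr__(self, "static_discs", tuple(map(tuple, self.static_discs)))


def _paint_disc(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    h, w = img.shape
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    disc = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= r * r
    region = img[y0:y1, x0:x1]
    region[disc] = np.maximum(region[disc], value)


def make_image_stack(script: ImageStackScript) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic grayscale court-event stack plus the static-pattern mask.

    Every frame contains the same static disc pattern; distractor blobs land
    at a fresh uniform location each frame (so at any one pixel they appear
    in well under half the frames) and Gaussian pixel noise is added. Frames
    are clipped to [0, 1].
    """
    rng = np.random.default_rng(script.seed)
    h, w = script.height, script.width

    static = np.full((h, w), script.background)
    mask = np.zeros((h, w), dtype=bool)
    for cx, cy, r, val in script.static_discs:
        _paint_disc(static, cx, cy, r, val)
        tmp = np.zeros((h, w))
        _paint_disc(tmp, cx, cy, r, 1.0)
        mask |= tmp > 0

    frames = np.empty((script.n_frames, h, w))
    for f in range(script.n_frames):
        frame = static.copy()
        for _ in range(script.n_distractors):
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            _paint_disc(frame, cx, cy, script.distractor_radius, script.distractor_intensity)
        if script.noise_sd > 0:
            frame = frame + rng.normal(0.0, script.noise_sd, (h, w))
        frames[f] = np.clip(frame, 0.0, 1.0)
    return frames, mask
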
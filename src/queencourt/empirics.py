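"""Analysis of empirically tracked queen trajectories and court-event imagery.

The observational pipeline this mirrors: infrared stills of an observation
hive taken every 4 s, the queen tracked manually in pixels (1 mm ~ 5 px).
Queen court events (QCEs) are intervals where the queen's speed stays below
1 px/s for longer than 48 s. Event frames are cropped to 360 x 360 px around
the queen's mean position, and a per-pixel median across the (globally
normalised) event stack suppresses moving bees while keeping the static
queen and her court; the median image is then histogram-equalised. Court
sizes from events are compared between samples with a two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from skimage import exposure

__all__ = [
    "TrackedTrajectory",
    "QueenCourtEvent",
    "detect_qce",
    "crop_event_frames",
    "median_stack_image",
    "compare_court_distributions",
]


@dataclass
class TrackedTrajectory:
    """Timestamped pixel positions of a tracked queen."""

    times: np.ndarray  # seconds, strictly increasing
    x: np.ndarray  # px
    y: np.ndarray  # px
    frame_interval: float = 4.0  # nominal seconds between frames
    px_per_mm: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise ValueError("times, x, y must have equal length")
        if self.frame_interval <= 0 or self.px_per_mm <= 0:
            raise ValueError("frame_interval and px_per_mm must be > 0")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    # -- text IO: CSV with header + YAML metadata sidecar -----------------
    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "x_px": self.x, "y_px": self.y}).to_csv(
            path, index=False
        )
        meta = {"frame_interval": self.frame_interval, "px_per_mm": self.px_per_mm}
        with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def from_csv(cls, path) -> "TrackedTrajectory":
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".meta.yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
        return cls(
            df["time_s"].to_numpy(),
            df["x_px"].to_numpy(),
            df["y_px"].to_numpy(),
            frame_interval=float(meta.get("frame_interval", 4.0)),
            px_per_mm=float(meta.get("px_per_mm", 5.0)),
        )


@dataclass
class QueenCourtEvent:
    """A detected low-speed interval: the queen at rest amid her court.

    ``court_size`` is an annotation: counted manually on real imagery, or
    filled from ground truth for simulation-derived trajectories.
    """

    start_time: float
    end_time: float
    mean_position: tuple[float, float]
    start_index: int
    end_index: int  # inclusive sample index
    court_size: int | None = None

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def detect_qce(
    traj: TrackedTrajectory,
    speed_threshold_px_s: float = 1.0,
    min_duration_s: float = 48.0,
    inclusive_duration: bool = False,
) -> list[QueenCourtEvent]:
    """Detect queen court events: maximal runs of consecutive inter-sample
    intervals with speed below ``speed_threshold_px_s`` whose total duration
    exceeds ``min_duration_s`` (strictly, per the 'longer than 48 s' rule;
    set ``inclusive_duration=True`` for >=).

    Speeds are raw consecutive-sample displacements over the actual elapsed
    time, with no smoothing. ``mean_position`` averages the member samples.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(traj.times)
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    slow = disp / dt < speed_threshold_px_s

    events: list[QueenCourtEvent] = []
    i = 0
    n_int = slow.size
    while i < n_int:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_int and slow[j + 1]:
            j += 1
        # intervals i..j cover samples i..j+1
        duration = traj.times[j + 1] - traj.times[i]
        long_enough = (
            duration >= min_duration_s if inclusive_duration else duration > min_duration_s
        )
        if long_enough:
            sl = slice(i, j + 2)
            events.append(
                QueenCourtEvent(
                    start_time=float(traj.times[i]),
                    end_time=float(traj.times[j + 1]),
                    mean_position=(
                        float(traj.x[sl].mean()),
                        float(traj.y[sl].mean()),
                    ),
                    start_index=i,
                    end_index=j + 1,
                )
            )
        i = j + 1
    return events


def crop_event_frames(
    frames: np.ndarray, center_px: tuple[float, float], crop: int = 360
) -> np.ndarray:
    """Crop every frame to ``crop x crop`` px centred as close to ``center_px``
    (x, y in pixel coordinates; x = column, y = row) as the frame bounds
    allow — windows are clamped at the borders, never padded."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    _, h, w = frames.shape
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} larger than frame {w} x {h}")
    cx, cy = center_px
    x0 = int(np.clip(int(round(cx)) - crop // 2, 0, w - crop))
    y0 = int(np.clip(int(round(cy)) - crop // 2, 0, h - crop))
    return frames[:, y0 : y0 + crop, x0 : x0 + crop]


def median_stack_image(frames: np.ndarray) -> np.ndarray:
    """Median-stack background extraction of a court event.

    (1) normalise the whole stack jointly to its global min/max,
    (2) take the per-pixel median across frames,
    (3) histogram-equalise the result.

    Static structure (queen and court) survives the median; bees that moved
    between frames appear at any given pixel in fewer than half the frames
    and vanish. A fully constant stack degenerates to a mid-gray (0.5)
    image by convention. Returns a float image in [0, 1].
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.size == 0:
        raise ValueError("empty image stack")
    lo, hi = float(frames.min()), float(frames.max())
    if hi == lo:
        return np.full(frames.shape[1:], 0.5)
    norm = (frames - lo) / (hi - lo)
    med = np.median(norm, axis=0)
    if med.max() == med.min():
        return np.full(med.shape, 0.5)
    return exposure.equalize_hist(med)


def compare_court_distributions(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two court-size samples.

    Returns ``(U, p)`` with U the statistic of ``sample_a``. Small samples
    (combined n <= 20) without ties are tested by exact enumeration;
    otherwise the tie-corrected normal approximation is used (without
    continuity correction, so identical samples give p = 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)
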
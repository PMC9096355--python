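"""Scalar fields on the comb lattice.

The comb face is discretised into 1 x 1 cm patches. Two fields live on this
lattice: a *static* temperature field that marks the brood nest (warm centre,
cool rim), and a *dynamic* pheromone field fed by the queen's mandibular
pheromone emission and shaped by proportional decay plus conservative
8-neighbour diffusion. Agents move in continuous space but sense the patch
they stand on.

Units: patch values are abstract model units. For temperature, the rim maps
to 0.0, the taxis threshold to 1.0 (outer rim of the brood area, ~30-32 C)
and the brood centre to 2.0 (~36-38 C). Pheromone is measured in "pheromone
units" throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import convolve

__all__ = [
    "PatchGrid",
    "PheromoneParams",
    "TemperatureParams",
    "NEIGHBOR_OFFSETS",
    "NEIGHBOR_ANGLES_DEG",
    "build_temperature_field",
    "emit_pheromone",
    "decay_and_diffuse",
    "sense_patch",
    "neighbor_extreme",
    "neighbor_direction_maps",
    "neighbor_counts",
]

# Moore neighbourhood in the fixed tie-breaking order N, NE, E, SE, S, SW, W, NW.
# Offsets are (dx, dy) with +x east and +y north; the first extreme in this
# order wins ties, deterministically and independently of any RNG.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),  # N
    (1, 1),  # NE
    (1, 0),  # E
    (1, -1),  # SE
    (0, -1),  # S
    (-1, -1),  # SW
    (-1, 0),  # W
    (-1, 1),  # NW
)

# Heading (degrees, 0 = east, counterclockwise) toward each neighbour.
NEIGHBOR_ANGLES_DEG: np.ndarray = np.array(
    [90.0, 45.0, 0.0, 315.0, 270.0, 225.0, 180.0, 135.0]
)

_EIGHT_KERNEL = np.array([[1.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 1.0]])


@dataclass
class PatchGrid:
    """Lattice of scalar patch values covering one comb side.

    ``values`` has shape ``(width, height)`` and is indexed ``values[ix, iy]``
    with patch ``(ix, iy)`` covering the half-open square
    ``[ix, ix+1) x [iy, iy+1)`` cm.
    """

    width: int
    height: int
    patch_size: float = 1.0
    side: str = "A"
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("grid must be at least 3 x 3 patches")
        if self.values is None:
            self.values = np.zeros((self.width, self.height))
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (self.width, self.height):
                raise ValueError(
                    f"values shape {self.values.shape} does not match "
                    f"({self.width}, {self.height})"
                )

    # -- geometry ---------------------------------------------------------
    @property
    def extent_cm(self) -> tuple[float, float]:
        return self.width * self.patch_size, self.height * self.patch_size

    def patch_of(self, x: float, y: float) -> tuple[int, int]:
        """Patch containing continuous position ``(x, y)`` cm (floor rule)."""
        w, h = self.extent_cm
        if not (0.0 <= x < w and 0.0 <= y < h):
            raise ValueError(f"position ({x}, {y}) outside arena {w} x {h} cm")
        return int(x // self.patch_size), int(y // self.patch_size)

    def contains_patch(self, patch: tuple[int, int]) -> bool:
        ix, iy = patch
        return 0 <= ix < self.width and 0 <= iy < self.height

    def copy(self) -> "PatchGrid":
        return PatchGrid(
            self.width, self.height, self.patch_size, self.side, self.values.copy()
        )

    # -- text / image IO --------------------------------------------------
    def save_text(self, path) -> None:
        """Write the field as delimited text, one text row per patch row (y)."""
        np.savetxt(path, self.values.T, fmt="%.10g")

    @classmethod
    def load_text(cls, path, patch_size: float = 1.0, side: str = "A") -> "PatchGrid":
        rows = np.atleast_2d(np.loadtxt(path))
        values = rows.T
        return cls(values.shape[0], values.shape[1], patch_size, side, values)

    def save_png(self, path) -> None:
        """Grayscale heatmap for inspection (row 0 of the image = top, +y up)."""
        import imageio.v3 as iio

        v = self.values.T[::-1]  # rows = y, flipped for image convention
        lo, hi = float(v.min()), float(v.max())
        scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 255).astype(np.uint8))


@dataclass(frozen=True)
class PheromoneParams:
    """Queen-pheromone field dynamics: emission E, decay mu, diffusion D."""

    emission_rate: float = 10.0  # pheromone units emitted per step
    decay_fraction: float = 0.05  # proportion lost per step
    diffusion_coeff: float = 1.0  # fraction of patch content exported per step

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay_fraction <= 1.0:
            raise ValueError("decay_fraction must be in [0, 1]")
        if not 0.0 <= self.diffusion_coeff <= 1.0:
            raise ValueError("diffusion_coeff must be in [0, 1]")
        if self.emission_rate < 0.0:
            raise ValueError("emission_rate must be >= 0")


@dataclass(frozen=True)
class TemperatureParams:
    """Model-unit anchors of the brood temperature field.

    rim 0.0 (~24-26 C), threshold 1.0 (~30-32 C, the thermotaxis trigger),
    centre 2.0 (~36-38 C); linear in physical degrees between ~25 and ~37 C.
    """

    center_model_value: float = 2.0
    rim_model_value: float = 0.0
    threshold_model_value: float = 1.0

    def __post_init__(self) -> None:
        if not self.rim_model_value < self.threshold_model_value < self.center_model_value:
            raise ValueError("require rim < threshold < center")


def build_temperature_field(
    grid_dims: tuple[int, int],
    temp_params: TemperatureParams = TemperatureParams(),
    brood_center: tuple[float, float] | None = None,
    brood_radius: float = 8.0,
    side: str = "A",
    tol: float = 1e-8,
    max_iter: int = 1_000_000,
) -> PatchGrid:
    """Static brood-nest temperature field.

    The brood disc (patch centres within ``brood_radius`` cm of
    ``brood_center``) is clamped at the centre value and the boundary ring of
    patches at the rim value; the interior is relaxed with an 8-neighbour
    averaging diffusion until the largest per-patch change drops below
    ``tol``. The result is maximal at the brood centre, at the rim value on
    the boundary, and radially non-increasing from the centre.
    """
    width, height = grid_dims
    grid = PatchGrid(width, height, side=side)
    if brood_center is None:
        brood_center = (width / 2.0, height / 2.0)
    cx, cy = brood_center
    if not (0.0 <= cx <= width and 0.0 <= cy <= height):
        raise ValueError(f"brood_center {brood_center} outside grid {grid_dims}")
    if brood_radius <= 0:
        raise ValueError("brood_radius must be > 0")

    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    dist = np.hypot(xs[:, None] - cx, ys[None, :] - cy)
    disc = dist <= brood_radius
    # ensure at least the patch holding the centre is clamped
    nearest = np.unravel_index(np.argmin(dist), dist.shape)
    disc[nearest] = True

    boundary = np.zeros((width, height), dtype=bool)
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True

    clamp_hot = disc & ~boundary
    v = np.full((width, height), temp_params.rim_model_value)
    v[clamp_hot] = temp_params.center_model_value

    free = ~(clamp_hot | boundary)
    for _ in range(max_iter):
        avg = convolve(v, _EIGHT_KERNEL, mode="nearest") / 8.0
        delta = np.abs(avg[free] - v[free]).max() if free.any() else 0.0
        v[free] = avg[free]
        if delta < tol:
            break
    grid.values = v
    return grid


def emit_pheromone(
    field: PatchGrid, queen_patch: tuple[int, int], emission_rate: float = 10.0
) -> PatchGrid:
    """Deposit one step's emission onto the queen's patch; all else unchanged."""
    if not field.contains_patch(queen_patch):
        raise ValueError(f"queen_patch {queen_patch} outside grid")
    out = field.copy()
    out.values[queen_patch] += emission_rate
    return out


def neighbor_counts(width: int, height: int) -> np.ndarray:
    """Number of existing Moore neighbours per patch (3 corners, 5 edges, 8 interior)."""
    ones = np.ones((width, height))
    return convolve(ones, _EIGHT_KERNEL, mode="constant", cval=0.0)


@njit(cache=True)
def _decay_diffuse_kernel(values, mu, d, n_neighbors):  # pragma: no cover
    w, h = values.shape
    values *= 1.0 - mu
    if d == 0.0:
        return
    share = d * values / n_neighbors
    new = values - d * values
    for ix in range(w):
        for iy in range(h):
            inc = 0.0
            for k in range(8):
                nx = ix + _OFFSETS_ARR[k, 0]
                ny = iy + _OFFSETS_ARR[k, 1]
                if 0 <= nx < w and 0 <= ny < h:
                    inc += share[nx, ny]
            new[ix, iy] += inc
    values[:, :] = new


def _decay_diffuse_inplace(
    values: np.ndarray, mu: float, d: float, n_neighbors: np.ndarray
) -> None:
    """In-place decay-then-diffuse on a raw array (hot path used by the engine).

    Decay first (multiply by 1 - mu), then every patch exports a fraction
    ``d`` of its content split equally among its *existing* neighbours and
    keeps the remainder. No-flux boundary: shares of missing neighbours stay
    home implicitly because exports are divided by the existing-neighbour
    count. Total mass is multiplied by exactly (1 - mu).
    """
    _decay_diffuse_kernel(values, float(mu), float(d), n_neighbors)


def decay_and_diffuse(field: PatchGrid, params: PheromoneParams) -> PatchGrid:
    """Apply one step of proportional decay and conservative 8-neighbour diffusion."""
    if np.any(field.values < 0):
        raise ValueError("pheromone field has negative values")
    out = field.copy()
    n_nb = neighbor_counts(field.width, field.height)
    _decay_diffuse_inplace(out.values, params.decay_fraction, params.diffusion_coeff, n_nb)
    return out


def sense_patch(field: PatchGrid, position: tuple[float, float]) -> float:
    """Value of the patch containing a continuous position (half-open patches)."""
    return float(field.values[field.patch_of(*position)])


def neighbor_extreme(
    field: PatchGrid, patch: tuple[int, int], mode: str = "max"
) -> tuple[int, int]:
    """Moore neighbour with the extreme value; ties go to the first of
    N, NE, E, SE, S, SW, W, NW."""
    if not field.contains_patch(patch):
        raise ValueError(f"patch {patch} outside grid")
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    ix, iy = patch
    best_patch = None
    best_val = None
    for dx, dy in NEIGHBOR_OFFSETS:
        nb = (ix + dx, iy + dy)
        if not field.contains_patch(nb):
            continue
        val = field.values[nb]
        if best_val is None or (val > best_val if mode == "max" else val < best_val):
            best_val = val
            best_patch = nb
    return best_patch


_OFFSETS_ARR = np.array(NEIGHBOR_OFFSETS, dtype=np.int64)


@njit(cache=True)
def _direction_maps_kernel(values, angles):  # pragma: no cover
    w, h = values.shape
    max_dir = np.empty((w, h))
    min_dir = np.empty((w, h))
    for ix in range(w):
        for iy in range(h):
            best_max = -np.inf
            best_min = np.inf
            kmax = 0
            kmin = 0
            for k in range(8):
                nx = ix + _OFFSETS_ARR[k, 0]
                ny = iy + _OFFSETS_ARR[k, 1]
                if nx < 0 or nx >= w or ny < 0 or ny >= h:
                    continue
                v = values[nx, ny]
                if v > best_max:
                    best_max = v
                    kmax = k
                if v < best_min:
                    best_min = v
                    kmin = k
            max_dir[ix, iy] = angles[kmax]
            min_dir[ix, iy] = angles[kmin]
    return max_dir, min_dir


def neighbor_direction_maps(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch headings (degrees) toward the max- and min-valued neighbour.

    Vectorised counterpart of :func:`neighbor_extreme` used by the engine;
    edge patches compete only among existing neighbours and the strict
    comparisons keep the first-wins tie rule of the canonical neighbour
    order N, NE, E, SE, S, SW, W, NW.
    """
    return _direction_maps_kernel(np.ascontiguousarray(values), NEIGHBOR_ANGLES_DEG)
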
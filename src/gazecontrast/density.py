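"""Aligned Gaussian fixation-density maps, averages, differences, profiles.

Every analyzed fixation contributes an isotropic bivariate Gaussian of unit
mass (sd 0.3 degrees by default).  Before rendering, each face's fixations
are translated into a common reference frame by the translation that
minimizes the sum of squared differences between that face's AOI centers and
the mean AOI centers over all faces; the closed form is the mean of the
per-AOI center differences.  Pixel values are exact per-cell integrals of the
Gaussian (differences of the normal CDF along each axis), so a fixation well
inside the grid deposits almost exactly unit mass; out-of-grid mass is simply
lost and accounted for by ``mass_in_grid``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .model import AOI_NAMES, FaceLayout, FixationRecord

DEFAULT_SIGMA = 0.3  # deg


@dataclass(frozen=True)
class GridSpec:
    width: int  # pixels
    height: int
    pixel_size: float  # deg / pixel
    origin: tuple[float, float] = (0.0, 0.0)  # deg of pixel (0,0) top-left corner

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must have at least one pixel")

    @property
    def x_edges(self) -> np.ndarray:
        return self.origin[0] + self.pixel_size * np.arange(self.width + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.origin[1] + self.pixel_size * np.arange(self.height + 1)

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.pixel_size * (np.arange(self.width) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.pixel_size * (np.arange(self.height) + 0.5)


def grid_for_frame(frame, pixel_size: float = 0.0625, margin: float = 1.5) -> GridSpec:
    """A grid covering ``frame`` plus a margin on every side."""
    width = int(np.ceil((frame.width + 2 * margin) / pixel_size))
    height = int(np.ceil((frame.height + 2 * margin) / pixel_size))
    return GridSpec(
        width=width,
        height=height,
        pixel_size=pixel_size,
        origin=(frame.x0 - margin, frame.y0 - margin),
    )


@dataclass
class DensityMap:
    grid: GridSpec
    values: np.ndarray  # (height, width), non-negative for plain densities
    n_fixations: int
    mass_in_grid: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.height, self.grid.width):
            raise ValueError("values shape does not match grid")


@dataclass
class ProfileCurve:
    axis: str  # "x_profile" | "y_profile"
    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        expected = self.grid.width if self.axis == "x_profile" else self.grid.height
        if self.values.shape != (expected,):
            raise ValueError("profile length does not match grid")


# --- alignment --------------------------------------------------------------

def reference_centers(layouts: list[FaceLayout]) -> dict[str, tuple[float, float]]:
    """Mean AOI centers over all faces: the common reference frame."""
    out = {}
    for name in AOI_NAMES:
        cs = np.array([lay.aois[name].center for lay in layouts])
        out[name] = (float(cs[:, 0].mean()), float(cs[:, 1].mean()))
    return out


def align_translation(
    layout: FaceLayout, reference: dict[str, tuple[float, float]]
) -> tuple[float, float]:
    """Translation (dx, dy) minimizing sum of squared AOI-center differences.

    The SSD objective sum_a ||c_a + t - r_a||^2 is minimized in closed form by
    t = mean_a (r_a - c_a).
    """
    missing = set(AOI_NAMES) - set(reference)
    if missing:
        raise ValueError(f"reference missing AOIs: {sorted(missing)}")
    diffs = np.array(
        [
            (reference[name][0] - layout.aois[name].center[0],
             reference[name][1] - layout.aois[name].center[1])
            for name in AOI_NAMES
        ]
    )
    dx, dy = diffs.mean(axis=0)
    return (float(dx), float(dy))


def alignment_offsets(layouts: list[FaceLayout]) -> dict[str, tuple[float, float]]:
    ref = reference_centers(layouts)
    return {lay.face_id: align_translation(lay, ref) for lay in layouts}


# --- rendering --------------------------------------------------------------

def fixation_token_maps(
    xs: np.ndarray,
    ys: np.ndarray,
    grid: GridSpec,
    sigma: float = DEFAULT_SIGMA,
    dtype=np.float64,
) -> np.ndarray:
    """Per-fixation unit-mass pixel maps, shape (n, height, width).

    Pixel values are exact cell integrals of the isotropic Gaussian: the
    product of CDF differences along x and y.  This is the shared primitive
    of plain rendering and of the permutation resampler's fast path.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    cx = ndtr((grid.x_edges[None, :] - xs[:, None]) / sigma)  # (n, width+1)
    cy = ndtr((grid.y_edges[None, :] - ys[:, None]) / sigma)  # (n, height+1)
    mx = np.diff(cx, axis=1).astype(dtype)  # (n, width)
    my = np.diff(cy, axis=1).astype(dtype)  # (n, height)
    return my[:, :, None] * mx[:, None, :]


def _accumulate(maps: np.ndarray) -> np.ndarray:
    """Strictly sequential (index-order) sum of token maps; the deterministic
    reduction both the renderer and the resampler's exact path share."""
    out = np.zeros(maps.shape[1:], dtype=maps.dtype)
    for m in maps:
        out += m
    return out


def render_density(
    fixations: list[FixationRecord],
    offsets: dict[str, tuple[float, float]],
    grid: GridSpec,
    sigma: float = DEFAULT_SIGMA,
    weight_by_duration: bool = False,
) -> DensityMap:
    """Render pre-windowed fixations into a density map.

    ``offsets`` maps face_id to its alignment translation.  Each fixation is
    rendered at (x + dx, y + dy).  With duration weighting each Gaussian's
    mass is the fixation duration in seconds instead of 1.
    """
    if not fixations:
        return DensityMap(
            grid=grid,
            values=np.zeros((grid.height, grid.width)),
            n_fixations=0,
            mass_in_grid=0.0,
        )
    xs = np.array([f.x + offsets[f.face_id][0] for f in fixations])
    ys = np.array([f.y + offsets[f.face_id][1] for f in fixations])
    maps = fixation_token_maps(xs, ys, grid, sigma)
    if weight_by_duration:
        w = np.array([f.duration / 1000.0 for f in fixations])
        maps = maps * w[:, None, None]
    values = _accumulate(maps)
    return DensityMap(
        grid=grid,
        values=values,
        n_fixations=len(fixations),
        mass_in_grid=float(values.sum()),
    )


# --- map algebra ------------------------------------------------------------

def _check_grids(maps: list[DensityMap]) -> GridSpec:
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("grid mismatch between maps")
    return grid


def average_maps(maps: list[DensityMap]) -> DensityMap:
    if not maps:
        raise ValueError("cannot average zero maps")
    grid = _check_grids(maps)
    values = np.mean([m.values for m in maps], axis=0)
    return DensityMap(
        grid=grid,
        values=values,
        n_fixations=int(round(np.mean([m.n_fixations for m in maps]))),
        mass_in_grid=float(values.sum()),
    )


def difference_map(a: DensityMap, b: DensityMap) -> DensityMap:
    """Signed pixel-wise difference a - b (same grid)."""
    grid = _check_grids([a, b])
    values = a.values - b.values
    return DensityMap(
        grid=grid,
        values=values,
        n_fixations=a.n_fixations + b.n_fixations,
        mass_in_grid=float(values.sum()),
    )


def participant_difference_map(
    per_participant_a: list[DensityMap], per_participant_b: list[DensityMap]
) -> DensityMap:
    """Per-participant a - b, then averaged across participants."""
    if len(per_participant_a) != len(per_participant_b):
        raise ValueError("participant lists differ in length")
    diffs = [difference_map(a, b) for a, b in zip(per_participant_a, per_participant_b)]
    return average_maps(diffs)


def profile(dm: DensityMap, axis: str) -> ProfileCurve:
    """Marginal sum of a (possibly signed) map along one dimension.

    ``x_profile`` sums along the vertical dimension (a curve over x);
    ``y_profile`` sums along the horizontal dimension (a curve over y, i.e.
    over facial features from forehead to chin).
    """
    if axis == "x_profile":
        values = dm.values.sum(axis=0)
    elif axis == "y_profile":
        values = dm.values.sum(axis=1)
    else:
        raise ValueError(f"unknown profile axis {axis!r}")
    return ProfileCurve(axis=axis, values=values, grid=dm.grid)
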
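"""Canopy-height-model raster processing.

The core phenotyping computation: a sparse voxel grid is flattened into a
2D pixel grid holding the highest observed return per plan-view cell (a
canopy surface model), holes left by sparse LiDAR coverage are closed by
iterative neighbourhood interpolation, the soil surface under the crop is
estimated as a plane from the parcel's uncropped border strips, and the
crop stand is isolated by region growing before per-parcel height and
volume are measured.

Grids are indexed ``values[i, j]`` with ``i`` along x and ``j`` along y;
"row-major order" below means the flattened order of that array.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cloud import ParcelPolygon, VoxelGrid, points_in_polygon

__all__ = [
    "PixelGrid",
    "GroundPlane",
    "RegionMask",
    "ParcelSummary",
    "max_z_projection",
    "fill_missing_pixels",
    "fit_ground_plane",
    "subtract_ground",
    "grow_crop_region",
    "parcel_metrics",
]


class DegenerateSupportError(ValueError):
    """Ground-plane support region is too small or rank-deficient."""


@dataclass
class PixelGrid:
    """2D raster of z-values (m) with explicit missing cells (NaN).

    ``interpolated`` marks cells whose value was inferred rather than
    measured; it is carried through ground subtraction so parcel summaries
    can report the inferred fraction as a quality flag.
    """

    values: np.ndarray  # (nx, ny), NaN = missing
    resolution: tuple[float, float]
    origin: np.ndarray  # (2,) lower corner (not cell centre)
    frame: str = "local"
    interpolated: np.ndarray | None = None  # (nx, ny) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("pixel grid must be a 2D array with positive dimensions")
        self.resolution = (float(self.resolution[0]), float(self.resolution[1]))
        if min(self.resolution) <= 0:
            raise ValueError("pixel resolution must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        present = self.values[~np.isnan(self.values)]
        if present.size and not np.all(np.isfinite(present)):
            raise ValueError("pixel grid contains non-finite values")
        if self.interpolated is not None:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
            if self.interpolated.shape != self.values.shape:
                raise ValueError("interpolated mask must match grid shape")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of pixel-centre coordinates, shaped like ``values``."""
        nx, ny = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.resolution[0]
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.resolution[1]
        return np.meshgrid(xs, ys, indexing="ij")

    @property
    def cell_area(self) -> float:
        return self.resolution[0] * self.resolution[1]


@dataclass(frozen=True)
class GroundPlane:
    """Soil surface model h(x, y) = a0*x + a1*y + a2 under a parcel.

    A plane suffices because the seedbed was machine-prepared, leaving the
    soil locally planar even where the canopy hides it from the LiDAR.
    """

    a0: float
    a1: float
    a2: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.a0, self.a1, self.a2)):
            raise ValueError("ground plane coefficients must be finite")

    def height(self, x, y):
        return self.a0 * np.asarray(x) + self.a1 * np.asarray(y) + self.a2


@dataclass
class RegionMask:
    """Boolean mask of the grown crop region, congruent with its grid."""

    mask: np.ndarray  # (nx, ny) bool
    seed: tuple[int, int]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask[self.seed]:
            raise ValueError("region mask must contain its seed")

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ParcelSummary:
    """Per-parcel phenotype estimates."""

    parcel_id: str
    mean_height: float  # m, mean over region pixels
    volume: float  # m^3, negatives clamped to 0 in the sum
    n_pixels: int
    interpolated_fraction: float


def max_z_projection(grid: VoxelGrid) -> PixelGrid:
    """Collapse a voxel grid to the per-column maximum-z surface.

    Pixel (i, j) holds the centre z of the highest occupied voxel in
    column (i, j) — the max keeps the full length of each detectable
    plant — and columns with no occupied voxel are missing.  The raster
    covers the occupied columns' bounding box.
    """
    if len(grid) == 0:
        raise ValueError("cannot project an empty voxel grid")
    rx, ry, rz = grid.resolution
    ij = grid.indices[:, :2]
    lo = ij.min(axis=0)
    hi = ij.max(axis=0)
    shape = (int(hi[0] - lo[0] + 1), int(hi[1] - lo[1] + 1))
    kmax = np.full(shape, np.iinfo(np.int64).min, dtype=np.int64)
    cols = ij - lo
    np.maximum.at(kmax, (cols[:, 0], cols[:, 1]), grid.indices[:, 2])
    values = np.full(shape, np.nan)
    occ = kmax != np.iinfo(np.int64).min
    values[occ] = grid.origin[2] + (kmax[occ] + 0.5) * rz
    origin = grid.origin[:2] + lo * np.array([rx, ry])
    return PixelGrid(values, (rx, ry), origin, grid.frame)


_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def fill_missing_pixels(pixels: PixelGrid, min_valid_neighbors: int = 6) -> PixelGrid:
    """Close small holes by iterative 8-neighbour mean interpolation.

    Per iteration every missing pixel with at least ``min_valid_neighbors``
    valued 8-neighbours — judged on the grid as it stood at the start of
    the iteration, so the result is independent of scan order — receives
    the mean of those valued neighbours.  Iterates to fixpoint.  Measured
    pixels are never modified; the default 6-of-8 criterion keeps the fill
    from creeping into genuinely plant-free area.
    """
    values = pixels.values.copy()
    filled = np.zeros(values.shape, dtype=bool)
    while True:
        valid = ~np.isnan(values)
        nvalid = ndimage.convolve(valid.astype(float), _NEIGH_KERNEL, mode="constant", cval=0.0)
        zsum = ndimage.convolve(np.where(valid, values, 0.0), _NEIGH_KERNEL, mode="constant", cval=0.0)
        target = (~valid) & (np.rint(nvalid).astype(int) >= min_valid_neighbors)
        if not target.any():
            break
        values[target] = zsum[target] / nvalid[target]
        filled |= target
    prior = pixels.interpolated if pixels.interpolated is not None else False
    return PixelGrid(values, pixels.resolution, pixels.origin, pixels.frame, filled | prior)


def fit_ground_plane(pixels: PixelGrid, gross: ParcelPolygon, net: ParcelPolygon) -> GroundPlane:
    """Least-squares plane through the uncropped border of a parcel.

    The canopy is too dense for the LiDAR to see soil between plants, so
    the support is every valued pixel whose centre lies in the gross
    parcel but outside the net parcel (the trimmed end strips), where the
    surface is bare or near-bare soil.  Fits z = a0*x + a1*y + a2 by
    ordinary least squares over pixel centres.
    """
    xs, ys = pixels.cell_centers()
    valid = pixels.valid
    xy = np.column_stack([xs[valid], ys[valid]])
    support = points_in_polygon(xy, gross) & ~points_in_polygon(xy, net)
    x = xy[support, 0]
    y = xy[support, 1]
    z = pixels.values[valid][support]
    if x.size < 3:
        raise DegenerateSupportError(
            f"only {x.size} support pixels in gross-minus-net region (need >= 3)"
        )
    design = np.column_stack([x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateSupportError("support pixels are collinear; plane is unidentifiable")
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    return GroundPlane(float(coef[0]), float(coef[1]), float(coef[2]))


def subtract_ground(pixels: PixelGrid, plane: GroundPlane) -> PixelGrid:
    """Convert the surface raster to height above ground.

    Every valued pixel becomes z - h_ground(x, y) at the pixel centre;
    missing pixels stay missing.  Negative results (support noise, soil
    pixels below the fitted plane) are retained for diagnostics and only
    clamped later, in volume integration.
    """
    xs, ys = pixels.cell_centers()
    values = pixels.values - plane.height(xs, ys)
    values[~pixels.valid] = np.nan
    return PixelGrid(values, pixels.resolution, pixels.origin, pixels.frame, pixels.interpolated)


def grow_crop_region(heights: PixelGrid, threshold: float = 0.1) -> RegionMask:
    """Segment the crop stand by region growing from the tallest pixel.

    The seed is the global maximum (smallest row-major index on ties).
    Valued 8-neighbours of the region form the frontier, processed
    highest-first (row-major tie-break); a candidate joins iff its height
    is within ``threshold`` of the running region mean, which is updated
    incrementally.  A candidate that fails the test is discarded for good;
    growth stops when the frontier is exhausted.  The 0.1 m default
    separates the canopy (0.35-0.6 m) from bare border soil.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = heights.values
    valid = heights.valid
    if not valid.any():
        raise ValueError("cannot grow a region on an all-missing grid")
    nx, ny = values.shape
    flat = np.where(valid.ravel(), values.ravel(), -np.inf)
    seed_flat = int(np.argmax(flat))  # first max in row-major order
    seed = (seed_flat // ny, seed_flat % ny)

    mask = np.zeros(values.shape, dtype=bool)
    mask[seed] = True
    seen = np.zeros(values.shape, dtype=bool)  # pushed to frontier at some point
    seen[seed] = True
    total = float(values[seed])
    count = 1
    heap: list[tuple[float, int, int, int]] = []

    def push_neighbors(i: int, j: int) -> None:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and valid[a, b] and not seen[a, b]:
                    seen[a, b] = True
                    heapq.heappush(heap, (-values[a, b], a * ny + b, a, b))

    push_neighbors(*seed)
    while heap:
        negh, _, i, j = heapq.heappop(heap)
        if abs(-negh - total / count) <= threshold:
            mask[i, j] = True
            total += -negh
            count += 1
            push_neighbors(i, j)
        # else: permanently discarded
    return RegionMask(mask, seed)


def parcel_metrics(
    heights: PixelGrid,
    mask: RegionMask,
    cell_area: float | None = None,
    parcel_id: str = "",
) -> ParcelSummary:
    """Mean crop height and volume over the grown region.

    Volume is the sum of region pixel heights times the cell footprint
    (default the grid's own 0.04 x 0.04 = 0.0016 m^2); negative heights
    contribute zero to the volume but are kept in the mean as diagnostics.
    """
    if mask.mask.shape != heights.values.shape:
        raise ValueError("mask shape does not match grid shape")
    sel = mask.mask & heights.valid
    if not sel.any():
        raise ValueError("region mask selects no valued pixels")
    if cell_area is None:
        cell_area = heights.cell_area
    vals = heights.values[sel]
    mean_h = float(vals.mean())
    volume = float(np.clip(vals, 0.0, None).sum() * cell_area)
    if heights.interpolated is not None:
        interp_frac = float(heights.interpolated[sel].mean())
    else:
        interp_frac = 0.0
    return ParcelSummary(parcel_id, mean_h, volume, int(sel.sum()), interp_frac)
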
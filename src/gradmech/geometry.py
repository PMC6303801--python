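"""Spatial domain, vessel masks, distance maps and boundary-exclusion masks.

The imaged tissue is modelled as a rectangular domain partitioned into square
pixels. Lymphatic vessels are binary masks on that grid; they act as the
secretion source support of the reaction-diffusion model and as the reference
set for the distance-dependent summary statistic (mean intensity as a function
of the distance to the nearest vessel).

Conventions: pixel (0, 0) sits at the top-left, indexing is row-major, and
pixel (r, c) covers the half-open square
``[c*h, (c+1)*h) x [r*h, (r+1)*h)`` with ``h`` the pixel size in micrometres.
All distances are computed between pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class PixelGrid:
    """Regular pixel grid covering the imaged domain.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; both must be at least 2.
    pixel_size
        Edge length of a pixel in micrometres (default 1.0).
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (row, col) centre coordinates in micrometres, broadcastable."""
        h = self.pixel_size
        rows = (np.arange(self.n_rows) + 0.5) * h
        cols = (np.arange(self.n_cols) + 0.5) * h
        return rows[:, None], cols[None, :]

    def check_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.shape != self.shape:
            raise ValueError(
                f"image shape {image.shape} does not match grid {self.shape}"
            )
        return image


class VesselGeometry:
    """Set of L pairwise-disjoint binary vessel masks q_l on a grid.

    The union mask marks every vessel pixel; ``areas`` are the physical vessel
    areas |Omega_l| in square micrometres.
    """

    def __init__(self, grid: PixelGrid, masks: list[np.ndarray]):
        if len(masks) < 1:
            raise ValueError("at least one vessel mask is required")
        clean = []
        for m in masks:
            m = grid.check_image(m)
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("vessel masks must be strictly 0/1")
            clean.append(m.astype(bool))
        stack = np.stack(clean)
        if np.any(stack.sum(axis=0) > 1):
            raise ValueError("vessel masks must be pairwise disjoint")
        self.grid = grid
        self.masks = clean

    @classmethod
    def from_labels(cls, grid: PixelGrid, labels: np.ndarray) -> "VesselGeometry":
        """Build from a labelled mask image (0 = tissue, 1..L = vessel id)."""
        labels = grid.check_image(labels)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        if ids.size == 0:
            raise ValueError("labelled mask contains no vessel pixels")
        return cls(grid, [labels == i for i in ids])

    @property
    def n_vessels(self) -> int:
        return len(self.masks)

    @property
    def union_mask(self) -> np.ndarray:
        return np.logical_or.reduce(self.masks)

    @property
    def areas(self) -> np.ndarray:
        """|Omega_l| in um^2 for each vessel."""
        return np.array([m.sum() * self.grid.pixel_area for m in self.masks])

    def labels(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=np.int32)
        for i, m in enumerate(self.masks, start=1):
            out[m] = i
        return out


@dataclass(frozen=True)
class DistanceMap:
    """Per-pixel Euclidean distance (um) to the nearest vessel pixel centre."""

    grid: PixelGrid
    values: np.ndarray = field(repr=False)


@dataclass
class SummaryProfile:
    """Distance-binned mean intensity profile.

    ``mean_intensity`` is NaN for empty bins; ``n_pixels`` counts contributing
    pixels per bin. Bins are half-open ``[k*w, (k+1)*w)``.
    """

    bin_centres: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    bin_width: float

    @property
    def defined(self) -> np.ndarray:
        return self.n_pixels > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_um": self.bin_centres,
                "mean_intensity": self.mean_intensity,
                "n_pixels": self.n_pixels,
            }
        )


def distance_map(grid: PixelGrid, vessels: VesselGeometry) -> DistanceMap:
    """Euclidean distance transform to the nearest vessel pixel, in um.

    Distance is exactly zero on vessel pixels and measured centre-to-centre
    elsewhere.
    """
    union = vessels.union_mask
    if not union.any():
        raise ValueError("no vessel pixels")
    d = ndimage.distance_transform_edt(~union) * grid.pixel_size
    return DistanceMap(grid=grid, values=d)


def distance_average(
    image: np.ndarray,
    dmap: DistanceMap,
    bin_width: float = 1.0,
    include: np.ndarray | None = None,
) -> SummaryProfile:
    """Average pixel intensity as a function of distance to the nearest vessel.

    Pixels are grouped into half-open bins ``[k*w, (k+1)*w)`` of their distance
    values and the arithmetic mean of their intensities is taken per bin.
    ``include`` optionally restricts the computation to a pixel subset.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    image = dmap.grid.check_image(image)
    d = dmap.values
    if include is not None:
        include = dmap.grid.check_image(include).astype(bool)
        d = d[include]
        vals = image[include]
    else:
        d = d.ravel()
        vals = image.ravel()
    idx = np.floor(d / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1 if idx.size else 0
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = (np.arange(n_bins) + 0.5) * bin_width
    return SummaryProfile(
        bin_centres=centres,
        mean_intensity=means,
        n_pixels=counts,
        bin_width=bin_width,
    )


def boundary_margin_mask(grid: PixelGrid, depth: float) -> np.ndarray:
    """Mask (True = excluded) of pixels whose centre lies within ``depth`` of
    the domain boundary.

    Used to remove boundary pixels from the objective function because the
    no-flux boundary condition is only an approximation of the real tissue.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rows, cols = grid.pixel_centres()
    h = grid.pixel_size
    dist_edge = np.minimum(
        np.minimum(rows, grid.n_rows * h - rows),
        np.minimum(cols, grid.n_cols * h - cols),
    )
    excluded = dist_edge < depth
    if excluded.all():
        raise ValueError("boundary margin excludes every pixel")
    return excluded


def generate_vessel_masks(
    grid: PixelGrid,
    n_vessels: int,
    radius_range: tuple[float, float] = (2.5, 5.0),
    min_separation: float = 4.0,
    margin: float = 6.0,
    elongation_range: tuple[float, float] = (1.0, 2.5),
    seed: int | np.random.Generator = 0,
    max_tries: int = 500,
) -> VesselGeometry:
    """Place ``n_vessels`` random disjoint elliptical vessel cross-sections.

    Radii and separations are in pixels; the masks keep at least ``margin``
    pixels away from the image boundary. Vessel shapes are ellipses with an
    aspect ratio drawn from ``elongation_range`` and a uniform orientation,
    which mimics tubular vessel sections cut at arbitrary angles. Raises if
    the separation constraint cannot be met within ``max_tries`` placements.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr = np.arange(grid.n_rows)[:, None]
    cc = np.arange(grid.n_cols)[None, :]
    masks: list[np.ndarray] = []
    occupied_dist = None  # distance (px) to already-placed masks
    for _ in range(n_vessels):
        placed = False
        for _attempt in range(max_tries):
            a = rng.uniform(*radius_range)
            elong = rng.uniform(*elongation_range)
            b = a / elong
            phi = rng.uniform(0, np.pi)
            extent = a + margin
            if 2 * extent >= grid.n_rows or 2 * extent >= grid.n_cols:
                continue  # vessel + margin does not fit on this grid
            r0 = rng.uniform(extent, grid.n_rows - extent)
            c0 = rng.uniform(extent, grid.n_cols - extent)
            dr, dc = rr - r0, cc - c0
            xr = dc * np.cos(phi) + dr * np.sin(phi)
            yr = -dc * np.sin(phi) + dr * np.cos(phi)
            mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
            if not mask.any():
                continue
            if occupied_dist is not None and occupied_dist[mask].min() < min_separation:
                continue
            masks.append(mask)
            dist_new = ndimage.distance_transform_edt(~mask)
            occupied_dist = (
                dist_new if occupied_dist is None else np.minimum(occupied_dist, dist_new)
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place vessel {len(masks) + 1}/{n_vessels} under the "
                f"separation constraint after {max_tries} tries"
            )
    return VesselGeometry(grid, masks)
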
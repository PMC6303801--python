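"""Bright-spot detection (MSER) and spot-statistics extraction.

High-intensity spots in the CCL21 immunostainings stem from intracellular
chemokine and are structured noise with respect to the extracellular
gradient model. The filtering baseline detects them as maximally stable
extremal regions (MSER) of the bright upper level sets and excludes the
covered pixels from the objective. The detected regions also provide the
empirical spot shape/size distributions that drive the synthetic-data
generator.

Detection semantics (bright-on-dark only): the image is quantized to
integer levels (8-bit min-max rescale for float input). For an integer
threshold t, the upper level set is ``U_t = {image >= t}``; its 8-connected
components are the extremal regions. A region R at threshold t has

    variation(R, t) = (|R^+| - |R^-|) / |R|

where R^+ is the component of ``U_{t-delta}`` containing R (the whole image
if t-delta falls below the minimum level) and R^- is the largest component
of ``U_{t+delta}`` contained in R (area 0 if none survive). A region is
maximally stable when its variation is at most ``max_variation`` and its
area lies in ``[min_area, max_area]``; among nested detections the most
stable (lowest-variation) one is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class Region:
    """A detected extremal region with second-moment ellipse descriptors.

    Areas and axes are in pixel units; orientation is the angle (radians,
    in [0, pi)) of the major axis measured from the column axis.
    """

    pixels: np.ndarray = field(repr=False)  # (n, 2) row/col indices
    area: float
    centroid: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float
    mean_intensity: float
    level: int
    variation: float

    @property
    def axis_ratio(self) -> float:
        return self.semi_minor / self.semi_major if self.semi_major > 0 else 1.0


def _ellipse_from_pixels(pix: np.ndarray) -> tuple[float, float, float]:
    """Semi-axes and orientation from normalized second central moments.

    For a solid ellipse the second moment along a principal axis equals
    (semi-axis)^2 / 4, so semi-axis = 2*sqrt(eigenvalue).
    """
    centred = pix - pix.mean(axis=0)
    # +1/12: moment of a unit square pixel about its own centre
    cov = centred.T @ centred / len(pix) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    semi_minor, semi_major = 2.0 * np.sqrt(np.maximum(evals, 0.0))
    vr, vc = evecs[:, 1]  # eigenvector of the larger eigenvalue (row, col)
    phi = np.arctan2(vr, vc) % np.pi
    return float(semi_major), float(semi_minor), float(phi)


def _quantize(image: np.ndarray) -> np.ndarray:
    """8-bit rescale for float input; integer images are used as-is.

    The rescale clips at the 1st/99th intensity percentiles so that a few
    extreme outlier pixels cannot compress the dynamic range of the bulk.
    """
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.int64)
    lo, hi = np.percentile(image, [1.0, 99.0])
    if hi == lo:
        return np.zeros(image.shape, dtype=np.int64)
    scaled = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    return np.round(scaled * 255.0).astype(np.int64)


def mser_detect(
    image: np.ndarray,
    delta: int = 10,
    min_area: int = 5,
    max_area: int | None = None,
    max_variation: float = 0.25,
) -> list[Region]:
    """Detect bright maximally stable extremal regions.

    ``delta`` is the threshold offset (in quantization steps) used for the
    stability test; ``max_area`` defaults to 1% of the image. Returns
    non-overlapping regions sorted by decreasing area. A constant image has
    no extremal structure and yields an empty list.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    q = _quantize(image)
    raw = np.asarray(image, dtype=float)
    n_pixels = q.size
    if max_area is None:
        max_area = max(int(0.01 * n_pixels), min_area)
    lo, hi = int(q.min()), int(q.max())
    if hi == lo:
        return []

    # label all upper level sets once; areas per (threshold, label)
    labels_by_t: dict[int, np.ndarray] = {}
    areas_by_t: dict[int, np.ndarray] = {}
    for t in range(lo, hi + 1):
        lab, _ = ndimage.label(q >= t, structure=_EIGHT)
        labels_by_t[t] = lab
        areas_by_t[t] = np.bincount(lab.ravel())

    candidates: dict[tuple[int, int], tuple[float, np.ndarray, int]] = {}
    for t in range(lo + 1, hi + 1):  # U_lo is the whole image, never a spot
        lab = labels_by_t[t]
        areas = areas_by_t[t]
        for comp in range(1, len(areas)):
            area = int(areas[comp])
            if not (min_area <= area <= max_area):
                continue
            sel = lab == comp
            rows, cols = np.nonzero(sel)
            # parent component at t - delta (whole image below the range)
            if t - delta < lo:
                area_plus = n_pixels
            else:
                plab = labels_by_t[t - delta]
                area_plus = int(areas_by_t[t - delta][plab[rows[0], cols[0]]])
            # largest surviving child component at t + delta
            if t + delta > hi:
                area_minus = 0
            else:
                clab = labels_by_t[t + delta][sel]
                counts = np.bincount(clab[clab > 0])
                area_minus = int(counts.max()) if counts.size else 0
            variation = (area_plus - area_minus) / area
            if variation > max_variation:
                continue
            # identical pixel sets recur across thresholds; keep most stable
            key = (int(np.ravel_multi_index((rows[0], cols[0]), q.shape)), area)
            prev = candidates.get(key)
            if prev is None or variation < prev[0]:
                candidates[key] = (variation, np.column_stack([rows, cols]), t)

    # nested/overlapping resolution: greedily keep the most stable
    claimed = np.zeros(q.shape, dtype=bool)
    regions: list[Region] = []
    for variation, pix, t in sorted(
        candidates.values(), key=lambda c: (c[0], -len(c[1]))
    ):
        if claimed[pix[:, 0], pix[:, 1]].any():
            continue
        claimed[pix[:, 0], pix[:, 1]] = True
        a, b, phi = _ellipse_from_pixels(pix.astype(float))
        regions.append(
            Region(
                pixels=pix,
                area=float(len(pix)),
                centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
                semi_major=a,
                semi_minor=b,
                orientation=phi,
                mean_intensity=float(raw[pix[:, 0], pix[:, 1]].mean()),
                level=t,
                variation=float(variation),
            )
        )
    regions.sort(key=lambda r: -r.area)
    return regions


def regions_to_mask(
    regions: list[Region], shape: tuple[int, int], dilation: int = 0
) -> np.ndarray:
    """Union of region pixel sets as a boolean exclusion mask, optionally
    morphologically dilated by ``dilation`` pixels (8-connectivity)."""
    mask = np.zeros(shape, dtype=bool)
    for r in regions:
        mask[r.pixels[:, 0], r.pixels[:, 1]] = True
    if dilation > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=_EIGHT, iterations=dilation)
    return mask


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "area_px2": [r.area for r in regions],
            "semi_major_px": [r.semi_major for r in regions],
            "semi_minor_px": [r.semi_minor for r in regions],
            "axis_ratio": [r.axis_ratio for r in regions],
            "orientation_rad": [r.orientation for r in regions],
            "centroid_row": [r.centroid[0] for r in regions],
            "centroid_col": [r.centroid[1] for r in regions],
            "mean_intensity": [r.mean_intensity for r in regions],
        }
    )


@dataclass(frozen=True)
class SpotDistribution:
    """Parametric spot statistics used by the artificial-data generator.

    area ~ LogNormal(log(area_scale), area_sigma) in px^2;
    axis ratio ~ Beta(ratio_a, ratio_b) on (0, 1];
    orientation ~ Uniform[0, pi);
    elevation factor ~ 1 + LogNormal(log(elev_scale), elev_sigma), so spots
    always brighten the image (factor > 1).
    """

    area_sigma: float = 0.6
    area_scale: float = 12.0
    ratio_a: float = 5.0
    ratio_b: float = 2.0
    elev_sigma: float = 0.5
    elev_scale: float = 1.5

    def mean_area(self) -> float:
        return float(
            scipy.stats.lognorm.mean(self.area_sigma, scale=self.area_scale)
        )

    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        area = scipy.stats.lognorm.rvs(
            self.area_sigma, scale=self.area_scale, size=n, random_state=rng
        )
        ratio = scipy.stats.beta.rvs(
            self.ratio_a, self.ratio_b, size=n, random_state=rng
        )
        ratio = np.clip(ratio, 1e-3, 1.0)
        orientation = rng.uniform(0.0, np.pi, size=n)
        elevation = 1.0 + scipy.stats.lognorm.rvs(
            self.elev_sigma, scale=self.elev_scale, size=n, random_state=rng
        )
        return {
            "area": area,
            "axis_ratio": ratio,
            "orientation": orientation,
            "elevation": elevation,
        }


def _lognorm_mle(x: np.ndarray) -> tuple[float, float]:
    """Closed-form ML fit of a log-normal with loc = 0: (shape, scale)."""
    logx = np.log(x)
    return max(float(logx.std()), 1e-6), float(np.exp(logx.mean()))


def _beta_fit(x: np.ndarray) -> tuple[float, float]:
    """ML beta fit on (0, 1) with a method-of-moments fallback for samples
    too degenerate for the MLE solver (e.g. all values near 1)."""
    try:
        a, b, _, _ = scipy.stats.beta.fit(x, floc=0, fscale=1)
        return float(a), float(b)
    except Exception:  # noqa: BLE001 - scipy FitSolverError and kin
        m, v = float(x.mean()), float(x.var())
        k = m * (1 - m) / v - 1.0 if v > 1e-12 else 1e3
        k = max(k, 1e-3)
        return max(m * k, 1e-3), max((1 - m) * k, 1e-3)


def fit_spot_distributions(
    regions: list[Region], background: float
) -> SpotDistribution:
    """Maximum-likelihood fit of the spot statistics to detected regions.

    ``background`` is a reference intensity (e.g. the median outside the
    detected regions); the elevation factor of a region is its mean
    intensity divided by this reference. Requires at least 5 regions.
    """
    if len(regions) < 5:
        raise ValueError("need at least 5 regions to fit spot distributions")
    if not background > 0:
        raise ValueError("background must be strictly positive")
    areas = np.array([r.area for r in regions])
    ratios = np.clip(np.array([r.axis_ratio for r in regions]), 1e-6, 1.0 - 1e-9)
    elevations = np.array([r.mean_intensity for r in regions]) / background
    excess = elevations[elevations > 1.0] - 1.0
    if excess.size < 2:
        raise ValueError("too few regions brighter than background")
    s_area, scale_area = _lognorm_mle(areas)
    a, b = _beta_fit(ratios)
    s_elev, scale_elev = _lognorm_mle(excess)
    return SpotDistribution(
        area_sigma=float(s_area),
        area_scale=float(scale_area),
        ratio_a=float(a),
        ratio_b=float(b),
        elev_sigma=float(s_elev),
        elev_scale=float(scale_elev),
    )
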
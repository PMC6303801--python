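"""Artificial imaging datasets with known ground truth.

The generator emulates the experimental CCL21 immunostainings: a steady-state
gradient around seeded vessel masks, a configurable number of ellipsoidal
bright-spot artefacts with shape/size parameters sampled from the spot
distributions, and multiplicative log-normal pixel noise. Spots are rendered
before the noise is applied (they are part of the "true" corrupted intensity,
which is then measured with noise).

The packaged defaults define the study conditions: gradients decaying within
the image (decay length 8 um on a 64 x 64 um frame) and a noise level whose
closed-form signal-to-noise ratio is 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import SpotDistribution
from .forward_model import HeparanFieldSpec, ReducedParameters, steady_state_image
from .geometry import PixelGrid, VesselGeometry, generate_vessel_masks
from .noise_likelihood import NoiseModel, sample_noise

#: Default reduced parameters of the simulated gradients.
DEFAULT_REDUCED = ReducedParameters(d_over_gamma=64.0, rho=2.0, s_s0=100.0, bg=40.0)
#: Default noise level: closed-form SNR = 1/sqrt(e^{sigma^2}-1) equal to 6.
DEFAULT_SIGMA = float(np.sqrt(np.log(1.0 + 1.0 / 36.0)))
DEFAULT_NOISE = NoiseModel(sigma=DEFAULT_SIGMA)
#: Default spot-count grid for robustness suites.
DEFAULT_SPOT_COUNTS = (0, 40, 80, 160, 320, 620)
#: Median spot area in um^2 (a CCL21-expressing cell a few um across);
#: converted to pixel units per grid by :func:`default_spot_distribution`.
DEFAULT_SPOT_AREA_UM2 = 16.0


def default_spot_distribution(grid: PixelGrid) -> SpotDistribution:
    """Packaged spot statistics expressed in the pixel units of ``grid``."""
    return SpotDistribution(area_scale=DEFAULT_SPOT_AREA_UM2 / grid.pixel_area)


@dataclass(frozen=True)
class SpotInstance:
    """One ellipsoidal bright spot: centre (px), semi-axes (px), orientation
    (rad) and multiplicative intensity elevation factor (> 1)."""

    row: float
    col: float
    semi_major: float
    semi_minor: float
    orientation: float
    elevation: float

    def __post_init__(self) -> None:
        if not (self.semi_major > 0 and self.semi_minor > 0):
            raise ValueError("semi-axes must be positive")
        if not self.elevation > 1.0:
            raise ValueError("elevation factor must exceed 1")


@dataclass
class ArtificialDataset:
    """A generated dataset bundle with its full ground truth."""

    grid: PixelGrid
    vessels: VesselGeometry
    clean: np.ndarray = field(repr=False)
    noisy: np.ndarray = field(repr=False)
    params: ReducedParameters = DEFAULT_REDUCED
    spec: HeparanFieldSpec | None = None
    noise: NoiseModel = DEFAULT_NOISE
    spots: list[SpotInstance] = field(default_factory=list)
    seed: int = 0


def sample_spots(
    dist: SpotDistribution,
    n: int,
    grid: PixelGrid,
    seed: int | np.random.Generator = 0,
) -> list[SpotInstance]:
    """Draw ``n`` spots with centres uniform over the grid and shape/size
    parameters from the fitted spot distributions."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return []
    draws = dist.sample(n, rng)
    rows = rng.uniform(0.0, grid.n_rows, size=n)
    cols = rng.uniform(0.0, grid.n_cols, size=n)
    # area = pi * a * b with b = ratio * a
    semi_major = np.sqrt(draws["area"] / (np.pi * draws["axis_ratio"]))
    semi_minor = semi_major * draws["axis_ratio"]
    return [
        SpotInstance(
            row=float(rows[i]),
            col=float(cols[i]),
            semi_major=float(semi_major[i]),
            semi_minor=float(semi_minor[i]),
            orientation=float(draws["orientation"][i]),
            elevation=float(max(draws["elevation"][i], 1.0 + 1e-9)),
        )
        for i in range(n)
    ]


def spot_support(spot: SpotInstance, shape: tuple[int, int]) -> np.ndarray:
    """Boolean membership mask of a spot's ellipse over pixel centres."""
    rr = np.arange(shape[0])[:, None] - spot.row
    cc = np.arange(shape[1])[None, :] - spot.col
    co, si = np.cos(spot.orientation), np.sin(spot.orientation)
    xr = cc * co + rr * si
    yr = -cc * si + rr * co
    return (xr / spot.semi_major) ** 2 + (yr / spot.semi_minor) ** 2 <= 1.0


def render_spots(
    image: np.ndarray, spots: list[SpotInstance], mode: str = "multiplicative"
) -> np.ndarray:
    """Overlay bright-spot artefacts on a clean model image.

    In the default multiplicative mode the intensity inside each ellipse is
    multiplied by the spot's elevation factor (overlapping spots multiply),
    which keeps the image positive under the log-normal noise model. The
    additive mode adds ``(elevation - 1) * image`` contributions instead.
    """
    out = np.asarray(image, dtype=float).copy()
    base = np.asarray(image, dtype=float)
    for spot in spots:
        sel = spot_support(spot, out.shape)
        if mode == "multiplicative":
            out[sel] *= spot.elevation
        elif mode == "additive":
            out[sel] += (spot.elevation - 1.0) * base[sel]
        else:
            raise ValueError(f"unknown spot mode {mode!r}")
    return out


def generate_artificial_dataset(
    grid: PixelGrid,
    vessels: VesselGeometry,
    params: ReducedParameters = DEFAULT_REDUCED,
    spec: HeparanFieldSpec | None = None,
    noise: NoiseModel = DEFAULT_NOISE,
    n_spots: int = 0,
    seed: int = 0,
    spot_dist: SpotDistribution | None = None,
    spot_mode: str = "multiplicative",
) -> ArtificialDataset:
    """Full generation pipeline: steady-state image -> spots -> noise.

    Deterministic given (configuration, seed); the clean image equals the
    forward-model output exactly and is stored alongside the ground-truth
    parameters and the injected spot list. ``spot_dist`` defaults to the
    packaged physical spot statistics scaled to the grid's pixel size.
    """
    if spot_dist is None:
        spot_dist = default_spot_distribution(grid)
    ss = np.random.SeedSequence(seed)
    rng_spots, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    clean = steady_state_image(grid, vessels, params, spec)
    spots = sample_spots(spot_dist, n_spots, grid, rng_spots)
    corrupted = render_spots(clean, spots, mode=spot_mode)
    noisy = sample_noise(corrupted, noise, rng_noise)
    return ArtificialDataset(
        grid=grid,
        vessels=vessels,
        clean=clean,
        noisy=noisy,
        params=params,
        spec=spec,
        noise=noise,
        spots=spots,
        seed=seed,
    )


def default_scene(
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    n_vessels: int = 3,
    field_of_view: float = 64.0,
) -> tuple[PixelGrid, VesselGeometry]:
    """Seeded default imaging scene: grid plus random vessel geometry.

    The scene always represents a ``field_of_view`` x ``field_of_view`` um
    patch of tissue; coarser grids sample the same physical scene at a
    larger pixel size. The first vessel is a wide collecting-type section
    (10-13 um radius, wider than the default gradient decay length
    sqrt(D/gamma) = 8 um) and the remaining vessels are narrow initial
    capillaries (2.5-4.5 um radius), mirroring the heterogeneous vessel
    calibres seen in dermal tissue.
    """
    grid = PixelGrid(shape[0], shape[1], field_of_view / min(shape))
    h = grid.pixel_size
    ss = np.random.SeedSequence(seed)
    rng_large, rng_small = (np.random.default_rng(s) for s in ss.spawn(2))
    large = generate_vessel_masks(
        grid,
        n_vessels=1,
        radius_range=(10.0 / h, 13.0 / h),
        min_separation=6.0 / h,
        margin=4.0 / h,
        elongation_range=(1.0, 1.5),
        seed=rng_large,
    )
    masks = list(large.masks)
    if n_vessels > 1:
        # place the small vessels against the occupied large-vessel mask
        occupied = large.masks[0]
        from scipy import ndimage as _ndi

        occupied_dist = _ndi.distance_transform_edt(~occupied)
        for _ in range(n_vessels - 1):
            for _attempt in range(500):
                trial = generate_vessel_masks(
                    grid,
                    n_vessels=1,
                    radius_range=(2.5 / h, 4.5 / h),
                    min_separation=6.0 / h,
                    margin=4.0 / h,
                    elongation_range=(1.0, 2.0),
                    seed=rng_small,
                ).masks[0]
                if occupied_dist[trial].min() >= 6.0 / h:
                    break
            else:
                raise RuntimeError("could not place small vessels")
            masks.append(trial)
            occupied_dist = np.minimum(
                occupied_dist, _ndi.distance_transform_edt(~trial)
            )
    return grid, VesselGeometry(grid, [m.astype(np.uint8) for m in masks])
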
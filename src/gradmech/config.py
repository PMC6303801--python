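"""Run configuration: a YAML-serializable description of a full run.

Unknown keys are rejected on load so that typos in configuration files fail
loudly; the effective configuration of every CLI run is echoed back to the
output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .filtering import SpotDistribution
from .forward_model import HeparanFieldSpec, ReducedParameters
from .geometry import PixelGrid, VesselGeometry, generate_vessel_masks
from .noise_likelihood import NoiseModel
from .synthetic_data import DEFAULT_SIGMA


@dataclass
class GridConfig:
    n_rows: int = 64
    n_cols: int = 64
    pixel_size: float = 1.0


@dataclass
class GeometryConfig:
    n_vessels: int = 3
    radius_min: float = 2.5
    radius_max: float = 5.5
    min_separation: float = 6.0
    margin: float = 5.0


@dataclass
class ModelConfig:
    hypothesis: int = 1
    d_over_gamma: float = 64.0
    rho: float = 2.0
    s_s0: float = 100.0
    bg: float = 40.0
    tissue_level: float | None = None
    vessel_levels: list[float] = field(default_factory=list)


@dataclass
class NoiseConfig:
    sigma: float = DEFAULT_SIGMA
    w_o: float = 0.0
    mu_o: float = 0.0
    sigma_o: float = 1.0


@dataclass
class SpotConfig:
    n_spots: int = 0
    area_sigma: float = 0.6
    area_um2: float = 16.0
    ratio_a: float = 5.0
    ratio_b: float = 2.0
    elev_sigma: float = 0.5
    elev_scale: float = 1.5
    mode: str = "multiplicative"


@dataclass
class FitConfig:
    approach: str = "integrated"
    n_starts: int = 20
    boundary_depth: float = 0.0
    maxiter: int = 200
    mask_dilation: int = 1
    mser_delta: int = 10
    mser_min_area: int = 5
    mser_max_variation: float = 0.25


@dataclass
class ExperimentConfig:
    spot_counts: list[int] = field(default_factory=lambda: [0, 40, 80, 160, 320, 620])
    n_replicates: int = 30
    approaches: list[str] = field(
        default_factory=lambda: ["direct", "filtered", "integrated"]
    )
    bin_width: float = 1.0
    levels: list[float] = field(default_factory=lambda: [0.75, 0.90, 0.99])


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs"
    grid: GridConfig = field(default_factory=GridConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    spots: SpotConfig = field(default_factory=SpotConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    # -- construction helpers ------------------------------------------------

    def make_grid(self) -> PixelGrid:
        return PixelGrid(self.grid.n_rows, self.grid.n_cols, self.grid.pixel_size)

    def make_vessels(self, seed: int | None = None) -> VesselGeometry:
        g = self.geometry
        return generate_vessel_masks(
            self.make_grid(),
            n_vessels=g.n_vessels,
            radius_range=(g.radius_min, g.radius_max),
            min_separation=g.min_separation,
            margin=g.margin,
            seed=self.seed if seed is None else seed,
        )

    def make_params(self) -> ReducedParameters:
        m = self.model
        return ReducedParameters(
            d_over_gamma=m.d_over_gamma, rho=m.rho, s_s0=m.s_s0, bg=m.bg
        )

    def make_spec(self) -> HeparanFieldSpec | None:
        m = self.model
        if m.hypothesis == 1:
            return None if m.tissue_level is None else HeparanFieldSpec.uniform(m.tissue_level)
        return HeparanFieldSpec(
            model=m.hypothesis,
            tissue_level=m.tissue_level if m.tissue_level is not None else m.s_s0,
            vessel_levels=tuple(m.vessel_levels),
        )

    def make_noise(self) -> NoiseModel:
        n = self.noise
        return NoiseModel(sigma=n.sigma, w_o=n.w_o, mu_o=n.mu_o, sigma_o=n.sigma_o)

    def make_spot_dist(self) -> SpotDistribution:
        s = self.spots
        return SpotDistribution(
            area_sigma=s.area_sigma,
            area_scale=s.area_um2 / self.grid.pixel_size**2,
            ratio_a=s.ratio_a,
            ratio_b=s.ratio_b,
            elev_sigma=s.elev_sigma,
            elev_scale=s.elev_scale,
        )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return _from_dict(cls, data, "config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def _from_dict(cls, data: dict[str, Any], context: str):
    """Build a (possibly nested) dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _NESTED.get(name) if cls is RunConfig else None
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(sub, value, f"{context}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "grid": GridConfig,
    "geometry": GeometryConfig,
    "model": ModelConfig,
    "noise": NoiseConfig,
    "spots": SpotConfig,
    "fit": FitConfig,
    "experiment": ExperimentConfig,
}
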
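"""File input/output: TIFF images, CSV tables, YAML metadata, HDF5 results.

Model output images are written as 32-bit float TIFF; input images and
vessel masks are accepted in any integer or float dtype. Vessel masks may
come as one labelled TIFF (0 = tissue, 1..L = vessel) or as L binary TIFFs.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import PixelGrid, VesselGeometry
from .inference import FitResult, Param, ParameterSpace
from .synthetic_data import ArtificialDataset


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def read_vessels(
    paths: list[str | Path], pixel_size: float = 1.0
) -> VesselGeometry:
    """Read vessel masks from one labelled TIFF or several binary TIFFs."""
    images = [read_image(p) for p in paths]
    grid = PixelGrid(images[0].shape[0], images[0].shape[1], pixel_size)
    if len(images) == 1 and images[0].max() > 1:
        return VesselGeometry.from_labels(grid, images[0].astype(np.int64))
    return VesselGeometry(grid, [(im > 0).astype(np.uint8) for im in images])


def write_dataset(dataset: ArtificialDataset, out_dir: str | Path) -> Path:
    """Write an artificial dataset bundle (images, masks, ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / "noisy.tif", dataset.noisy)
    write_image(out / "clean.tif", dataset.clean)
    tifffile.imwrite(
        str(out / "vessel_labels.tif"),
        dataset.vessels.labels().astype(np.uint16),
    )
    pd.DataFrame(
        [
            {
                "row": s.row,
                "col": s.col,
                "semi_major": s.semi_major,
                "semi_minor": s.semi_minor,
                "orientation": s.orientation,
                "elevation": s.elevation,
            }
            for s in dataset.spots
        ]
    ).to_csv(out / "spots.csv", index=False)
    truth = {
        "seed": int(dataset.seed),
        "pixel_size": float(dataset.grid.pixel_size),
        "params": {
            "d_over_gamma": dataset.params.d_over_gamma,
            "rho": dataset.params.rho,
            "s_s0": dataset.params.s_s0,
            "bg": dataset.params.bg,
        },
        "noise": {
            "sigma": dataset.noise.sigma,
            "w_o": dataset.noise.w_o,
            "mu_o": dataset.noise.mu_o,
            "sigma_o": dataset.noise.sigma_o,
        },
        "n_spots": len(dataset.spots),
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
    return out


def write_fit(path: str | Path, fit: FitResult, attrs: dict | None = None) -> None:
    """Serialize a multi-start fit to HDF5 (starts, solutions, nll ladder)."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("starts", data=fit.starts)
        f.create_dataset("solutions", data=fit.solutions)
        f.create_dataset("nlls", data=fit.nlls)
        f.create_dataset("converged", data=fit.converged.astype(np.uint8))
        sp = f.create_group("space")
        sp.attrs["names"] = [p.name for p in fit.space.params]
        sp.attrs["scales"] = [p.scale for p in fit.space.params]
        sp.create_dataset("lo", data=[p.lo for p in fit.space.params])
        sp.create_dataset("hi", data=[p.hi for p in fit.space.params])
        for key, value in (attrs or {}).items():
            f.attrs[key] = value
        if fit.seed is not None:
            f.attrs["seed"] = fit.seed


def read_fit(path: str | Path) -> FitResult:
    with h5py.File(str(path), "r") as f:
        names = [str(n) for n in f["space"].attrs["names"]]
        scales = [str(s) for s in f["space"].attrs["scales"]]
        lo = f["space/lo"][:]
        hi = f["space/hi"][:]
        space = ParameterSpace(
            [Param(n, float(l), float(h), s) for n, l, h, s in zip(names, lo, hi, scales)]
        )
        return FitResult(
            space=space,
            starts=f["starts"][:],
            solutions=f["solutions"][:],
            nlls=f["nlls"][:],
            converged=f["converged"][:].astype(bool),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
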
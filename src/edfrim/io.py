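"""TIFF/YAML input-output and fixture generation.

Raster data travels as 32-bit float multi-page TIFF with a YAML sidecar
(``<stem>.yaml``) carrying acquisition metadata and the optics block; on
conflict between TIFF tags and sidecar, the sidecar wins. Point clouds go to
CSV, surface meshes to Wavefront OBJ with per-vertex grayscale.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .optics import GridGeometry, make_pupil, compute_psf3d, compute_edf_psf
from .optics import generate_speckle_ensemble, estimate_autocovariance
from .phantoms import (
    SpeckleStack,
    embed_on_surface,
    make_star_density,
    make_topography,
    simulate_acquisition,
)
from .topography import TexturedSurface, BrightPoints

logger = logging.getLogger("edfrim")

__all__ = [
    "PRESETS",
    "grid_from_config",
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "write_points_csv",
    "write_surface_obj",
    "make_fixtures",
    "load_config",
    "save_config",
]

# paper-scale and desk-scale optics presets: same pitches and optics, the
# desk grid is 4x smaller in every dimension
PRESETS: dict[str, dict[str, Any]] = {
    "paper_full": {
        "na": 0.8,
        "wavelength_nm": 530.0 / 1.3,
        "nx": 512,
        "ny": 512,
        "nz": 128,
        "dx_nm": 38.5,
        "dy_nm": 38.5,
        "dz_nm": 87.5,
    },
    "desk_small": {
        "na": 0.8,
        "wavelength_nm": 530.0 / 1.3,
        "nx": 128,
        "ny": 128,
        "nz": 32,
        "dx_nm": 38.5,
        "dy_nm": 38.5,
        "dz_nm": 87.5,
    },
}


def grid_from_config(cfg: dict[str, Any]) -> GridGeometry:
    return GridGeometry(
        nx=int(cfg["nx"]),
        ny=int(cfg["ny"]),
        nz=int(cfg["nz"]),
        dx=float(cfg["dx_nm"]),
        dy=float(cfg["dy_nm"]),
        dz=float(cfg["dz_nm"]),
    )


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_image(image: np.ndarray, path: str | Path, pixel_size_nm: float | None = None) -> None:
    path = Path(path)
    kwargs = {}
    if pixel_size_nm:
        # TIFF resolution tags are in pixels per unit; use micrometres
        per_um = 1000.0 / pixel_size_nm
        kwargs = {"resolution": (per_um, per_um), "resolutionunit": "MICROMETER"}
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32), photometric="minisblack", **kwargs)


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


def write_stack(stack: SpeckleStack, path: str | Path) -> None:
    """Multi-page float32 TIFF plus YAML sidecar with acquisition metadata."""
    path = Path(path)
    tifffile.imwrite(path, stack.images.astype(np.float32), photometric="minisblack")
    meta: dict[str, Any] = {
        "modality": stack.modality,
        "photon_budget": stack.photon_budget,
        "seeds": [int(s) for s in stack.seeds],
        "z_f": stack.z_f,
    }
    if stack.grid is not None:
        g = stack.grid
        meta["grid"] = {
            "nx": g.nx, "ny": g.ny, "nz": g.nz,
            "dx_nm": g.dx, "dy_nm": g.dy, "dz_nm": g.dz,
        }
    save_config(meta, _sidecar(path))


def read_stack(path: str | Path) -> SpeckleStack:
    """Read a stack and its sidecar; degrade gracefully without the sidecar."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        photometric = tf.pages[0].photometric
    if photometric == tifffile.PHOTOMETRIC.RGB or (
        arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] != arr.shape[-2]
    ):
        raise ValueError(
            f"{path} looks like a multi-channel/RGB image; expected a "
            "single-channel stack of speckled images"
        )
    if arr.ndim == 2:
        arr = arr[None]
    meta: dict[str, Any] = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = load_config(sidecar) or {}
    else:
        logger.warning("no sidecar %s: stack metadata unknown", sidecar)
    grid = grid_from_config(meta["grid"]) if "grid" in meta else None
    return SpeckleStack(
        images=arr,
        modality=meta.get("modality", "unknown"),
        photon_budget=meta.get("photon_budget"),
        seeds=[int(s) for s in meta.get("seeds", [])],
        grid=grid,
        z_f=meta.get("z_f"),
    )


def write_points_csv(points: BrightPoints, labels: np.ndarray, path: str | Path) -> None:
    rows = np.column_stack(
        [points.x, points.y, points.z, points.value, labels.astype(int)]
    )
    np.savetxt(
        path,
        rows,
        delimiter=",",
        header="x_nm,y_nm,z_nm,rhat,inlier",
        comments="",
        fmt=["%.3f", "%.3f", "%.3f", "%.6g", "%d"],
    )


def write_surface_obj(surface: TexturedSurface, path: str | Path) -> None:
    """Wavefront OBJ export; intensity becomes per-vertex grayscale color."""
    v = surface.vertices
    ny, nx = v.shape[:2]
    inten = surface.intensity
    vmax = inten.max() or 1.0
    with open(path, "w") as fh:
        for j in range(ny):
            for i in range(nx):
                gray = inten[j, i] / vmax
                fh.write(
                    f"v {v[j,i,0]:.2f} {v[j,i,1]:.2f} {v[j,i,2]:.2f} "
                    f"{gray:.4f} {gray:.4f} {gray:.4f}\n"
                )
        for j in range(ny - 1):
            for i in range(nx - 1):
                a = j * nx + i + 1
                b = a + 1
                c = a + nx
                d = c + 1
                fh.write(f"f {a} {b} {d}\nf {a} {d} {c}\n")


def make_fixtures(preset: str, out_dir: str | Path, seed: int = 0,
                  n_speckles: int = 100, n_cov_speckles: int = 64) -> dict[str, Path]:
    """Write the standard simulated inputs for a preset grid.

    Emits star/topography phantoms, the EDF PSF, a measured speckle
    auto-covariance, and an EDF acquisition stack of the flat star sample.
    """
    if preset not in PRESETS:
        raise ValueError(f"preset must be one of {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(PRESETS[preset])
    cfg["preset"] = preset
    cfg["seed"] = seed
    grid = grid_from_config(cfg)
    pupil = make_pupil(cfg["na"], cfg["wavelength_nm"], grid)

    files: dict[str, Path] = {}
    star = make_star_density(grid)
    files["star"] = out / "star_density.tif"
    write_image(star, files["star"], grid.dx)
    for kind in ("flat", "cone", "random"):
        zmap = make_topography(grid, kind, seed=seed)
        files[f"topo_{kind}"] = out / f"topography_{kind}.tif"
        write_image(zmap, files[f"topo_{kind}"], grid.dx)

    psf = compute_psf3d(pupil, grid)
    edf = compute_edf_psf(psf)
    files["edf_psf"] = out / "edf_psf.tif"
    write_image(edf.values, files["edf_psf"], grid.dx)

    speckles = generate_speckle_ensemble(
        pupil, n_cov_speckles, grid, seed=seed, z_indices=[0]
    )
    ens = estimate_autocovariance([s[0] for s in speckles])
    files["autocov"] = out / "speckle_autocov.tif"
    write_image(ens.autocov_slice, files["autocov"], grid.dx)

    sample = embed_on_surface(star, make_topography(grid, "flat"), grid)
    stack = simulate_acquisition(
        sample, pupil, n_speckles=n_speckles, photon_budget=1000.0,
        modality="edf", seed=seed, psf=psf,
    )
    files["stack"] = out / "edf_stack.tif"
    write_stack(stack, files["stack"])

    files["config"] = out / "optics.yaml"
    save_config(cfg, files["config"])
    return files
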
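"""Synthetic samples and the speckled-acquisition forward model.

Provides the star test object ``rho(r, theta) = 1 + cos(n_lobes * theta)``,
the three reference topographies (flat, right circular cone, uncorrelated
random heights), surface embedding ``rho(r, z) = rho_perp(r) delta(z - Z(r))``,
and simulators for single-plane images, EDF images, speckled image stacks and
plane-by-plane volume scans (with photon noise and an inhomogeneous
background for the topography pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .optics import (
    EDFPSF,
    GridGeometry,
    PSF3D,
    PupilMask,
    compute_edf_psf,
    compute_psf3d,
    generate_speckle,
)

__all__ = [
    "SampleVolume",
    "SpeckleStack",
    "make_star_density",
    "make_punctate_density",
    "make_topography",
    "embed_on_surface",
    "form_image",
    "form_edf_image",
    "simulate_acquisition",
    "simulate_volume_scan",
]


@dataclass(frozen=True)
class SampleVolume:
    """Fluorophore distribution on a single-valued surface.

    ``density3d`` places each lateral column's mass on the slice nearest to
    ``heightmap`` (nm), so the axial sum reproduces ``density2d`` exactly.
    """

    density2d: np.ndarray = field(repr=False)  # (ny, nx), >= 0
    heightmap: np.ndarray = field(repr=False)  # (ny, nx), nm
    density3d: np.ndarray = field(repr=False)  # (nz, ny, nx)
    slice_index: np.ndarray = field(repr=False)  # (ny, nx) int, occupied slice
    grid: GridGeometry = field(repr=False)


@dataclass
class SpeckleStack:
    """A stack of raw images acquired under independent speckles."""

    images: np.ndarray  # (N, ny, nx), >= 0
    modality: str  # "edf" | "plane" | "unknown"
    photon_budget: float | None
    seeds: list[int]
    grid: GridGeometry | None = None
    z_f: float | None = None  # focal plane for modality "plane", nm

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("images must be (N, ny, nx)")
        if self.images.shape[0] < 1:
            raise ValueError("empty stack")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]


# ---------------------------------------------------------------------------
# objects


def make_star_density(grid: GridGeometry, n_lobes: int = 40) -> np.ndarray:
    """Siemens-star density ``1 + cos(n_lobes * theta)``, values in [0, 2].

    Spatial frequency increases toward the center: the local azimuthal
    period at radius r is ``2 pi r / n_lobes``.
    """
    if n_lobes <= 0 or n_lobes % 2:
        raise ValueError("n_lobes must be an even positive integer")
    theta = np.arctan2(grid.y[:, None], grid.x[None, :])
    return 1.0 + np.cos(n_lobes * theta)


def make_punctate_density(
    grid: GridGeometry,
    n_puncta: int = 4000,
    radius_px: int = 2,
    seed: int | None = None,
) -> np.ndarray:
    """Sparse punctate fluorophore distribution (desmosome/junction-like).

    Bright disc-shaped puncta of ``radius_px`` pixels scattered uniformly
    over the field. Sparse markers are the regime where plane-by-plane
    surface detection works best: the integrated out-of-focus haze stays
    far below the in-focus puncta.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    density = np.zeros(grid.shape2d)
    iy = rng.integers(0, grid.ny, n_puncta)
    ix = rng.integers(0, grid.nx, n_puncta)
    amp = rng.uniform(0.5, 1.5, n_puncta)
    np.add.at(density, (iy, ix), amp)
    if radius_px > 0:
        r = np.hypot(*np.meshgrid(*[np.arange(-radius_px, radius_px + 1)] * 2))
        disc = (r <= radius_px).astype(float)
        density = np.fft.ifft2(
            np.fft.fft2(density)
            * np.fft.fft2(disc, s=grid.shape2d)
        ).real
        density = np.clip(density, 0.0, None)
    return density


def make_topography(
    grid: GridGeometry,
    kind: Literal["flat", "cone", "random"] = "flat",
    seed: int | None = None,
) -> np.ndarray:
    """Height map Z(r_perp) in nm over [0, nz * dz].

    flat
        constant mid-range height ``(nz // 2) * dz``.
    cone
        right circular cone: height ``nz * dz`` at r = 0 decreasing
        linearly to 0 at the base radius ``(nx / 2) * dx``, 0 outside.
    random
        i.i.d. uniform heights over the full z-range, no lateral
        correlation (requires a seed).
    """
    if kind == "flat":
        return np.full(grid.shape2d, (grid.nz // 2) * grid.dz)
    if kind == "cone":
        r = np.hypot(grid.y[:, None], grid.x[None, :])
        base = (grid.nx / 2) * grid.dx
        height = grid.nz * grid.dz
        return height * np.clip(1.0 - r / base, 0.0, 1.0)
    if kind == "random":
        if seed is None:
            raise ValueError("random topography requires a seed")
        rng = np.random.default_rng(seed)
        return rng.uniform(0.0, grid.z_range, size=grid.shape2d)
    raise ValueError(f"unknown topography kind {kind!r}")


def embed_on_surface(
    density2d: np.ndarray, heightmap: np.ndarray, grid: GridGeometry
) -> SampleVolume:
    """Place each column's mass on the slice nearest to Z(r_perp).

    Nearest-slice assignment (no sub-voxel splitting) keeps the projection
    identity ``sum_z density3d == density2d`` exact.
    """
    z = np.asarray(heightmap, dtype=float)
    if z.min() < 0 or z.max() > grid.z_range:
        raise ValueError("heightmap outside the grid z-range [0, nz*dz]")
    k = np.clip(np.rint(z / grid.dz).astype(int), 0, grid.nz - 1)
    density3d = np.zeros(grid.shape3d)
    iy, ix = np.indices(grid.shape2d)
    density3d[k, iy, ix] = density2d
    return SampleVolume(
        density2d=np.asarray(density2d, dtype=float),
        heightmap=z,
        density3d=density3d,
        slice_index=k,
        grid=grid,
    )


# ---------------------------------------------------------------------------
# image formation


def _conv2(image_f: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(image_f * transfer).real


def form_image(
    density3d: np.ndarray,
    speckle: np.ndarray,
    psf: PSF3D,
    z_f: float,
    grid: GridGeometry,
) -> np.ndarray:
    """Camera image at focal plane ``z_f`` (nm).

    ``I(r, z_f) = sum_z [(rho * S)(., z) conv2 h(., z_f - z)](r)``; the PSF
    slice at offset ``z_f - z`` is looked up circularly in z, so summing
    this image over all grid focal planes reproduces the EDF image exactly.
    """
    if density3d.shape != speckle.shape:
        raise ValueError("density and speckle shapes differ")
    z_planes = grid.z_planes
    if not (z_planes[0] - grid.dz / 2 <= z_f <= z_planes[-1] + grid.dz / 2):
        raise ValueError("z_f outside the simulated axial range")
    nz = psf.nz
    transfer = psf.slice_transfer()
    out_f = np.zeros(grid.shape2d, dtype=complex)
    excited = density3d * speckle
    occupied = np.nonzero(excited.reshape(excited.shape[0], -1).any(axis=1))[0]
    for k in occupied:
        offset = z_f - z_planes[k]
        # PSF slices are stored at offsets (i - nz//2) * dz; wrap circularly
        i = int(np.rint(offset / grid.dz)) % nz
        i = (i + nz // 2) % nz
        out_f += np.fft.fft2(excited[k]) * transfer[i]
    return np.fft.ifft2(out_f).real


def form_edf_image(
    density3d: np.ndarray,
    speckle: np.ndarray,
    psf: PSF3D | EDFPSF,
    grid: GridGeometry | None = None,
) -> np.ndarray:
    """EDF image: axial sum of the excited density convolved with h_perp."""
    if density3d.shape != speckle.shape:
        raise ValueError("density and speckle shapes differ")
    edf = compute_edf_psf(psf) if isinstance(psf, PSF3D) else psf
    projected = (density3d * speckle).sum(axis=0)
    return _conv2(np.fft.fft2(projected), edf.otf)


def _surface_excitation(
    sample: SampleVolume,
    pupil: PupilMask,
    envelope_sigma: float | None,
    seed,
    columnar: bool | None,
) -> np.ndarray:
    """rho_perp(r) * S(r, Z(r)) for one fresh speckle, computed only on the
    occupied slices of the surface sample."""
    occupied = np.unique(sample.slice_index)
    s = generate_speckle(
        pupil,
        sample.grid,
        envelope_sigma,
        seed=seed,
        z_indices=occupied,
        columnar=columnar,
    )
    lut = np.zeros(sample.grid.nz, dtype=int)
    lut[occupied] = np.arange(len(occupied))
    gather = lut[sample.slice_index]
    iy, ix = np.indices(sample.grid.shape2d)
    return sample.density2d * s[gather, iy, ix]


def simulate_acquisition(
    sample: SampleVolume,
    pupil: PupilMask,
    n_speckles: int,
    photon_budget: float | None = 1000.0,
    modality: str = "edf",
    seed: int | None = None,
    z_f: float | None = None,
    envelope_sigma: float | None = None,
    columnar: bool | None = None,
    read_noise_sd: float = 0.0,
    psf: PSF3D | None = None,
    illumination: str = "speckle",
) -> SpeckleStack:
    """Acquire ``n_speckles`` raw images under fresh speckled illuminations.

    Noiseless images are scaled so the *expected* (speckle-averaged) image
    peaks at ``photon_budget`` photons, then Poisson noise is applied
    (plus optional additive Gaussian read noise). ``photon_budget=None``
    disables noise and leaves the images in density units.
    ``illumination="uniform"`` replaces the speckles by S = 1 (useful to
    isolate photon statistics from speckle fluctuations).
    """
    if illumination not in ("speckle", "uniform"):
        raise ValueError("illumination must be 'speckle' or 'uniform'")
    if n_speckles < 2:
        raise ValueError("need at least 2 speckles")
    if photon_budget is not None and photon_budget <= 0:
        raise ValueError("photon_budget must be positive (or None for noiseless)")
    grid = sample.grid
    if psf is None:
        psf = compute_psf3d(pupil, grid)
    edf = compute_edf_psf(psf)
    if modality == "edf":
        reference = _conv2(np.fft.fft2(sample.density2d), edf.otf)
    elif modality == "plane":
        if z_f is None:
            raise ValueError("modality 'plane' requires z_f")
        reference = form_image(
            sample.density3d, np.ones_like(sample.density3d), psf, z_f, grid
        )
    else:
        raise ValueError(f"unknown modality {modality!r}")
    scale = 1.0 if photon_budget is None else photon_budget / reference.max()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_speckles)
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    images = np.empty((n_speckles, grid.ny, grid.nx))
    for m, child in enumerate(children):
        if illumination == "uniform":
            img = reference
        elif modality == "edf":
            excited = _surface_excitation(
                sample, pupil, envelope_sigma, child, columnar
            )
            img = _conv2(np.fft.fft2(excited), edf.otf)
        else:
            s = generate_speckle(
                pupil, grid, envelope_sigma, seed=child, columnar=columnar
            )
            img = form_image(sample.density3d, s, psf, z_f, grid)
        img = np.clip(img * scale, 0.0, None)
        if photon_budget is not None:
            img = noise_rng.poisson(img).astype(float)
            if read_noise_sd > 0:
                img += noise_rng.normal(0.0, read_noise_sd, size=img.shape)
        images[m] = img
    return SpeckleStack(
        images=images,
        modality=modality,
        photon_budget=photon_budget,
        seeds=[int(c.generate_state(1)[0]) for c in children],
        grid=grid,
        z_f=z_f,
    )


def simulate_volume_scan(
    sample: SampleVolume,
    pupil: PupilMask,
    z_planes: Sequence[float],
    seed: int,
    signal_photons: float = 1000.0,
    background_photons: float = 100.0,
    background_cv: float = 0.1,
    envelope_sigma: float | None = None,
    max_defocus: float = 4000.0,
) -> np.ndarray:
    """Plane-by-plane scan under a single speckled illumination.

    Emulates the acquisition used for topography estimation: at each focal
    plane the surface sample is imaged through the defocused PSF under one
    fixed speckle, Poisson photon noise is applied to the signal, and a
    smooth multiplicative background gain field ``a(x, y, z)`` (separable
    low-order ramps) with Gaussian fluctuations of coefficient of variation
    ``background_cv`` is added. Returns ``(n_planes, ny, nx)``.

    Defocus is evaluated exactly (no axial wrap-around): the PSF slice at
    every required focal offset is computed from the pupil. Source slices
    further than ``max_defocus`` (nm) from the focal plane are dropped —
    their light is spread so thin that it vanishes under the background
    (sub-photon per pixel at the default contrast).

    The signal is scaled so the brightest in-focus pixel averages
    ``signal_photons``; the background averages ``background_photons`` —
    their ratio sets the detection contrast of the surface.
    """
    grid = sample.grid
    ss = np.random.SeedSequence(seed)
    sp_seed, noise_seed = ss.spawn(2)
    rng = np.random.default_rng(noise_seed)

    excited = _surface_excitation(sample, pupil, envelope_sigma, sp_seed, None)
    excited3d = np.zeros(grid.shape3d)
    iy, ix = np.indices(grid.shape2d)
    excited3d[sample.slice_index, iy, ix] = excited

    occupied = np.unique(sample.slice_index)
    excited_f = {k: np.fft.fft2(excited3d[k]) for k in occupied}
    zg = grid.z_planes
    w = pupil.axial_frequency()
    sup = pupil.amplitude
    # Parseval: every defocus slice carries sum(P^2)/N; normalize like a
    # unit-sum 3D PSF over the grid depth
    norm = (sup ** 2).sum() / (grid.nx * grid.ny) * grid.nz

    # smooth separable gain ramps, mean ~= background_photons
    gx = 1.0 + 0.5 * np.linspace(-1, 1, grid.nx) + 0.2 * np.linspace(-1, 1, grid.nx) ** 2
    gy = 1.0 + 0.3 * np.linspace(-1, 1, grid.ny)
    volume = np.empty((len(z_planes), grid.ny, grid.nx))
    zspan = max(float(np.ptp(np.asarray(z_planes))), grid.dz)
    peak = 0.0
    planes = []
    for z_f in z_planes:
        ks = [k for k in occupied if abs(z_f - zg[k]) <= max_defocus]
        out_f = np.zeros(grid.shape2d, dtype=complex)
        for start in range(0, len(ks), 16):
            chunk = ks[start : start + 16]
            offs = np.array([z_f - zg[k] for k in chunk])
            fields = np.fft.ifft2(
                sup[None] * np.exp(2j * np.pi * offs[:, None, None] * w[None]),
                axes=(-2, -1),
            )
            slices = np.abs(fields) ** 2 / norm  # kernel origin at [0, 0]
            transfer = np.fft.fft2(slices, axes=(-2, -1))
            for j, k in enumerate(chunk):
                out_f += excited_f[k] * transfer[j]
        img = np.clip(np.fft.ifft2(out_f).real, 0.0, None)
        planes.append(img)
        peak = max(peak, img.max())
    sig_scale = signal_photons / peak if peak > 0 else 0.0
    for j, (z_f, img) in enumerate(zip(z_planes, planes)):
        gz = 1.0 + 0.2 * (z_f - np.min(z_planes)) / zspan
        gain = background_photons * gz * gy[:, None] * gx[None, :]
        background = gain * (1.0 + background_cv * rng.standard_normal(grid.shape2d))
        signal = rng.poisson(img * sig_scale).astype(float)
        volume[j] = background + signal
    return volume
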
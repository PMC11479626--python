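"""Scalar-diffraction optical model and speckle synthesis.

This module builds the ingredients of speckled extended-depth-of-field (EDF)
imaging: the binary pupil (disc or annulus), the 3D intensity point-spread
function ``h`` obtained by angular-spectrum defocus propagation, the EDF PSF
``h_perp = sum_z h(., z)`` and its optical transfer function, and random
speckle illumination volumes synthesized from random-phase pupil masks.

Conventions (used throughout the package):

* 2D arrays are indexed ``(y, x)``; 3D arrays ``(z, y, x)``. All lengths are
  in nanometres, all spatial frequencies in 1/nm (cycles per nm).
* Frequency grids follow ``numpy.fft`` layout: DC at index ``[0, 0]``.
* Real-space kernels (PSF slices, EDF PSF, auto-covariances) are stored
  *centered*, with the origin at pixel ``(ny//2, nx//2)`` (and ``nz//2``
  axially); use :func:`kernel_otf` to obtain the transfer function of a
  centered kernel.
* The axial coordinate of volume slice ``k`` is ``k * dz``; PSF slice
  offsets are centered on focus, ``(k - nz//2) * dz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GridGeometry",
    "PupilMask",
    "PSF3D",
    "EDFPSF",
    "SpeckleEnsemble",
    "make_pupil",
    "compute_psf3d",
    "compute_edf_psf",
    "generate_speckle",
    "generate_speckle_ensemble",
    "estimate_autocovariance",
    "speckle_autocovariance",
    "kernel_otf",
]


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid of the simulated sample space.

    Parameters
    ----------
    nx, ny, nz : int
        Voxel counts along x, y (lateral) and z (axial).
    dx, dy : float
        Lateral voxel pitch in nm.
    dz : float
        Axial voxel pitch in nm.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel pitches must be > 0")

    # -- real-space coordinates (pixel-centered, origin at index n//2) ----
    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) - self.nx // 2) * self.dx

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny // 2) * self.dy

    @property
    def z_offsets(self) -> np.ndarray:
        """Axial slice offsets centered on focus (nm)."""
        return (np.arange(self.nz) - self.nz // 2) * self.dz

    @property
    def z_planes(self) -> np.ndarray:
        """Axial slice positions of a sample volume, ``k * dz`` (nm)."""
        return np.arange(self.nz) * self.dz

    @property
    def z_range(self) -> float:
        return self.nz * self.dz

    @property
    def shape2d(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    # -- frequency-space coordinates (numpy.fft layout, DC at [0, 0]) -----
    @property
    def kx(self) -> np.ndarray:
        return np.fft.fftfreq(self.nx, d=self.dx)

    @property
    def ky(self) -> np.ndarray:
        return np.fft.fftfreq(self.ny, d=self.dy)

    @property
    def k_perp(self) -> np.ndarray:
        """Radial transverse frequency |k| on the (ny, nx) grid, 1/nm."""
        return np.hypot(self.ky[:, None], self.kx[None, :])

    def supports_band(self, cutoff: float) -> bool:
        """Whether the lateral sampling resolves frequencies up to ``cutoff``."""
        return 1.0 / (2 * self.dx) > cutoff and 1.0 / (2 * self.dy) > cutoff

    def nyquist_ok_for_reconstruction(self, wavelength: float, na: float) -> bool:
        """Check ``dx <= lambda / (8 NA)``: Nyquist for the doubled band.

        The variance channel carries frequencies up to twice the incoherent
        cutoff ``2 NA / lambda``; reconstruction grids must sample at least
        at half that period.
        """
        limit = wavelength / (8 * na)
        return self.dx <= limit and self.dy <= limit


# ---------------------------------------------------------------------------
# pupil


@dataclass(frozen=True)
class PupilMask:
    """Binary pupil over the transverse frequency grid.

    ``amplitude`` is 1 inside the support and 0 outside, with cutoff
    frequency ``na / wavelength``. ``wavelength`` is the in-medium
    wavelength in nm.
    """

    na: float
    wavelength: float
    kind: Literal["disc", "annulus"]
    annulus_inner_fraction: float
    amplitude: np.ndarray = field(repr=False)
    grid: GridGeometry = field(repr=False)

    @property
    def cutoff(self) -> float:
        """Pupil cutoff frequency NA/lambda in 1/nm."""
        return self.na / self.wavelength

    def defocus_phase(self, z: float) -> np.ndarray:
        """Angular-spectrum defocus factor ``exp(i 2 pi z w(k))`` on the support.

        ``w(k) = sqrt(1/lambda^2 - k^2)`` is the axial spatial frequency of a
        plane wave with transverse frequency ``k``.
        """
        return np.exp(2j * np.pi * z * self.axial_frequency())

    def axial_frequency(self) -> np.ndarray:
        k2 = self.grid.k_perp ** 2
        w2 = np.maximum(1.0 / self.wavelength ** 2 - k2, 0.0)
        return np.sqrt(w2)

    def ring_averaged_axial_frequency(self) -> float:
        """Mean of w(k) over the pupil support (for columnar propagation)."""
        sup = self.amplitude > 0
        return float(self.axial_frequency()[sup].mean())


def make_pupil(
    na: float,
    wavelength: float,
    grid: GridGeometry,
    kind: Literal["disc", "annulus"] = "disc",
    annulus_inner_fraction: float = 0.0,
) -> PupilMask:
    """Build a binary disc or annulus pupil with cutoff ``na/wavelength``.

    Raises if the lateral sampling cannot represent the cutoff (aliasing) or
    if the annulus inner fraction is outside (0, 1).
    """
    if na <= 0 or wavelength <= 0:
        raise ValueError("na and wavelength must be positive")
    cutoff = na / wavelength
    if not grid.supports_band(cutoff):
        raise ValueError(
            f"grid pitch dx={grid.dx} nm cannot represent the pupil cutoff "
            f"{cutoff:.3e} 1/nm (needs dx < lambda/(2 NA) = {1/(2*cutoff):.1f} nm)"
        )
    k = grid.k_perp
    if kind == "disc":
        if annulus_inner_fraction not in (0, 0.0):
            raise ValueError("annulus_inner_fraction must be 0 for a disc pupil")
        amplitude = (k <= cutoff).astype(np.float64)
    elif kind == "annulus":
        f = annulus_inner_fraction
        if not 0.0 < f < 1.0:
            raise ValueError("annulus_inner_fraction must be in (0, 1)")
        amplitude = ((k > f * cutoff) & (k <= cutoff)).astype(np.float64)
        if not amplitude.any():
            # thin annulus below grid resolution: keep the outermost in-band ring
            in_band = k <= cutoff
            rmax = k[in_band].max()
            df = min(1.0 / (grid.nx * grid.dx), 1.0 / (grid.ny * grid.dy))
            amplitude = (in_band & (k > rmax - df)).astype(np.float64)
    else:
        raise ValueError(f"unknown pupil kind {kind!r}")
    return PupilMask(
        na=na,
        wavelength=wavelength,
        kind=kind,
        annulus_inner_fraction=float(annulus_inner_fraction),
        amplitude=amplitude,
        grid=grid,
    )


# ---------------------------------------------------------------------------
# PSFs


@dataclass(frozen=True)
class PSF3D:
    """3D intensity PSF, unit total sum, slices centered at (ny//2, nx//2)."""

    values: np.ndarray = field(repr=False)  # (nz, ny, nx), sum == 1
    z_offsets: np.ndarray = field(repr=False)  # (nz,), nm, centered on focus

    @property
    def nz(self) -> int:
        return self.values.shape[0]

    def slice_transfer(self) -> np.ndarray:
        """FFT of each (centered) slice, shape (nz, ny, nx)."""
        return np.fft.fft2(np.fft.ifftshift(self.values, axes=(-2, -1)))


@dataclass(frozen=True)
class EDFPSF:
    """Extended-depth-of-field PSF ``h_perp`` (axial sum of the 3D PSF)."""

    values: np.ndarray = field(repr=False)  # (ny, nx), sum == 1, centered
    otf: np.ndarray = field(repr=False)  # fft2 of the (de-centered) values


def kernel_otf(kernel: np.ndarray) -> np.ndarray:
    """Transfer function of a centered real-space kernel (2D)."""
    return np.fft.fft2(np.fft.ifftshift(kernel))


def compute_psf3d(pupil: PupilMask, grid: GridGeometry | None = None) -> PSF3D:
    """Intensity PSF ``h(r_perp, z) = |F^-1{P(k) e^{i 2 pi z w(k)}}|^2``.

    The whole volume is normalized to unit sum; slices are even in z for the
    aberration-free binary pupil.
    """
    grid = grid or pupil.grid
    w = pupil.axial_frequency()
    sup = pupil.amplitude
    vols = np.empty(grid.shape3d)
    for i, z in enumerate(grid.z_offsets):
        field_ = np.fft.ifft2(sup * np.exp(2j * np.pi * z * w))
        vols[i] = np.fft.fftshift(np.abs(field_) ** 2)
    vols /= vols.sum()
    return PSF3D(values=vols, z_offsets=grid.z_offsets.copy())


def compute_edf_psf(psf: PSF3D) -> EDFPSF:
    """EDF PSF ``h_perp = sum_z h(., z)`` with its cached OTF."""
    values = psf.values.sum(axis=0)
    return EDFPSF(values=values, otf=kernel_otf(values))


# ---------------------------------------------------------------------------
# speckle synthesis


def _speckle_mask(
    pupil: PupilMask, envelope_sigma: float | None
) -> np.ndarray:
    """Pupil amplitude, optionally shaped by a Gaussian frequency envelope,
    scaled to unit mean speckle intensity.

    The default (``envelope_sigma=None``) is a *fully developed* speckle:
    uniform weight across the whole pupil support, so the illumination
    power spectrum extends to the pupil edge and the variance channel
    carries the full doubled band. A finite ``envelope_sigma`` (1/nm)
    apodizes the pupil, which lengthens the speckle correlation at the
    price of the outer spectral band.
    """
    k = pupil.grid.k_perp
    if envelope_sigma is None:
        mask = pupil.amplitude.astype(float).copy()
    else:
        if envelope_sigma <= 0:
            raise ValueError("envelope_sigma must be > 0")
        mask = pupil.amplitude * np.exp(-(k ** 2) / (2.0 * envelope_sigma ** 2))
    n = mask.size
    # mean intensity <|ifft2(M e^{i phi})|^2> = sum(M^2)/n^2; scale to 1
    mask *= n / np.sqrt((mask ** 2).sum())
    return mask


def generate_speckle(
    pupil: PupilMask,
    grid: GridGeometry | None = None,
    envelope_sigma: float | None = None,
    seed: int | np.random.SeedSequence | None = None,
    z_indices: Sequence[int] | None = None,
    columnar: bool | None = None,
) -> np.ndarray:
    """One 3D speckle intensity volume from a random-phase pupil mask.

    The field on the mask support gets i.i.d. uniform phases on [0, 2pi), a
    Gaussian frequency envelope (default FWHM = pupil radius), and is
    propagated to each slice ``z = k * dz`` with the angular-spectrum
    defocus phase; the returned volume is ``|field|^2`` per slice, with unit
    ensemble-mean intensity. Deterministic for a given seed.

    ``columnar`` replaces ``w(k)`` by its ring average so the intensity is
    exactly invariant along z (idealized Bessel speckle). It defaults to
    True for annular pupils and False for disc pupils: on a pixelated grid a
    thin annulus has finite radial width, and literal propagation would lose
    the axial invariance that is the point of Bessel speckles.

    ``z_indices`` restricts which slices are computed (others are skipped);
    the output is then ``(len(z_indices), ny, nx)``.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    grid = grid or pupil.grid
    if columnar is None:
        columnar = pupil.kind == "annulus"
    rng = np.random.default_rng(seed)
    mask = _speckle_mask(pupil, envelope_sigma)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=mask.shape)
    field0 = mask * np.exp(1j * phases)
    if columnar:
        # intensity is z-invariant: compute one slice and broadcast
        s0 = np.abs(np.fft.ifft2(field0)) ** 2
        nsl = grid.nz if z_indices is None else len(z_indices)
        return np.broadcast_to(s0, (nsl,) + s0.shape).copy()
    w = pupil.axial_frequency()
    z_planes = grid.z_planes
    idx = range(grid.nz) if z_indices is None else z_indices
    out = np.empty((len(list(idx)), grid.ny, grid.nx))
    idx = range(grid.nz) if z_indices is None else z_indices
    for j, k in enumerate(idx):
        fz = np.fft.ifft2(field0 * np.exp(2j * np.pi * z_planes[k] * w))
        out[j] = np.abs(fz) ** 2
    return out


def generate_speckle_ensemble(
    pupil: PupilMask,
    n: int,
    grid: GridGeometry | None = None,
    envelope_sigma: float | None = None,
    seed: int | None = None,
    z_indices: Sequence[int] | None = None,
    columnar: bool | None = None,
) -> list[np.ndarray]:
    """n independent speckle volumes with per-realization child seeds."""
    ss = np.random.SeedSequence(seed)
    return [
        generate_speckle(
            pupil, grid, envelope_sigma, seed=child, z_indices=z_indices,
            columnar=columnar,
        )
        for child in ss.spawn(n)
    ]


# ---------------------------------------------------------------------------
# auto-covariance


@dataclass(frozen=True)
class SpeckleEnsemble:
    """Speckle realizations with their second-order statistics.

    ``autocov3d`` is the auto-covariance Gamma_S(x, y, z) stored centered
    (zero lag at index (nz//2, ny//2, nx//2)); ``autocov_slice`` is its
    z = 0 slice, Gamma_EDF(r_perp), centered at (ny//2, nx//2).
    """

    realizations: list[np.ndarray] = field(repr=False)
    mean_intensity: float
    autocov3d: np.ndarray = field(repr=False)
    autocov_slice: np.ndarray = field(repr=False)


def estimate_autocovariance(
    realizations: Sequence[np.ndarray], ensemble: bool = False
) -> SpeckleEnsemble:
    """Auto-covariance of a speckle ensemble.

    The default estimator subtracts the ensemble mean per voxel and spatially
    averages (Wiener-Khinchin, stationarity assumed):
    ``Gamma(lag) = mean_m IFFT(|FFT(S_m - mean)|^2) / Nvox``.
    With ``ensemble=True`` the covariance is instead computed between the
    central voxel and every other voxel, averaged over realizations only
    (no stationarity assumption) — slower converging, used for cross-checks.

    Realizations may be 2D ``(ny, nx)`` or 3D ``(nz, ny, nx)``; 2D inputs
    are treated as single-slice volumes.
    """
    if len(realizations) < 2:
        raise ValueError("need at least 2 realizations")
    arrs = [np.asarray(r) for r in realizations]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("realizations must share a common shape")
    stack = np.stack([a[None] if a.ndim == 2 else a for a in arrs])  # (M, nz, ny, nx)
    mean = stack.mean(axis=0)
    delta = stack - mean
    nz, ny, nx = stack.shape[1:]
    if ensemble:
        center = (nz // 2, ny // 2, nx // 2)
        ref = delta[:, center[0], center[1], center[2]]
        cov = np.einsum("m,mzyx->zyx", ref, delta) / stack.shape[0]
        # center the lag origin: cov is indexed by absolute position; shift
        # so that the reference voxel sits at the center index
        gamma = cov
    else:
        nvox = nz * ny * nx
        spec = np.abs(np.fft.fftn(delta, axes=(1, 2, 3))) ** 2
        gamma = np.fft.ifftn(spec.mean(axis=0), axes=(0, 1, 2)).real / nvox
        gamma = np.fft.fftshift(gamma)
    return SpeckleEnsemble(
        realizations=list(arrs),
        mean_intensity=float(mean.mean()),
        autocov3d=gamma,
        autocov_slice=gamma[nz // 2],
    )


def speckle_autocovariance(
    pupil: PupilMask, envelope_sigma: float | None = None
) -> np.ndarray:
    """Analytic lateral auto-covariance Gamma_EDF(r_perp) of the speckle.

    The field covariance is the inverse transform of the (envelope-weighted)
    pupil intensity; for independent uniform phases on the discrete pupil
    the intensity covariance is exactly

    ``Gamma(dr) = |C(dr)|^2 - sum_k M_k^4 / n^4``,

    the constant being the finite-mode (fourth-moment) correction to the
    circular-Gaussian limit — identical at every z for both disc and
    annular pupils. Returned centered at ``(ny//2, nx//2)``;
    ``Gamma(0) ~= 1`` (unit speckle contrast, minus the finite-mode term).
    """
    mask = _speckle_mask(pupil, envelope_sigma)
    n = mask.size
    c = np.fft.ifft2(mask ** 2) / n
    finite_mode = (mask ** 4).sum() / n ** 4
    return np.fft.fftshift(np.abs(c) ** 2 - finite_mode)
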
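# Methods

`edfrim` implements extended-depth-of-field random illumination microscopy
(EDF-RIM): super-resolved projective imaging of thick fluorescent samples
from stacks of images taken under random speckled illumination with an
axially extended detection PSF, plus robust estimation of the sample's
surface topography from a single plane-by-plane speckled scan.

## Image-formation model

With fluorophore density ρ(r⊥, z), illumination intensity S(r⊥, z) and
detection PSF h, a camera image focused at z_f is

    I(r⊥, z_f) = ∬ ρ(r'⊥, z') S(r'⊥, z') h(r⊥ − r'⊥, z_f − z') dr'⊥ dz'.

Sweeping the focal plane during one exposure integrates I over z_f, which
collapses the axial blur into the extended-depth PSF h⊥(r⊥) = ∫ h(r⊥, z) dz:

    I⊥(r⊥) = ∬ ρ S h⊥(r⊥ − r'⊥) dr'⊥ dz'.

The model is scalar-diffraction: a binary pupil (disc, or annulus for
Bessel-type illumination) with cutoff NA/λ, defocus applied as the
angular-spectrum phase exp(i2πz·w(k)), w(k) = √(1/λ² − k²), λ the in-medium
wavelength. The 3D PSF is normalized to unit sum over the simulated volume
so EDF summation and photon bookkeeping are exact.

Discretely, the axial axis is treated circularly (a PSF slice at offset Δz
is looked up mod the grid depth), which makes the identity "sum of all
focal-plane images = EDF image" exact on the grid. The plane-by-plane scan
simulator used for topography does *not* wrap: it evaluates the defocused
PSF at the true offset and truncates beyond 4 µm, where the light per pixel
is far below the background. Lateral convolutions are circular FFT
convolutions; synthesized speckles are periodic by construction, so this is
self-consistent (the spec'd pad-and-crop option was dropped in favor of
this consistency).

## Speckle statistics

Speckles are synthesized by assigning i.i.d. uniform phases to the pupil
pixels and propagating; intensities are scaled to unit ensemble mean. The
default is a *fully developed* speckle (uniform weight over the whole
pupil): the illumination power spectrum then extends to the pupil edge,
which is what lets the variance channel carry frequencies out to twice the
detection cutoff. An optional Gaussian pupil envelope is provided; note
that an envelope with FWHM equal to the pupil radius suppresses the outer
spectral band to ~0.4% and destroys the resolution doubling — it is a
deliberate non-default.

The lateral intensity auto-covariance is computed in closed form from the
pupil: Γ(Δ) = |C(Δ)|² − Σ M⁴/n⁴, with C the inverse transform of the
(envelope-weighted) pupil intensity. The subtracted constant is the exact
fourth-moment correction for a finite number of uniform-phase pupil modes;
without it the model standard deviation runs ~2% above a simulated
ensemble. The same expression holds at every z and for annular pupils.

Annular ("Bessel") pupils propagate by default with the ring-averaged
axial frequency, making each realization exactly invariant along z. On a
pixelated grid a thin annulus has finite radial width, and literal
propagation decorrelates over a few micrometres — the opposite of what an
axially invariant illumination is for. The literal behaviour is available
with `columnar=False`.

## Variance matching

The reconstruction minimizes, over ρ ≥ 0,

    F(ρ) = ‖σ̂ − σ(ρ)‖² + μ‖ρ‖²,

where σ̂ is the per-pixel (population) standard deviation of the Wiener
pre-filtered speckled images (filter g̃ = h̃⊥*/(|h̃⊥|² + η), η = 10⁻³), and
σ(ρ) the model deviation with the effective PSF h⊥∗g:

    σ²(r) = ∬ ρ(r')ρ(r'') Γ(r''−r') h_eff(r−r') h_eff(r−r'') dr' dr''.

Evaluation uses the spectral decomposition of Γ: with P(k) ≥ 0 its discrete
power spectrum, σ²(r) = (1/N) Σ_k P(k) |[(ρ e_k*) ∗ h_eff](r)|². Modes with
P below 10⁻⁶ of the maximum are dropped; ±k pairs are merged (Γ is real and
even, h_eff real), halving the cost. The analytic gradient is assembled
from the same modes and is validated against central finite differences.
A Tukey window (cosine fraction 0.2) is available for experimental-style
inputs and off by default for simulations. An ε-floor (10⁻¹²) guards the
1/σ factor in the gradient. When an empirical auto-covariance is supplied,
`mask_autocov_support` restricts the model Γ to its Fourier support.

Optimizer: bound-constrained L-BFGS-B by default (stop at relative
objective decrease 10⁻⁶ or `max_iters`); a monotone projected-gradient
scheme with Barzilai–Borwein steps and backtracking is available as
`method="pgd"`. PGD needs several times more iterations for the same
objective decade, which is why quasi-Newton is the default; PGD remains the
reference for the monotone-descent property.

The baseline for comparisons is the Wiener-deconvolved mean image
("deconvolved EDF-widefield", η = 2×10⁻⁴). A rolling-ball background
subtraction is provided for experimental stacks with out-of-volume
background.

### What the inversion can and cannot recover

The variance data constrain ρ only inside the doubled band (|k| ≤ 4NA/λ =
2× the incoherent cutoff): Γ's spectrum and the effective OTF each have
support 2NA/λ, and density components beyond their sum lie in the exact
null space of the quadratic form. The 40-lobe star contains ~30% of its
energy beyond that band near its center, so "recovery" is always assessed
against the band-limited star (a 60 nm Gaussian blur, which also keeps the
target nonnegative — the sharply band-limited star has negative ringing
that the nonnegativity constraint cannot represent). Under these terms the
noiseless inverse-crime test recovers the density to <1% L2.

## Synthetic-data conditions

The reference optics are the ones used throughout: NA 0.8, in-medium
wavelength 530/1.3 nm, voxel pitches dx = dy = 38.5 nm, dz = 87.5 nm; the
full-scale grid is 512×512×128 (`paper_full` preset) and the desk-scale
grid 128×128×32 (`desk_small`). The star object is 1 + cos(40θ);
topographies are flat (mid-range), a right circular cone (height nz·dz,
base radius (nx/2)·dx) and i.i.d. uniform random heights. Acquisitions
apply Poisson noise after scaling the expected image peak to the photon
budget (default 10³–2×10³ photons; read noise optional, off by default —
the noise model of the original simulations is unstated). Where a
depth-dependent effect is the point (the random-topography regime), the
64×64 lateral grid keeps the full 128-slice depth so random heights span
many axial speckle correlation lengths.

The benchmark problem sizes (64² for variance-model and inverse-crime
checks, 128² for the resolution comparison, 512² for topography) are the
package's desk-scale choices; `paper_full` runs the same code at full scale.

What the generator does *not* emulate: optical aberrations, sample
scattering/absorption, fluorophore photophysics, camera read noise by
default, multi-surface samples. Passing tests demonstrate internal
consistency of model and inversion under the stated forward model, not
robustness to those effects.

## Topography estimation

A single speckled illumination is scanned plane by plane (default one
plane every 2 µm). The pipeline:

1. **Background**: a separable polynomial gain â (lateral degree ≤ 2,
   axial degree up to n_planes − 1, capped at 5) is fitted to a random
   1/1000 voxel subsample by one-sided trimmed least squares (discard
   voxels >2.5 robust SD *above* the fit — signal only adds photons). The
   axial flexibility is needed because integrated defocus haze is not
   quadratic in z; a stiff axial model bends at the extreme planes and
   miscalibrates detection there. The noise scale σ̂₀ is the normalized MAD
   of s/â over the subsample.
2. **Normalization**: r̂ = (s − â)/(â σ̂₀); background voxels ≈ N(0, 1).
3. **Detection**: threshold at the upper-pfa normal quantile (pfa = 0.01 →
   2.3263). Detected columns get a sub-plane height from the
   clipped-squared-intensity axial centroid over planes within an adaptive
   window (≥800 nm, or 1.1× the plane spacing) of the column's brightest
   plane.
4. **RANSAC**: overlapping windows (default 16×16, 50% overlap) with
   quadratic fits z = q(x, y) on minimal 6-point samples; sampling and
   consensus are weighted by detection brightness (brighter ⇒ closer to
   focus), which prevents degenerate all-in-one-plane fits when heights
   are quantized; inlier tolerance 175 nm (2× the reference axial pitch);
   iteration count 300 (≥99% success at 50% outliers); labels fused across
   windows by intersection (the union reading is available via
   `fuse="union"`).
5. **Consolidation + spline**: inliers are merged into local centroid
   anchors (600 nm tiles), anchors inconsistent with a local plane through
   their neighbours are dropped, and a biharmonic (thin-plate) spline
   interpolates the rest to the full grid, with a convex-hull validity
   mask. ("Bi-cubic harmonic spline" is not a standard single method; the
   thin-plate spline is the choice here.) `interpolate_surface` passes
   exactly through the points it is given.

The EDF-RIM image is then draped on Z_s as a textured vertex grid (OBJ
export; intensities pass through unchanged).

### Accuracy limits at coarse z-sampling

With 2 µm plane spacing nearly every detection carries its plane's
quantized height (the defocus capture range is < the spacing), so after
RANSAC banding the anchor error floor is set by the windowed-quadratic
model bias and by the frozen speckle (contrast ≈ 1) modulating which part
of the detection band is seen. On the steep reference cone (slope ≈ 1.1)
this floors the surface RMSE near ~3× the axial voxel pitch; at 0.5 µm
spacing, where the capture range spans several planes and the axial
centroid engages, the same pipeline reaches ≈1× the axial pitch. The cone
apex is a curvature singularity that no quadratic window follows; errors
concentrate there. The detector's false-alarm rate is exact on a
standard-normal background; with a *fitted* background the end-to-end rate
runs ~1.3–1.5% at pfa 1% because of subsample fit wiggle.

## Star-resolution readout

Images of the star are unwrapped on circles; on each ring the modulation
contrast is the magnitude of the n_lobes-th angular Fourier coefficient
over the ring mean. The resolved radius is the innermost radius whose
contrast reaches 0.1 (a conventional resolvability criterion, exposed as a
parameter) and stays above it outward; the corresponding local period is
2πr/n_lobes. Image comparisons normalize to unit mean first (RMS error,
peak-to-RMS ratio, Pearson).

## Known limitations

* The inversion is non-convex; convergence from the widefield
  initialization is reliable in the tested regimes but not guaranteed.
* The μ scale is tied to the data scale (σ̂ units); values quoted here
  assume the simulation scaling used by the benchmarks.
* The topography pipeline assumes a single-valued surface and sub-50%
  contamination per RANSAC window.
* Speckle synthesis and the forward model share the same pupil code; the
  Monte-Carlo variance oracle is kept free of the spectral decomposition
  so the model check is two independent routes, but both inherit the same
  scalar-diffraction assumptions.
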
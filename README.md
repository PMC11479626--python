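# edfrim

Extended-depth-of-field random illumination microscopy (EDF-RIM):
simulation, super-resolved reconstruction, and surface-topography
estimation for speckle-illuminated fluorescence imaging of thick samples.

## The problem and who this is for

Imaging a thick, curved sample (an epithelium, an embryo surface) plane by
plane is slow and photon-hungry. Extended-depth-of-field (EDF) detection —
sweeping the focal plane within one camera exposure — projects the whole
volume into a single 2D image, but at the cost of background haze and
diffraction-limited resolution. Random illumination microscopy (RIM)
restores both: the sample is illuminated with many independent laser
speckles, and the *variance* of the image stack across speckles is matched
to a physical model. Because only the second-order statistics of the
illumination enter the model (the speckle auto-covariance Γ_S, a known
function of the pupil), the method needs no knowledge of the individual
patterns and is robust to aberrations. The variance channel carries sample
frequencies up to twice the detection cutoff 2NA/λ — a factor-two
resolution gain over (deconvolved) widefield.

This package is for microscopists and methods developers who want to
simulate EDF-RIM acquisitions end to end, reconstruct super-resolved
projective images from speckled stacks, and re-drape those projections in
3D by estimating the sample surface from a single plane-by-plane scan.

## The model in brief

A camera image under illumination S with detection PSF h is
`I(r⊥, z_f) = ∬ ρ S h(r⊥−r'⊥, z_f−z') dr'⊥ dz'`; the EDF image replaces h
by its axial integral h⊥. For fluorophores on a surface z = Z(r⊥) (or for
axially invariant "Bessel" speckles from an annular pupil), the EDF image
variance takes the 2D canonical form

    σ²(r⊥) = ∬ ρ⊥(r')ρ⊥(r'') Γ(r''−r') h⊥(r⊥−r') h⊥(r⊥−r'') dr' dr''

and the density is estimated by Tikhonov-regularized variance matching

    ρ̂ = argmin_{ρ≥0} ‖σ̂ − σ(ρ)‖² + μ‖ρ‖²

where σ̂ is the empirical standard deviation of the Wiener pre-filtered
stack (g̃ = h̃⊥*/(|h̃⊥|²+η), η = 10⁻³; h⊥ is replaced by h⊥∗g in the model).
Topography is recovered from one speckled plane-by-plane scan by
normalizing the volume against a robustly fitted background gain
(r̂ = (s−â)/(â·σ̂₀)), thresholding at a chosen false-alarm probability,
classifying the bright points with windowed quadratic RANSAC fits, and
interpolating the inliers with a thin-plate spline. See `docs/methods.md`
for the full account.

## Worked example

```python
import numpy as np
from edfrim import (
    GridGeometry, make_pupil, compute_psf3d, compute_edf_psf,
    speckle_autocovariance, make_star_density, make_topography,
    embed_on_surface, simulate_acquisition, reconstruct_rim,
    deconvolve_widefield, star_resolution,
)

grid = GridGeometry(nx=128, ny=128, nz=32, dx=38.5, dy=38.5, dz=87.5)
pupil = make_pupil(na=0.8, wavelength=530 / 1.3, grid=grid)
psf = compute_psf3d(pupil, grid)
edf = compute_edf_psf(psf)

sample = embed_on_surface(make_star_density(grid),
                          make_topography(grid, "flat"), grid)
stack = simulate_acquisition(sample, pupil, n_speckles=200,
                             photon_budget=2000.0, modality="edf",
                             seed=0, psf=psf)

wf = np.clip(deconvolve_widefield(stack, edf, eta=2e-4), 0, None)
rim = reconstruct_rim(stack, edf, speckle_autocovariance(pupil),
                      mu=1e-5, eta=1e-3, max_iters=300)

for name, img in [("widefield", wf), ("EDF-RIM", rim.rho)]:
    r = star_resolution(np.clip(img, 0, None), grid.dx, n_lobes=40)
    print(f"{name}: smallest resolved star radius "
          f"{r.min_resolved_radius:.0f} nm "
          f"(local period {r.local_period_at_radius:.0f} nm)")
```

Output:

```
widefield: smallest resolved star radius 1617 nm (local period 254 nm)
EDF-RIM: smallest resolved star radius 924 nm (local period 145 nm)
```

The star object `1 + cos(40θ)` gets finer toward its center; the innermost
radius at which the 40 spokes keep ≥10% modulation contrast measures
resolution. Deconvolved widefield resolves down to a 254 nm local period —
essentially the incoherent limit λ/(2NA) ≈ 255 nm — while the variance
reconstruction resolves 145 nm, a 1.75× gain on this noisy desk-scale run
(the ideal factor is 2).

## Command line

`edfrim fixtures | simulate | reconstruct | topo | project | evaluate` —
thin wrappers over the library; every command takes a YAML optics config
and explicit seeds, writes float32 TIFF with YAML sidecars, and logs one
JSON line per stage. `edfrim fixtures --preset desk_small --out d --seed 0`
writes phantoms, the EDF PSF, a measured speckle auto-covariance and a
simulated stack to start from.

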
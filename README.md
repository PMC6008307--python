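# phaseloc

3D single-molecule localization microscopy (SMLM) with engineered point
spread functions: phase-retrieved PSF calibration, maximum-likelihood 3D
localization, Cramér–Rao precision limits, CRLB-optimal PSF design, and
localization post-processing (filtering, merging, fiducial-free 3D drift
correction, rendering).

SMLM reconstructs super-resolution images by fitting thousands of sparse,
blinking fluorophores across many camera frames. When the microscope's PSF
is engineered — astigmatic, saddle-point or tetrapod shapes produced by a
deformable mirror or phase mask — its shape encodes the emitter's axial
position, so a single 2D frame yields (x, y, z). Extracting those
coordinates at the physical precision limit requires a realistic continuous
PSF model, which this package estimates directly from a z-stack of
fluorescent beads. `phaseloc` is aimed at microscopists and image-analysis
developers who want a scriptable, fully testable implementation of that
computational chain, runnable end to end on synthetic data.

## Model

The PSF is a scalar-diffraction pupil model. A point source at (x, y, z)
produces the image-plane intensity

    P(x, y, z) = | F[ rho(k) · exp(jΦ(k)) · exp(2jπ(x kx + y ky))
                      · exp(2jπ(k_z2 z − k_z1 f)) ] |²  ⊗  G(σ)

where `rho` is the indicator of the NA/λ pupil disk,
`k_z{1,2} = sqrt((n{1,2}/λ)² − |k|²)` accounts for refractive-index
mismatch between immersion (n₁) and sample (n₂), `f` is the focal-plane
height, and `G(σ)` is a small Gaussian absorbing non-modeled blur. The
phase is a Zernike expansion `Φ = Σ_{j=4..J} c_j Z_j` (Noll indexing,
unit-RMS, radians).

* **Calibration** fits Θ = {c₄..c_J, σ, per-bead amplitudes, background
  polynomial, offsets} to bead z-stacks by minimizing the Poisson negative
  log-likelihood `Σ (M − I log M)` with safeguarded coordinate Newton
  updates.
* **Detection** matched-filters each frame against model PSFs on an axial
  grid (zero-mean normalized cross-correlation, threshold 0.2) and takes
  3D local maxima.
* **Localization** refines each candidate by MLE over {A, B, x, y, z} with
  the pupil fixed, reporting per-molecule CRLBs from the 5×5 Fisher matrix
  `I_uv = Σ_i (1/M_i) ∂M_i/∂θ_u ∂M_i/∂θ_v` and the reduced χ² of the
  residual.
* **PSF design** finds the coefficients minimizing the mean axial CRLB
  over a chosen axial range (astigmatic-like optima for ~1 µm ranges,
  saddle/tetrapod-like for 3–5 µm).
* **Post-processing** filters by CRLB/χ², merges consecutive localizations
  of the same molecule, estimates 3D drift by redundant cross-correlation
  of time-window reconstructions, and renders average shifted histograms.

## Worked example

Calibrate a pupil from a synthetic bead stack with known aberrations
(astigmatism c₅ = 1.2, c₆ = −0.8 rad, spherical c₁₁ = 0.5 rad), then ask
for the precision limit of the retrieved PSF:

```python
import numpy as np
from phaseloc import (OpticsConfig, PupilModel, RetrievalConfig, crlb,
                      retrieve, simulate_bead_stack)

optics = OpticsConfig(na=1.2, wavelength=670.0, pixel_size=110.0, fft_size=64)
true_coeffs = np.zeros(12)            # Noll c4..c15
true_coeffs[5 - 4] = 1.2
true_coeffs[6 - 4] = -0.8
true_coeffs[11 - 4] = 0.5
truth = PupilModel(optics=optics, coeffs=true_coeffs, blur_sigma=0.0)

beads, _ = simulate_bead_stack(truth, z_start=-2000.0, z_step=100.0,
                               n_planes=40, photons_per_plane=4000.0,
                               background=10.0, window=31, seed=1)
params, report = retrieve(beads, RetrievalConfig(j_max=15, n_iterations=30))

for j in (5, 6, 11):
    print(f"c{j}: retrieved {params.pupil.coeff(j):+.3f} rad "
          f"(truth {truth.coeff(j):+.1f})")
print(f"mean per-plane reduced chi2: {report['chi2_per_plane'].mean():.3f}")

sx, sy, sz = crlb(params.pupil, photons=3000.0, background=50.0, z=500.0,
                  window=31)
print(f"CRLB at z=+500 nm (A=3000, B=50): "
      f"sigma_x={sx:.1f} nm, sigma_y={sy:.1f} nm, sigma_z={sz:.1f} nm")
```

Output:

```
c5: retrieved +1.208 rad (truth +1.2)
c6: retrieved -0.796 rad (truth -0.8)
c11: retrieved +0.485 rad (truth +0.5)
mean per-plane reduced chi2: 0.998
CRLB at z=+500 nm (A=3000, B=50): sigma_x=11.7 nm, sigma_y=7.5 nm, sigma_z=18.8 nm
```

The retrieved coefficients match the generating aberrations to a few
milliradians from a single noisy 40-plane stack; a reduced χ² of ~1 says
the residual is pure Poisson noise. The CRLB values are the best standard
deviation any unbiased fit can achieve for a 3000-photon molecule on a
50-photon background at that depth.

The same stages are available from the shell:

```bash
phaseloc simulate bead-stack --out beads.tif --seed 1
phaseloc calibrate --stack beads.tif --z-start -2000 --z-step 100 \
         --jmax 15 --out pupil.json
phaseloc localize --movie movie.tif --pupil pupil.json --out locs.csv
phaseloc postprocess --in locs.csv --preset saddle --out locs_final.csv
phaseloc render --in locs_final.csv --voxel 20 --out image.tif
phaseloc optimize-psf --range 3000 --out pupil_opt.json
phaseloc crlb-curve --pupil pupil.json --photons 4677 --background 18.2 \
         --z -2000:2000:50 --out curve.csv
```

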
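# Methods

This note documents the models, estimators, numerical choices and
validation protocols implemented in `phaseloc`, and what the synthetic
studies do and do not establish about real data.

## Image formation

A point emitter at (x, y, z) nm produces, on the camera, the squared
modulus of the Fourier transform of the pupil field: a unit-amplitude wave
on the numerical-aperture disk of radius NA/λ carrying the phase

    Φ(k) + 2π(x·kx + y·ky) + 2π(k_z2·z − k_z1·f),
    k_z{1,2} = sqrt((n{1,2}/λ)² − kx² − ky²),

with n₁ the immersion index, n₂ the sample index, and f the height of the
nominal focal plane above the coverslip. The index mismatch term makes
depth-induced spherical aberration part of the model rather than a
nuisance. The aberration/engineering phase Φ is expanded on Zernike
polynomials, Noll single-index convention with unit-RMS normalization,
coefficients in radians, indices 4..J (piston, tip and tilt do not change
the PSF shape and are excluded). The intensity PSF is convolved with an
isotropic Gaussian of standard deviation σ pixels that absorbs blur not
captured by scalar diffraction (camera pixelation, residual high-order
aberrations); σ ≈ 0.7 px is a typical retrieved value and the default.

Numerics: the pupil is sampled on an fft_size² grid with k-spacing
1/(fft_size · pixel_size), so one image pixel equals the physical pixel
pitch (110 nm default). The PSF is obtained by a centered FFT and
normalized so the unaberrated, index-matched, in-focus PSF sums to one
over the grid — PSF values are per-pixel photon fractions and fitted
amplitudes are photon counts. The Gaussian blur is applied as a transfer
function on the same periodic grid (exact intensity conservation, no
kernel truncation). Where NA > n₂ the super-critical pupil annulus is cut
off (those components are evanescent in the sample); the PSF then sums to
less than one, which is physical. Wraparound of very defocused PSFs on the
finite grid is accepted; fft_size = 64 keeps it negligible over ±2.5 µm
for the PSFs used here. Derivatives of the PSF with respect to x, y, z,
each c_j and σ are computed analytically through the Fourier model
(∂|p|² = 2·Re(p̄·F[g·u]) with the appropriate pupil factor g), verified
against central finite differences to ~1e-7 relative.

## Camera model

Fitting operates in photon units: photons = (ADU − offset)/gain, clipped
at zero. EMCCD data are treated as Poisson. For sCMOS cameras with
per-pixel statistics, the per-pixel readout variance (in photons²) is
added to both data and model and the sum treated as Poisson — the standard
variance-matching approximation; it is an approximation, adequate when
readout noise is small against shot noise. EM-gain excess noise is not
modeled.

## PSF calibration by phase retrieval

The calibration model for bead s, plane k, pixel i is

    M = A[s,k] · P(dx_s, dy_s, z_k + dz_s) + B_s(i),

with per-plane amplitudes (photobleaching), per-bead 3D offsets, and a
second-order polynomial background B = b0x² + b1y² + b2xy + b3x + b4y + b5
on centered window coordinates normalized to [−1, 1] (conditioning; the
coefficients are reproducible under that convention). All parameters —
Zernike coefficients, σ, and the per-bead nuisances — are estimated
jointly by minimizing the Poisson negative log-likelihood Σ(M − I·log M),
pooling all beads into one likelihood.

The optimizer is safeguarded coordinate-wise Newton iteration in grouped
sweeps: per-bead geometry (dx, dy, dz) → amplitudes → background →
Zernike coefficients → σ, for a fixed number of outer iterations (30 by
default) with early exit below 1e-6 relative improvement. Curvatures use
Fisher scoring (the expected Hessian, always positive) for parameters
that enter through the PSF, and exact second derivatives for the linear
amplitude/background parameters; steps are clamped (0.5 px lateral,
100 nm axial, 0.25 rad, 0.25 in σ per iteration) and every grouped step
is accepted only if the NLL does not increase, backtracking by halving
and reverting otherwise. The per-iteration NLL sequence is therefore
non-increasing by construction. The model is floored at 1e-6 photons
before logs; clamp events are counted in the fit report. σ is bounded in
[0, 3] px so blur cannot absorb defocus.

Initialization is moment-based: zero phase, lateral offsets from the
central-plane intensity centroid, amplitudes from background-subtracted
plane sums, constant background from the border-pixel median, and dz from
the plane with the sharpest smoothed peak. For strongly astigmatic pupils
the sharpest plane is a *line focus* several hundred nm from the true
focus, and descending from it reliably lands in a local minimum. Because
of this, `retrieve` launches short pilot runs from both the
sharpest-plane dz and the mid-stack dz and continues the best; with the
pilot guard, coefficient recovery at the reference conditions (single
bead, 40 planes × 100 nm, 4000 photons/plane, background 10) is ~0.003 rad
median error for coefficients drawn up to ±1.5 rad.

Two identifiability facts worth knowing. First, defocus c₄ is nearly
degenerate with the bead offset dz (the propagation phase 2π·k_z·z and
the parabolic Zernike defocus differ only in their higher-order radial
terms); estimates typically show a small c₄ compensated by dz with no
effect on the PSF itself or on the other coefficients. Second, a global
phase sign has a twin solution in pure intensity data; the through-focus
diversity of the z-stack breaks it in practice.

## Detection

Model PSFs are computed at x = y = 0 on an axial grid from z_min to z_max
with step δz (default: the pixel size), and each frame is correlated with
every template. The correlation is the zero-mean normalized
cross-correlation over the sliding window, computed via FFT
(`skimage.feature.match_template`), so scores lie in [−1, 1], are
invariant to affine intensity transforms of the frame, and the default
threshold 0.2 is scale-free. Candidates are strict 26-connected local
maxima of the (z, y, x) correlation volume above threshold, with maxima
within half a template of the frame border discarded and laterally
overlapping candidates suppressed (best score wins) — the downstream fit
is single-emitter by contract; overlapping PSFs are out of scope.

## Localization

Each candidate is refined by MLE of the five parameters {A, B, x, y, z}
of M = A·P(x, y, z) + B on the template-sized window centered on the
detected pixel, with the pupil held fixed to the calibration and B
locally uniform. Updates are coordinate Newton steps (analytic gradients,
Fisher-scoring curvature) clamped to one pixel laterally, 200 nm axially
and 50% in A and B per iteration, with NLL backtracking; iteration stops
when the position moves less than 0.1 nm or after 30 iterations.
Non-converged fits are flagged and retained; candidates whose window
clips the frame are rejected. Each record carries the reduced residual
χ² = Σ(I−M)²/M / n_pixels — ≈1 under pure Poisson noise, larger when
unmodeled signal (a neighboring molecule) contaminates the window — and
per-axis CRLBs.

## Precision limits and PSF design

The Fisher information of the five-parameter model under Poisson noise is
I_uv = Σ_i (1/M_i)(∂M_i/∂θ_u)(∂M_i/∂θ_v); the reported per-axis precision
bound is the square root of the corresponding diagonal element of the
full 5×5 inverse, i.e., photons and background are nuisance parameters,
matching the per-molecule estimation problem. Singular matrices yield
NaN markers.

PSF design minimizes Σ_i σ_z^CR(z_i) over a k+1-point grid discretizing
the target axial range (k = 10 default; the grid includes both endpoints)
at a fixed photometric operating point (A = 3000, B = 50 by default), over
Noll indices 5–15 by default — smooth low-order modes, excluding defocus
(which only recenters the range) and avoiding phase-wrap solutions.
The optimizer is coordinate Newton with finite-difference curvature
(h = 0.05 rad), step clamp 0.3 rad, backtracking, and multi-start (5
starts by default: the supplied/zero start plus random perturbations) with
best-objective selection, since the objective is multimodal. Optimizing a
1 µm range from scratch yields a dominant primary-astigmatism term;
larger ranges yield saddle-point/tetrapod-like mixtures of astigmatism
and spherical terms, and the 3 µm design beats the 1 µm design on mean
axial CRLB over ±1.5 µm (the range/resolution trade-off).

## Post-processing

*Filtering* keeps records with per-axis CRLB strictly below threshold and
reduced χ² ≤ 3. Presets: astigmatic 20/40 nm (lateral/axial), saddle
30/60 nm, tetrapod no CRLB cut. The χ² threshold is applied to the
*reduced* statistic, whose null value is ≈1.

*Merging* links localizations of the same blinking molecule across
consecutive frames: within 100 nm lateral and 200 nm axial capture radii
of the chain's last position, with at most `max_gap` skipped frames
(default 0). A chain collapses into one record with photons summed,
background and χ² averaged, position the inverse-variance (1/CRLB²)
weighted mean per axis, and CRLB combined by inverse variance — the
statistically standard weighting; the capture-radius rule is applied
greedily in frame order.

*Drift correction* follows the redundant cross-correlation scheme:
localizations are binned into non-overlapping time windows (10,000 frames
default), each rendered as a 3D histogram at the drift voxel (30 nm
default); all window pairs are cross-correlated by FFT (histograms are
zero-padded by the maximum expected drift, 6 µm default, so the searched
lags are wrap-free); each pairwise displacement is located with subvoxel
precision as the intensity-weighted mean of voxels above 95% of the
correlation peak; per-window displacements are solved from all pairwise
estimates by least squares (the redundancy averages down the subvoxel
quantization error); a natural cubic spline through the window midpoints
gives per-frame drift, held constant beyond the first/last midpoints; and
the drift is subtracted from the coordinates. Windows with fewer than 50
localizations are dropped from the least-squares system and bridged by
the spline. The trace is anchored at zero for the first usable window:
the absolute offset is unobservable from localizations alone, so accuracy
against an injected truth is assessed after mean alignment.

*Rendering* produces 2D or 3D average shifted histograms (2 shifts per
axis by default); total intensity equals the record count exactly.

## Synthetic data

The generators draw Poisson pixel noise from the same image-formation
model used for fitting and return exact ground truth; all are
deterministic under a fixed seed. Defaults mirror a typical engineered-PSF
calibration: 40 bead planes stepped by 100 nm over 4 µm with optional
exponential photobleaching; repeated-bead precision runs of 50 frames per
z position at 4677 photons and 18.2 background (a realistic bright-bead
operating point); movies with log-normal emitter brightness (median 3000
photons, σ_log = 0.5), geometric on-times, and a minimum lateral
separation of 1.5 fitting windows between simultaneously active emitters,
enforcing the single-emitter contract of the localizer.

Because generator and fitter share the forward model, these studies
validate the *estimation machinery* — calibration accuracy, CRLB
attainment, detection recall, drift recovery — not the realism of the
optical model itself. Real data add model mismatch the simulations do not
probe: field-dependent aberrations, dipole emission effects, EM-gain
excess noise, fluorophore photophysics beyond geometric on-times, and
sample-induced scattering. Passing tests therefore bound what the
algorithms can do when the PSF model is adequate, which on real systems
must be checked through the calibration residual χ².

## Validation protocols and problem sizes

The studies in `phaseloc.validation` (run by the test suite and
`scripts/acceptance.py`) use desk-scale sizes chosen to finish in minutes
on one CPU while keeping Monte-Carlo noise understood:

* Precision vs CRLB: 50 repeats at each of 9 z positions spanning ±2 µm,
  saddle-like pupil (c₁₁ = 2 rad), 4677 photons, background 18.2. Note
  the sampling noise of a standard deviation at n = 50 is ~10% (1σ), so
  individual std/CRLB ratios scatter accordingly; the max deviation over
  the 27 (z, axis) checks is expected to reach ~0.22 for a perfectly
  efficient estimator. The better-powered 150-repeat unit test bounds
  efficiency in [0.85, 1.25].
* Coefficient recovery: 10 independent pupils with c₅–c₈ and c₁₁ drawn in
  ±1.5 rad, one 40-plane bead stack each at 4000 photons/plane.
* Fisher consistency: 20 random pupils, analytic vs central differences
  (0.1 nm position step), window 21.
* χ² calibration: 500 Poisson windows of 15×15 pixels at mean 50.
* Drift: 20 windows × 1000 frames, linear + sinusoidal drift of 300 nm
  amplitude, 30 nm voxels, 5 localizations/frame on a rigid 3D ring —
  a records-level simulation standing in for re-fitting tens of
  thousands of frames.
* PSF design: 1 µm and 3 µm ranges, 5 starts × 15 iterations, evaluated
  on ±1.5 µm.

## Known limitations

Scalar (not vectorial) diffraction; no apodization; no phase
discontinuities (double-helix PSFs are outside the Zernike model); single
emitter per fitting window; c₄/dz near-degeneracy in calibration (benign);
drift recovery assumes a structure rigid over the acquisition; CRLB
assumes an unbiased estimator and pure Poisson noise, which is why the χ²
filter accompanies it.
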
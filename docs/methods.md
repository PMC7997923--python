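# Methods

## Physical model

The package treats fluorescence recovery after volumetric photobleaching
as free diffusion of the unbleached-fluorophore concentration `c(x, t)`
with a spatially constant, symmetric 3×3 diffusion tensor **D**
(µm² s⁻¹):

    ∂c/∂t = ∇·(D ∇c)

On a periodic domain every spatial-frequency mode **q** = (u, v, w)
(cycles µm⁻¹) of `c` decays independently as
`exp(−4π² qᵀDq t)`.  The estimator lives entirely in this spectral
picture; the model excludes binding, immobile fractions, anomalous
diffusion, photophysics beyond irreversible bleaching, and spatial
variation of **D** within the analyzed volume.  One experiment yields one
tensor.

Derived scalars: principal diffusivities λ₁ ≥ λ₂ ≥ λ₃ (eigenvalues of
**D**), mean diffusivity (Dxx + Dyy + Dzz)/3, and the diffusion
fractional anisotropy

    FA = sqrt((λ₁−λ₂)² + (λ₁−λ₃)² + (λ₂−λ₃)²) / sqrt(2(λ₁²+λ₂²+λ₃²)),

a scalar in [0, 1] (0 isotropic, 1 purely unidirectional).  Conventions
that the field leaves open and we fix: eigenvalues are sorted descending;
each eigenvector's sign makes its largest-magnitude entry positive.  A
fitted tensor whose smallest eigenvalue is slightly negative (possible
under noise) is reported as-is with `is_spd=False` rather than projected
onto the SPD cone; FA on such a tensor is computed on eigenvalues clipped
at zero.

## Virtual microscope (`frap_sim`)

`simulate_liftfrap` emulates a volumetric light-sheet FRAP acquisition.
Defaults are the standard acquisition conditions: a 76 µm × 76 µm × 76 µm
field of view imaged as 64 planes of 192 × 192 px at 8 volumes s⁻¹, 80
prebleach volumes (10 s), a 10 µm × 10 µm × 10 µm bleach cube applied for
1 s, then up to 80 postbleach volumes.  `SimulationConfig.test_default`
is the reduced problem size used throughout the test suite
(32 × 64 × 64 voxels, 8 prebleach + 60 postbleach volumes, same physical
field of view and timing), chosen so a full simulate/analyze cycle takes
about two seconds.

Concentration propagation uses the exact periodic spectral propagator
(each rFFT mode multiplied by `exp(−4π² qᵀDq Δt)`).  The unbleached
surround is large relative to the bleach cube, so periodic wrap-around is
negligible over the simulated window; this is quantified against the
zero-flux/periodic finite-difference solver in the tests (voxelwise
agreement < 1% over 20 volumes when the bleach edge is resolved by the
grid).

**Bleach profile.**  The instrument raster-scans the bleach volume, and
its achieved depth profile is not specified; we model the bleach as a
product of per-axis error-function-smoothed boxes, `B(x) ∈ [0, 1]`, with
free parameters depth (default 0.8 — a deep but not saturating bleach)
and edge width (default 1 µm).  The field is multiplied by
`(1 − depth·B)`.  Bleaching is applied in 8 substeps interleaved with
diffusion across the 1 s bleach duration, so diffusion during bleaching
is part of the generated data — the analysis must not (and does not)
assume a pristine initial profile.

**Noise model.**  Each recorded volume passes through a camera model:
Poisson shot noise with `photon_scale` expected photons at unit prebleach
intensity, additive Gaussian read noise `read_sigma`, and a constant
offset.  Defaults — photon_scale 2000, read_sigma 0.01, offset 0 —
represent a bright solution/tissue sample on a fast sCMOS camera at
~125 ms per volume (per-voxel SNR ≈ 45 at prebleach intensity).  The
per-voxel variance follows mean/photon_scale + read_sigma², verified to
5% in the tests.  A seed is mandatory for any stochastic run and
reproduces the series bit-exactly.  Because the noise is specified per
voxel, reducing the voxel count (the scaled-down test grids) makes the
data *noisier* than the full acquisition; precision-sensitive checks
(e.g. the isotropy null) therefore use a grid closer to the full protocol
(64 × 96 × 96, 80 + 80 volumes).

What the generator does **not** emulate: optical blur (PSF, light-sheet
thickness), sample drift, refractive effects, photobleaching during
imaging, spatially varying dye concentration beyond an optional
multiplicative illumination pattern.  Passing tests therefore demonstrate
estimator correctness under the stated model, not robustness to every
instrument artifact.

## Finite-difference solver

`fd_diffuse` integrates the same PDE by an explicit conservative
finite-volume scheme with the full anisotropic stencil: face-centered
normal derivatives, tangential derivatives averaged from adjacent cell
centers, zero-flux (reflective) or periodic boundaries, and an optional
constant-concentration source mask re-imposed after every step.  Because
fluxes telescope, total concentration is conserved to round-off under
zero-flux boundaries.  The stability bound

    dt_max = 1 / ( 2 Σᵢ Dᵢᵢ/hᵢ² + 2 Σᵢ<ⱼ |Dᵢⱼ|/(hᵢhⱼ) )

is enforced at run time; an oversized step raises an error naming the
bound.  The solver shares no code with the spectral route and serves as
the independent oracle: per-mode decay rates extracted from its runs
match the analytic `4π² qᵀDq` to better than 2% for the low modes on a
32³ grid (dominant error: the second-order spatial symbol,
≈ (πqh)²/3).

## Estimator (`frap3d_analysis`)

1. **Normalization.**  Each postbleach volume is divided voxelwise by the
   time-averaged prebleach volume, removing multiplicative illumination
   and staining inhomogeneity.  Averaging all prebleach volumes first
   suppresses reference noise.  Voxels below 1% of the median prebleach
   intensity are masked and in-filled with a local median before
   division.
2. **Mode selection.**  Axis modes (n/Lx, 0, 0), (0, n/Ly, 0),
   (0, 0, n/Lz) and signed diagonal-plane modes (n/Lx, ±m/Ly, 0) etc.,
   with harmonic indices n, m ∈ [1, n_harm] (default 4), restricted to
   |q| ≤ q_max.  The default cutoff q_max = 0.6/(bleach extent) keeps the
   modes inside the high-power region of the bleach-box spectrum (the
   box's first spectral zero lies at 1/extent).  Both signs of the
   diagonal modes are kept; their rate difference carries the
   off-diagonal tensor components.
3. **Extraction.**  3D DFT of each normalized volume (the constant
   background affects only the excluded q = 0 bin); per-mode magnitude
   series normalized to the first postbleach volume.  Time origin t = 0
   is the first postbleach volume, which makes the estimator agnostic to
   diffusion during bleaching.  The coefficient *magnitude* is fitted
   rather than the complex value, for robustness to sub-voxel bleach
   center offsets (pure phase shifts); the amplitude A absorbs the small
   magnitude bias this introduces.
4. **Per-mode fits.**  `C̃/C̃₀ = A·exp(−kt)` by bounded nonlinear least
   squares (A near 1 free, k ≥ 0; optional additive offset off by
   default), truncated at the first time the raw magnitude falls below
   the noise floor.  The floor is 5× the RMS magnitude of coefficients
   with |q| > 2 q_max in the first postbleach volume.  Modes with fewer
   than 4 surviving points or non-convergent fits are flagged unusable,
   not fatal.
5. **Assembly.**  Weighted linear least squares (weights 1/k_se²,
   unweighted fallback for degenerate standard errors) of the fitted
   rates against the quadratic form, yielding the six components and a
   6×6 covariance.  Rank deficiency raises an error naming the missing
   quadratic directions.  A two-stage scheme (fit modes, then solve) is
   the default; the mode table in the result allows external joint
   refits.
6. **Diagnostics.**  If even the lowest-|q| mode decays below the noise
   floor within fewer than 4 volumes the analysis raises a "diffusion too
   fast for frame rate" error instead of returning biased values.  This
   bounds the measurable diffusivity for a given volume rate and field of
   view.

Under the default acquisition settings the estimator is exact to
numerical precision on noiseless data, and under the default noise model
recovers eigenvalues of anisotropic tensors spanning 2–51 µm² s⁻¹ with a
median relative error of ~2–4% (median |FA| error < 0.01), including
tensors beyond 51 µm² s⁻¹ — the capability regime of the fast volumetric
acquisition.

## 2D analysis (`frap2d_analysis`)

The single-plane pipeline mirrors the 3D one with two deliberate
convention differences that follow the conventional 2D protocol: the
averaged prebleach image is *subtracted* (not divided), and the default
bleach region is a centered square with side 1/8 of the image.  Rates
are solved for (Dxx, Dyy, Dxy); principal diffusivities are returned
ascending (λ₁ ≤ λ₂).  The anisotropy proxy `fa_from_2d` assumes the
unmeasured out-of-plane diffusivity equals λ₂ and evaluates the 3D FA on
(λ₁, λ₂, λ₂) through the same code path as the 3D FA.

A single plane of a thick sample does not obey 2D diffusion: the plane
also refills axially, so the apparent in-plane rates are inflated.  With
Dzz = 5× the in-plane diffusivity, the single-plane analysis
overestimates the in-plane components by ~65% while the volumetric
pipeline recovers the truth — the package's in-silico demonstration of
why sectioned-sample 2D measurements misrepresent 3D transport.
Reconstructing a 3D tensor from orthogonal 2D sections is deliberately
not offered.

## Auxiliary metrics

* **Stokes–Einstein**: D = k_B·T/(6πηr) in µm² s⁻¹, with k_B fixed at
  the exact 2019 SI value.  Used as the theoretical reference for
  solution experiments.
* **Structure coherency**: the Gaussian-windowed structure tensor of the
  image gradients (default window σ = 8 px) is averaged over the image —
  a gradient-energy-weighted mean, the region semantics of
  fiber-orientation tools — and the coherency
  (λ_max − λ_min)/(λ_max + λ_min) of that mean tensor is returned.
  Averaging the tensor (rather than per-pixel coherencies) is what makes
  randomly oriented texture score ≈ 0: local orientations cancel in the
  mean, whereas the mean of per-pixel coherencies is positively biased
  for noise.  Exact parameter parity with any particular plugin is not
  claimed.
* **Water content**: (w_wet − w_dry)/w_wet × 100%.

## Problem sizes and tolerances

The test suite and the acceptance script use reduced problem sizes —
32 × 64 × 64 voxels for recovery tests, 64 × 96 × 96 with the full
80 + 80 volume protocol for the isotropy null, 32³ grids for solver
cross-validation, 3–12 seeds per stochastic check — sizes at which every
validated property is already stable; the full-resolution defaults
remain available through `SimulationConfig`.  Numerical tolerances used
in validation: eigen-reconstruction 1e−8 relative; rotation invariants
1e−9; noiseless recovery 1% (measured ~1e−6); FD-vs-analytic mode rates
2% (measured < 1.1%); noisy eigenvalue recovery 10% median (measured
~2–4%).

## Known limitations

* Constant-tensor model only; no per-voxel tensor maps.
* No optics: the simulator's voxels are ideal point samples of the
  concentration field.
* The magnitude-fit convention slightly biases very weak modes (Rice
  floor); the noise-floor truncation keeps fitted points at SNR ≥ 5.
* The periodic propagator ignores the sample boundary; for bleach
  regions comparable to the field of view the finite-difference solver
  should be used as the generator instead.
* Measurable diffusivity is bounded above by the volume rate and below
  by the acquisition duration; outside that window the pipeline raises
  diagnostics rather than extrapolating.
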
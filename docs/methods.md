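# Methods

## Registration model

The transformation is parameterized by a dense displacement field `u` on
the fixed-image grid, in voxel units, with pull-back convention
`φ(x) = x + u(x)`: warping samples the moving image at `x + u(x)`, and a
good registration satisfies `I_M(x + u(x)) ≈ I_F(x)`. Each iteration
computes a per-voxel force from the current residual, composes it into the
field (`u ← u ∘ f`, i.e. `f(x) + u(x + f(x))`), and regularizes the
composed field by filtering. This is the diffusion-like (compositive)
Demons scheme; fluid-like smoothing of the update alone is deliberately
not offered. No explicit energy is minimized once the Gaussian is replaced
by a guided filter — the scheme is defined by its fixed points (force
equilibrium under the chosen filter), and convergence is monitored through
the mean update norm.

### Forces

**Symmetric SSD force.**
`f = (I_F − I_M∘φ) / (‖∇I‖² + λκ²) · ∇I`, with the gradient averaged
between fixed and warped-moving images and `κ` equal to the residual. The
denominator yields the classic bounded step `‖f‖ ≤ 1/(2√λ)` per voxel
(AM–GM), which the test suite asserts on random inputs. Voxels whose
denominator falls below `denom_floor` (default 1e-9 on [0,1]-normalized
intensities) produce zero force. `λ` defaults to 1.0 (maximum step half a
voxel per iteration).

**Local-correlation force.** For contrast-varying data the residual is
replaced by a locally affine-corrected one: per cubic window of radius
`lcc_radius` (default 4) the least-squares fit of the warped moving image
to the fixed image is subtracted, `κ_lcc = (I_F − μ_F) − (c/σ²_W)(W − μ_W)`
with box-window means, variances and covariance. The corrected residual
goes through the same bounded normalization. Where either image is locally
flat (variance below `denom_floor`) the force is zero. This residual is
exactly zero for any aligned pair related by an affine intensity map, and
it is an ascent direction on the local correlation coefficient wherever
the local correlation is positive. The window statistics are computed with
the same truncated box filters as the guided filter, so the force is O(N).
On small bias-field phantoms a single bias realization can be locally
near-constant — then the plain SSD force is barely corrupted — so the
LCC-vs-SSD comparison in the tests is aggregated over realizations.

### Guided-filter regularization

Per window N of radius `r`, `γ_N = cov_N(I_g, u)/(σ²_N(I_g) + ε)` and
`β_N = μ_N(u) − γ_N μ_N(I_g)`; the output at a voxel averages
`γ I_g + β` over every window containing it. For M-channel guidance the
window fit solves `(Σ + εU) Γ = cov(I_g, u)` with `Σ` the window covariance
of the channels; M = 3 requires one 3×3 solve per voxel, done in a single
vectorized `np.linalg.inv` over the volume and cached per guidance/(r, ε)
pair since guidance is fixed within a pyramid level.

All window statistics are truncated at the volume borders and normalized
by the true in-bounds count, so kernel weights sum to exactly 1 and
constant fields are fixed points everywhere, including corners. The fast
path is validated to 1e-6 (measured ~1e-15) against a brute-force
evaluation of the explicit aggregated kernel
`W(x,y) = (1/n_x) Σ_{k∋x,y} (1/n_k)(1 + (I_g(x)−μ_k)ᵀ(Σ_k+εU)⁻¹(I_g(y)−μ_k))`,
which the package ships as a reference path (`explicit_kernel_weights`,
`filter_with_kernel_weights`).

Two limits orient the parameter choices: `ε → ∞` degenerates to a double
box mean independent of guidance (pure smoothing, effective Gaussian
σ ≈ √(2·((2r+1)²−1)/12) ≈ 4.5 voxels at r = 5), and `ε → 0` with
self-guidance reproduces the input. Defaults r = 5, ε = 0.1 on
[0,1]-normalized guidance.

### Supervoxel guidance

SLIC clustering minimizes the joint distance
`D = √((d_xw/S)² + (d_I/m)²)` by localized k-means: seeds on a regular
grid with interval `S = (N/K)^⅓`, optionally perturbed by `N(μ_z, σ_z²)`
and snapped to the flattest voxel of their 3³ neighborhood; assignment
restricted to a ±S window per center (this caps cluster bounding boxes at
2S+1 per axis); centers recomputed until the labeling stops changing or
`i_max` (default 10) is reached; 26-connectivity enforced afterwards
(largest component keeps the label, fragments ≥ S³/4 become new labels,
smaller orphans merge into their dominant neighbor). Rare voxels outside
every search window (possible when perturbed centers drift) are assigned
to the nearest center. Intensities are internally rescaled to [0, 255] —
the 8-bit convention of the original algorithm — so the compactness weight
default m = 24 is meaningful for any input normalization. On weakly
structured input the k-means labels can flicker indefinitely; the labeling
records `n_iter`/`converged`, and `i_max` bounds the cost.

Guidance channels hold per-supervoxel **mean intensities** (normalized to
[0,1]), not label ids — covariances of arbitrary label ids would be
meaningless in the multichannel filter. Random guidance uses seeds
`rng_seed + i` per channel with perturbation σ_z = S/4 (μ_z = 0) by
default; multiscale guidance uses the unperturbed ladder {K, K/2, K/4}
with K = 3750 and M = 3 channels. Guidance depends only on the fixed
image, so it is built once per pyramid level and reused across iterations;
K is divided by 8 per level so supervoxels keep a roughly constant edge
length in voxels.

### Multiresolution driver

Default 3 levels (factor-2 decimation with σ = 1 voxel pre-smoothing),
up to 50 iterations per level, convergence when the mean per-voxel update
norm drops below 0.01 voxels, divergence abort when the mean displacement
exceeds a third of the image extent. Fields transfer between levels by
trilinear upsampling with per-axis voxel-unit rescaling. The run is fully
deterministic given the config and `rng_seed`.

**Baseline σ.** The `iso-dem` baseline smooths with a Gaussian of
σ = 4.5 voxels per iteration — chosen to match the guided filter's
interior smoothing at r = 5 (see the ε → ∞ limit above). With a much
smaller σ the baseline is a weaker prior than the guided filter and a
comparison between the two confounds regularization strength with kernel
shape; matching the strength isolates the property under study, edge
awareness. Users comparing against a differently-tuned Demons can set
`gaussian_sigma` freely.

## Synthetic study conditions

The sliding phantom emulates, at desk scale, respiratory sliding at the
lung–liver/abdominal-wall interface as seen in resampled (2 mm isotropic)
abdominal CT:

* 64³ grid, planar interface at the mid-plane of one axis;
* region mean intensities 0.15/0.85 — organ interfaces in normalized CT
  span most of the intensity range;
* band-limited interior texture (Gaussian-filtered white noise, σ = 2
  voxels) of amplitude 4% of the range — soft-tissue parenchymal contrast
  in CT is a few percent of the display range, and this low-contrast
  interior is where the regularizer choice matters;
* additive noise of sd 1.5% on the moving image;
* true motion: ±t/2 voxels tangentially on either side (jump t, default
  6), decaying smoothly to zero within 6 voxels of the outer borders so
  warping stays in-bounds;
* the moving image is the fixed image resampled at `x − u(x)`, so the
  constructed field is exactly what registration should recover;
* 10 landmarks per region, ≥3 voxels from the interface and inside the
  full-motion plateau, so the TRE measures motion recovery rather than
  interface ambiguity or border effects; texture, bias, noise and
  landmarks draw from independent RNG streams, so toggling one never
  changes another.

The benchmark additionally reports the recovered cross-interface jump
(mean tangential displacement difference between bands 2–4 voxels on
either side of the plane, central half of the volume) and the fraction of
non-positive Jacobian determinants ≥3 voxels from interface and borders.

A multiplicative low-frequency bias field (smoothed white noise scaled to
±`bias_amplitude`) emulates contrast-induced intensity change for testing
the LCC force. A separate translation phantom applies an exactly constant
3-voxel shift (constant fields are fixed points of every regularizer here,
so recovery accuracy is independent of smoothing strength).

**What the phantom does not model:** curved interfaces, more than two
tissue classes, spatially varying motion amplitude along the interface,
through-plane motion, CT reconstruction artifacts, and the
breathing-state-dependent intensity changes of real 4D data. Passing the
phantom study shows that the implementation preserves a planar sliding
discontinuity that isotropic smoothing destroys under matched conditions —
not that clinical accuracy figures transfer.

At the 64³ benchmark scale (2 levels × 30 iterations) the guided-filter
methods recover ≈54% of the 6-voxel jump at the measurement bands and cut
the landmark TRE by ≈73% versus ≈44% for the matched-strength Gaussian;
the residual gap to 100% jump recovery is the soft edge of the filter at
ε = 0.1, whose leak decays over roughly 2r voxels from the interface —
small volumes feel it more than clinical ones.

## Numerical choices

* Trilinear interpolation with edge clamping for warping, composition and
  field upsampling (zero-fill would create spurious border forces).
* Gradients by central differences (one-sided at borders), voxel units.
* Displacements stored in voxel units; mm appear only in TRE evaluation.
* Box filters via separable moving sums; counts cached per (shape, r).
* SLIC ties resolved by fixed center order (first center wins), making
  clustering bit-reproducible for a given seed.
* `resample_isotropic` rounds output dimensions (`round(n·s/target)`),
  preserving physical extent within one voxel; degenerate constant
  volumes normalize to zeros with a warning rather than dividing by zero.
* Direction cosines other than identity are rejected at I/O time; the
  solver assumes axis-aligned grids throughout.

## Known limitations

* The guided filter's edge preservation at ε = 0.1 is soft: a fraction of
  cross-interface kernel weight survives, so recovered jumps saturate
  below the truth (see above). Lower ε sharpens edges at the cost of
  noisier fields.
* The LCC force uses a window-center approximation of the correlation
  gradient; it is a descent heuristic, not an exact gradient.
* No inverse-consistency or diffeomorphism guarantee; folding is only
  diagnosed (Jacobian report), not prevented.
* 4-D sequences are handled as independent 3-D pairs; no temporal
  regularization.
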
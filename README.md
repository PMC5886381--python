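# gifdemons

Deformable image registration for organ motion with **sliding interfaces**,
built on the Demons framework with **guided-filter regularization driven by
supervoxel guidance images**.

## The problem

Demons registration alternates an intensity-driven force step with Gaussian
smoothing of the displacement field. That isotropic smoothing assumes motion
is smooth everywhere — but at the lung–pleura and liver–abdominal-wall
interfaces, organs *slide* tangentially against each other, producing a
discontinuous displacement field. Gaussian regularization blurs the
discontinuity, corrupting the estimate in a band around every sliding
surface. Methods that fix this with explicit sliding-surface segmentations
inherit the cost and fragility of the segmentation step; liver surfaces in
CT are particularly hard to segment.

This package replaces the Gaussian with a **guided image filter** whose
kernels are shaped by a pseudo-segmentation of the fixed image obtained by
**SLIC supervoxel clustering**. The filter transfers guidance structure
(organ interfaces) into the displacement field while smoothing homogeneous
regions, with no prior segmentation and in O(N) time per iteration.

## The method

One Demons iteration is

1. **Force** — symmetric intensity force
   `f = (I_F − I_M∘φ) / (‖∇I‖² + λκ²) · ∇I` with
   `∇I = ½(∇I_F + ∇(I_M∘φ))`, `κ = I_F − I_M∘φ`, `φ(x) = x + u(x)`;
   per-voxel step bounded by `1/(2√λ)`. A local-correlation (LCC) force,
   invariant to local affine intensity changes, is available for
   contrast-enhanced data.
2. **Update** — composition `u ← u ∘ f`.
3. **Regularization** — each component of `u` is filtered. Per cubic window
   N of radius r the guided filter fits `γ_N = cov(I_g, u)/(σ²_{I_g} + ε)`,
   `β_N = μ_u − γ_N μ_{I_g}` and averages `γ I_g + β` over all windows
   containing each voxel; the multichannel form solves
   `(Σ_{I_g} + εU) Γ_N = cov(I_g, u)` per window. Everything reduces to box
   filters, so cost is O(N) regardless of r.

The guidance image `I_g = [S₁ … S_M]` stacks per-supervoxel mean-intensity
renders of SLIC clusterings of the fixed image (joint distance
`D = √((d_xw/S)² + (d_I/m)²)`, `S = (N/K)^⅓`), either

* **rnd-gif** — M clusterings with Gaussian-perturbed seeds: strong image
  edges are reproduced in every channel, while clustering in homogeneous
  regions decorrelates across channels so no spurious structure survives;
* **mls-gif** — one clustering per cluster count K on a ladder, encoding
  structure at several spatial scales;
* **iso-dem** — the classic Gaussian baseline, with σ matched by default to
  the guided filter's interior smoothing so the comparison isolates edge
  awareness.

A coarse-to-fine pyramid (factor-2 decimation) wraps the iteration.
Accuracy is evaluated as landmark target registration error (TRE, mm).

## Worked example

The built-in phantom puts two textured regions (interface contrast ~0.7 of
the intensity range, interior texture ~4%) on either side of a plane and
slides them tangentially by ±3 voxels — a 6-voxel displacement jump that a
smooth regularizer cannot represent. Landmarks sit ≥3 voxels from the
interface; voxel size is 2 mm.

```bash
gifdemons benchmark --out report.csv --seed 1
```

prints

```
 method  tre_mean_mm  tre_sd_mm  mean_abs_residual  interface_jump_voxels  jump_fraction  frac_nonpos_jacobian status
initial     6.000000   0.000000           0.023415               0.000000       0.000000                   0.0     ok
iso-dem     3.387497   0.823299           0.016615               0.992559       0.165426                   0.0     ok
rnd-gif     1.653386   0.606705           0.015087               3.218554       0.536426                   0.0     ok
mls-gif     1.619453   0.584483           0.015068               3.281844       0.546974                   0.0     ok
```

Reading the table: landmarks start 6 mm (3 voxels) from their targets.
Gaussian regularization halves the error but smears the sliding interface —
it recovers only 17% of the true cross-interface jump. Both guided-filter
variants cut the TRE to ~1.6 mm (≈73% reduction), recover ~54% of the
6-voxel jump, and keep every interior Jacobian determinant positive (no
folding). Random and multiscale guidance perform nearly identically.

Registering your own volumes (NIfTI or MetaImage, axis-aligned):

```bash
gifdemons register --fixed exhale.nii.gz --moving inhale.nii.gz \
    --out field.nii.gz --warped aligned.nii.gz \
    --regularizer rnd-gif --similarity ssd --isotropic 2.0
```

The field is written as a 3-component vector volume in voxel units of the
fixed grid (pull-back convention: warping samples the moving image at
`x + u(x)`).

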
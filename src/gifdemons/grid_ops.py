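"""Displacement-field algebra on regular voxel grids.

Displacement fields are stored in voxel units on the reference grid as
``vectors[x, y, z, c]`` with ``c`` indexing the x/y/z components.  The
transformation they encode is the pull-back map ``phi(x) = x + u(x)``:
warping samples the moving image at ``x + u(x)``.  Out-of-bounds samples
are edge-clamped, which avoids spurious similarity forces at volume
borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .volume_io import Volume

__all__ = [
    "DisplacementField",
    "zero_field",
    "warp_volume",
    "compose_fields",
    "gaussian_smooth_field",
    "build_pyramid",
    "upsample_field",
    "spatial_gradient",
    "jacobian_determinant",
]


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement (voxel units) on a reference grid."""

    vectors: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"field must have shape (nx, ny, nz, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy(), self.spacing, self.origin)

    def with_vectors(self, vectors: np.ndarray) -> "DisplacementField":
        return DisplacementField(vectors, self.spacing, self.origin)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))


def zero_field(reference: Volume) -> DisplacementField:
    """The identity transformation on the grid of ``reference``."""
    return DisplacementField(
        np.zeros(reference.shape + (3,)), reference.spacing, reference.origin
    )


def _identity_coords(shape: tuple[int, int, int]) -> list[np.ndarray]:
    return list(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    )


def _sample_coords(field: DisplacementField) -> list[np.ndarray]:
    base = _identity_coords(field.shape)
    return [base[c] + field.vectors[..., c] for c in range(3)]


def warp_volume(moving: Volume, field: DisplacementField) -> Volume:
    """Pull-back warp: ``output(x) = moving(x + u(x))`` (trilinear)."""
    if moving.shape != field.shape:
        raise ValueError(
            f"grid mismatch: volume {moving.shape} vs field {field.shape}"
        )
    if not np.any(field.vectors):
        return moving.with_data(moving.data.copy())
    coords = _sample_coords(field)
    data = map_coordinates(moving.data, coords, order=1, mode="nearest")
    return Volume(data, field.spacing, field.origin)


def compose_fields(u: DisplacementField, f: DisplacementField) -> DisplacementField:
    """Composition ``(u o f)(x) = f(x) + u(x + f(x))``.

    Applying the composed field is equivalent to applying ``f`` first and
    then ``u``; with the zero field on either side it is exact identity.
    """
    if u.shape != f.shape:
        raise ValueError(f"grid mismatch: {u.shape} vs {f.shape}")
    if not np.any(f.vectors):
        return u.copy()
    if not np.any(u.vectors):
        return f.copy()
    coords = _sample_coords(f)
    out = np.empty_like(u.vectors)
    for c in range(3):
        out[..., c] = f.vectors[..., c] + map_coordinates(
            u.vectors[..., c], coords, order=1, mode="nearest"
        )
    return u.with_vectors(out)


def gaussian_smooth_field(
    field: DisplacementField, sigma: float
) -> DisplacementField:
    """Separable Gaussian smoothing of each component (sigma in voxels)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return field.copy()
    out = np.empty_like(field.vectors)
    for c in range(3):
        out[..., c] = gaussian_filter(field.vectors[..., c], sigma, mode="nearest")
    return field.with_vectors(out)


def build_pyramid(volume: Volume, levels: int) -> list[Volume]:
    """Coarse-to-fine pyramid: level 0 is the original volume.

    Each subsequent level is Gaussian pre-smoothed (sigma = 1 voxel) and
    decimated by a factor of 2 per axis; voxel spacing doubles per level.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    coarsest = [n // 2 ** (levels - 1) for n in volume.shape]
    if min(coarsest) < 4:
        raise ValueError(
            f"{levels} levels too many for volume of shape {volume.shape}: "
            "coarsest level would have < 4 voxels per axis"
        )
    pyramid = [volume]
    for _ in range(1, levels):
        prev = pyramid[-1]
        smoothed = gaussian_filter(prev.data, 1.0, mode="nearest")
        data = smoothed[::2, ::2, ::2]
        pyramid.append(
            Volume(data, tuple(2 * s for s in prev.spacing), prev.origin)
        )
    return pyramid


def upsample_field(
    field: DisplacementField,
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float] | None = None,
) -> DisplacementField:
    """Trilinear upsampling to a finer grid with voxel-unit rescaling.

    Components are multiplied by the per-axis dimension ratio (about 2 for
    one pyramid step) because displacements are stored in voxel units.
    """
    src_shape = field.shape
    ratios = [nt / ns for nt, ns in zip(target_shape, src_shape)]
    if target_spacing is None:
        target_spacing = tuple(
            s / r for s, r in zip(field.spacing, ratios)
        )
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) for n in target_shape], indexing="ij"
    )
    coords = [g / r for g, r in zip(grids, ratios)]
    out = np.empty(tuple(target_shape) + (3,))
    for c in range(3):
        out[..., c] = ratios[c] * map_coordinates(
            field.vectors[..., c], coords, order=1, mode="nearest"
        )
    return DisplacementField(out, target_spacing, field.origin)


def spatial_gradient(volume: Volume) -> np.ndarray:
    """Per-voxel intensity gradient in voxel units, shape ``(nx,ny,nz,3)``.

    Central differences in the interior, one-sided at the borders.
    """
    gx, gy, gz = np.gradient(volume.data)
    return np.stack([gx, gy, gz], axis=-1)


def jacobian_determinant(field: DisplacementField) -> Volume:
    """``det(grad phi)`` with ``phi = identity + u`` (finite differences).

    Equals 1 everywhere for any pure translation; values <= 0 flag folding.
    """
    if any(n < 3 for n in field.shape):
        raise ValueError("need at least 3 voxels per axis for the Jacobian")
    J = np.empty(field.shape + (3, 3))
    for i in range(3):
        grads = np.gradient(field.vectors[..., i])
        for j in range(3):
            J[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
    det = (
        J[..., 0, 0] * (J[..., 1, 1] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 1])
        - J[..., 0, 1] * (J[..., 1, 0] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 0])
        + J[..., 0, 2] * (J[..., 1, 0] * J[..., 2, 1] - J[..., 1, 1] * J[..., 2, 0])
    )
    return Volume(det, field.spacing, field.origin)
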
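"""Demons update forces: symmetric SSD and a local-correlation variant.

The symmetric SSD force at each voxel is

    f = (I_F - I_M o phi) / (||grad I||^2 + lambda * kappa^2) * grad I

with ``grad I`` the average of the fixed and warped-moving gradients and
``kappa = I_F - I_M o phi`` acting as a local noise estimate.  The
``lambda`` weight caps the step length: ``||f|| <= 1 / (2 sqrt(lambda))``
per voxel (AM-GM on the denominator).  Voxels with a near-zero denominator
produce zero force.

The LCC force replaces the raw residual by a locally affine-corrected one:
per cubic window the best linear fit of the warped moving image to the
fixed image is subtracted, making the force invariant to local affine
intensity changes (contrast wash-in/out).  The corrected residual is fed
through the same bounded Demons normalization.  This is a
local-correlation-coefficient-style force computed with box-window
statistics; windows with negligible variance in either image yield zero
force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_ops import DisplacementField, spatial_gradient, warp_volume
from .guided_filter import box_mean_array
from .volume_io import Volume

__all__ = ["ForceParams", "ssd_symmetric_force", "lcc_force"]


@dataclass(frozen=True)
class ForceParams:
    """Force-step knobs.

    lam: step-control weight (dimensionless); the per-voxel force magnitude
        is bounded by 1/(2*sqrt(lam)).
    denom_floor: stability threshold below which the force is zeroed.
    lcc_radius: cubic window radius (voxels) for local correlation stats.
    """

    lam: float = 1.0
    denom_floor: float = 1e-9
    lcc_radius: int = 4

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.denom_floor <= 0:
            raise ValueError("denom_floor must be > 0")
        if self.lcc_radius < 1:
            raise ValueError("lcc_radius must be >= 1")


def _check_grids(fixed: Volume, moving: Volume, u: DisplacementField) -> None:
    if fixed.shape != moving.shape or fixed.shape != u.shape:
        raise ValueError(
            f"grid mismatch: fixed {fixed.shape}, moving {moving.shape}, "
            f"field {u.shape}"
        )


def _demons_normalize(
    residual: np.ndarray, grad: np.ndarray, params: ForceParams
) -> np.ndarray:
    """Residual-driven step with the Demons bounded normalization."""
    grad_sq = np.sum(grad**2, axis=-1)
    denom = grad_sq + params.lam * residual**2
    safe = denom >= params.denom_floor
    scale = np.where(safe, residual / np.where(safe, denom, 1.0), 0.0)
    return scale[..., None] * grad


def ssd_symmetric_force(
    fixed: Volume,
    moving: Volume,
    u: DisplacementField,
    params: ForceParams = ForceParams(),
) -> DisplacementField:
    """Symmetric-gradient SSD Demons force for the current alignment."""
    _check_grids(fixed, moving, u)
    warped = warp_volume(moving, u)
    residual = fixed.data - warped.data
    grad = 0.5 * (spatial_gradient(fixed) + spatial_gradient(warped))
    return u.with_vectors(_demons_normalize(residual, grad, params))


def lcc_force(
    fixed: Volume,
    moving: Volume,
    u: DisplacementField,
    params: ForceParams = ForceParams(),
) -> DisplacementField:
    """Local-correlation force, invariant to local affine intensity changes."""
    _check_grids(fixed, moving, u)
    warped = warp_volume(moving, u)
    r = params.lcc_radius
    F = fixed.data
    W = warped.data
    mu_f = box_mean_array(F, r)
    mu_w = box_mean_array(W, r)
    var_f = box_mean_array(F * F, r) - mu_f**2
    var_w = box_mean_array(W * W, r) - mu_w**2
    cov = box_mean_array(F * W, r) - mu_f * mu_w
    valid = (var_f >= params.denom_floor) & (var_w >= params.denom_floor)
    slope = np.where(valid, cov / np.where(valid, var_w, 1.0), 0.0)
    # Residual after the per-window affine fit of W to F; zero wherever
    # either image is locally flat.
    residual = np.where(valid, (F - mu_f) - slope * (W - mu_w), 0.0)
    grad = 0.5 * (spatial_gradient(fixed) + spatial_gradient(warped))
    return u.with_vectors(_demons_normalize(residual, grad, params))
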
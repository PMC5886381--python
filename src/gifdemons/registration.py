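"""Multiresolution Demons registration with pluggable regularization.

One iteration alternates (i) a per-voxel similarity force, (ii) a
composition update ``u <- u o f`` and (iii) regularization of the composed
field.  The regularizer is either an isotropic Gaussian (``iso-dem``, the
classic diffusion-like scheme) or a guided filter driven by supervoxel
guidance built from the fixed image (``rnd-gif``: randomly perturbed
clusterings as channels; ``mls-gif``: one channel per cluster-count on a
ladder).  Guidance depends only on the fixed image, so it is computed once
per pyramid level and reused across iterations.

A coarse-to-fine pyramid (factor-2 decimation) stabilizes large motions;
the field recovered at each level is trilinearly upsampled (with voxel-
unit rescaling) to initialize the next.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .grid_ops import (
    DisplacementField,
    build_pyramid,
    compose_fields,
    gaussian_smooth_field,
    upsample_field,
    warp_volume,
    zero_field,
)
from .guided_filter import GifParams, GuidanceImage, regularize_field
from .similarity_forces import ForceParams, lcc_force, ssd_symmetric_force
from .supervoxels import (
    SlicParams,
    build_multiscale_guidance,
    build_random_guidance,
)
from .volume_io import Volume

__all__ = [
    "RegistrationConfig",
    "RegistrationError",
    "demons_iteration",
    "has_converged",
    "register_pair",
]

logger = logging.getLogger("gifdemons")

REGULARIZERS = ("iso-dem", "rnd-gif", "mls-gif")
SIMILARITIES = ("ssd", "lcc")


class RegistrationError(RuntimeError):
    """Raised when a registration run diverges or is misconfigured."""


@dataclass
class RegistrationConfig:
    """All solver knobs for one registration run.

    Defaults mirror the reference parameterization: 3 pyramid levels, up to
    50 iterations per level, guided-filter radius r=5 and epsilon=0.1,
    SLIC compactness m=24 with K=3750 target supervoxels and M=3 guidance
    channels.  ``gaussian_sigma`` (voxels) applies only to the ``iso-dem``
    baseline; its default 4.5 matches the interior smoothing of the guided
    filter at r=5 (the aggregated filter acts as a double box of width
    2r+1 in homogeneous-guidance regions, variance 2*((2r+1)^2 - 1)/12),
    so the two regularizers differ only in edge awareness, not strength.
    ``tol`` stops a level once the mean per-voxel update magnitude falls
    below it.
    """

    levels: int = 3
    iter_max: int = 50
    similarity: str = "ssd"
    regularizer: str = "rnd-gif"
    gif: GifParams = dc_field(default_factory=GifParams)
    slic: SlicParams = dc_field(default_factory=SlicParams)
    channels: int = 3
    K_ladder: tuple[int, ...] | None = None
    lam: float = 1.0
    denom_floor: float = 1e-9
    lcc_radius: int = 4
    gaussian_sigma: float = 4.5
    tol: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.iter_max < 1:
            raise ValueError("iter_max must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.similarity not in SIMILARITIES:
            raise ValueError(f"similarity must be one of {SIMILARITIES}")
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"regularizer must be one of {REGULARIZERS}")

    def force_params(self) -> ForceParams:
        return ForceParams(
            lam=self.lam, denom_floor=self.denom_floor, lcc_radius=self.lcc_radius
        )

    def ladder(self) -> tuple[int, ...]:
        if self.K_ladder is not None:
            return tuple(self.K_ladder)
        K = self.slic.K
        return (K, max(1, K // 2), max(1, K // 4))


def _compute_force(
    fixed: Volume, moving: Volume, u: DisplacementField, config: RegistrationConfig
) -> DisplacementField:
    params = config.force_params()
    if config.similarity == "ssd":
        return ssd_symmetric_force(fixed, moving, u, params)
    return lcc_force(fixed, moving, u, params)


def demons_iteration(
    fixed: Volume,
    moving: Volume,
    u: DisplacementField,
    guidance: GuidanceImage | None,
    config: RegistrationConfig,
) -> DisplacementField:
    """One Demons step: force, composition update, regularization."""
    if config.regularizer != "iso-dem" and guidance is None:
        raise ValueError(
            f"regularizer {config.regularizer!r} requires a guidance image"
        )
    f = _compute_force(fixed, moving, u, config)
    updated = compose_fields(u, f)
    if config.regularizer == "iso-dem":
        return gaussian_smooth_field(updated, config.gaussian_sigma)
    return regularize_field(updated, guidance, config.gif)


def has_converged(
    u_new: DisplacementField, u_old: DisplacementField, tol: float
) -> bool:
    """True iff the mean voxel-wise update norm dropped below ``tol``."""
    if u_new.shape != u_old.shape:
        raise ValueError("fields must share one grid")
    diff = u_new.vectors - u_old.vectors
    return float(np.mean(np.sqrt(np.sum(diff**2, axis=-1)))) < tol


def _scaled_K(K: int, level: int) -> int:
    """Keep the supervoxel edge length roughly constant across levels."""
    return max(8, int(round(K / 8**level)))


def build_guidance_for_level(
    fixed_level: Volume, level: int, config: RegistrationConfig
) -> GuidanceImage | None:
    if config.regularizer == "iso-dem":
        return None
    slic = replace(
        config.slic,
        K=min(_scaled_K(config.slic.K, level), fixed_level.data.size),
        rng_seed=config.rng_seed,
    )
    if config.regularizer == "rnd-gif":
        return build_random_guidance(fixed_level, slic, config.channels)
    ladder = [
        min(_scaled_K(K, level), fixed_level.data.size) for K in config.ladder()
    ]
    # Scaling can collapse ladder entries; keep them strictly monotone.
    dedup: list[int] = []
    for K in ladder:
        if not dedup or K != dedup[-1]:
            dedup.append(K)
    return build_multiscale_guidance(fixed_level, slic, dedup)


def register_pair(
    fixed: Volume, moving: Volume, config: RegistrationConfig
) -> DisplacementField:
    """Coarse-to-fine Demons registration of a preprocessed volume pair.

    Returns the displacement field mapping fixed-grid points into the
    moving image (pull-back convention: ``warp_volume(moving, u) ~ fixed``).
    Inputs are expected to be intensity-normalized to a shared scale.
    """
    if fixed.shape != moving.shape:
        raise ValueError(
            f"fixed {fixed.shape} and moving {moving.shape} must share a grid"
        )
    if not fixed.same_grid(moving):
        raise ValueError("fixed and moving volumes must share spacing and origin")
    fixed_pyr = build_pyramid(fixed, config.levels)
    moving_pyr = build_pyramid(moving, config.levels)
    u: DisplacementField | None = None
    for level in range(config.levels - 1, -1, -1):
        f_lvl = fixed_pyr[level]
        m_lvl = moving_pyr[level]
        if u is None:
            u = zero_field(f_lvl)
        else:
            u = upsample_field(u, f_lvl.shape, f_lvl.spacing)
        guidance = build_guidance_for_level(f_lvl, level, config)
        max_extent = max(f_lvl.shape)
        for it in range(config.iter_max):
            u_new = demons_iteration(f_lvl, m_lvl, u, guidance, config)
            mean_disp = float(np.mean(u_new.magnitude()))
            if mean_disp > max_extent / 3.0:
                raise RegistrationError(
                    f"divergence at level {level}, iteration {it}: mean "
                    f"displacement {mean_disp:.2f} voxels exceeds a third of "
                    f"the image extent ({max_extent})"
                )
            converged = has_converged(u_new, u, config.tol)
            update = float(
                np.mean(np.sqrt(np.sum((u_new.vectors - u.vectors) ** 2, axis=-1)))
            )
            u = u_new
            logger.debug(
                "level=%d iter=%d mean_update=%.4f mean_disp=%.4f",
                level,
                it,
                update,
                mean_disp,
            )
            if converged:
                logger.info(
                    "level %d converged after %d iterations (update %.4f)",
                    level,
                    it + 1,
                    update,
                )
                break
        else:
            logger.info("level %d reached iter_max=%d", level, config.iter_max)
    assert u is not None
    return u
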
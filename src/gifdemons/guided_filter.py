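"""Linear-time guided image filtering of volumes and displacement fields.

The guided filter expresses its output as a local linear function of a
guidance image: within each cubic window N of radius ``r`` the coefficients

    gamma_N = cov_N(I_g, I_i) / (var_N(I_g) + eps)
    beta_N  = mean_N(I_i) - gamma_N * mean_N(I_g)

are fitted, and the output at a voxel averages ``gamma * I_g + beta`` over
every window containing it.  The whole computation reduces to a handful of
box means and therefore runs in O(N) independent of the radius.  Small
``eps`` preserves guidance edges in the filtered signal; large ``eps``
degenerates to plain (double) box smoothing.

For an M-channel guidance image the per-window fit solves the regularized
M x M system ``(Sigma + eps U) Gamma = cov(I_g, I_i)`` where ``Sigma`` is
the window covariance of the guidance channels.

Windows are truncated at the volume borders and every mean is normalized
by the true in-bounds voxel count, so kernel weights sum to exactly 1
everywhere and constant inputs are fixed points of the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .grid_ops import DisplacementField
from .volume_io import Volume

__all__ = [
    "GifParams",
    "GuidanceImage",
    "box_mean",
    "box_mean_array",
    "guided_filter_single",
    "guided_filter_multichannel",
    "explicit_kernel_weights",
    "filter_with_kernel_weights",
    "regularize_field",
]


@dataclass(frozen=True)
class GifParams:
    """Guided-filter knobs.

    r: cubic window radius in voxels (full width 2r+1).
    epsilon: edge-preservation parameter, dimensionless on [0,1]-normalized
        guidance; smaller values preserve guidance edges more strongly.
    """

    r: int = 5
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("window radius r must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


_count_cache: dict[tuple[tuple[int, ...], int], np.ndarray] = {}


def _window_counts(shape: tuple[int, ...], r: int) -> np.ndarray:
    """In-bounds voxel count of the truncated cubic window at every voxel."""
    key = (tuple(shape), r)
    cached = _count_cache.get(key)
    if cached is not None:
        return cached
    per_axis = []
    for n in shape:
        idx = np.arange(n)
        per_axis.append(
            np.minimum(idx + r, n - 1) - np.maximum(idx - r, 0) + 1.0
        )
    counts = per_axis[0][:, None, None] * per_axis[1][None, :, None] * per_axis[2][None, None, :]
    _count_cache[key] = counts
    return counts


def _box_sum(arr: np.ndarray, r: int) -> np.ndarray:
    """Separable moving-window sum with zero-padded (truncated) borders."""
    size = 2 * r + 1
    out = arr.astype(np.float64, copy=True)
    for axis in range(arr.ndim):
        out = uniform_filter1d(out, size, axis=axis, mode="constant", cval=0.0)
    return out * size**arr.ndim


def box_mean_array(arr: np.ndarray, r: int) -> np.ndarray:
    """Truncated-window box mean (normalized by in-bounds counts)."""
    if r < 1:
        raise ValueError("r must be >= 1")
    return _box_sum(arr, r) / _window_counts(arr.shape, r)


def box_mean(volume: Volume, r: int) -> Volume:
    """Cubic-window mean of a Volume, truncated at the borders."""
    return volume.with_data(box_mean_array(volume.data, r))


@dataclass
class GuidanceImage:
    """M-channel guidance volume, each channel normalized to [0, 1].

    ``data`` has shape ``(nx, ny, nz, M)``.  Per-(r, epsilon) window
    statistics are cached because guidance is typically reused across many
    filtering calls within one registration level.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    _stats_cache: dict = dc_field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4 or self.data.shape[-1] < 1:
            raise ValueError(
                f"guidance must have shape (nx, ny, nz, M), got {self.data.shape}"
            )
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise ValueError("guidance channels must be normalized to [0, 1]")

    @classmethod
    def from_volumes(cls, channels: list[Volume]) -> "GuidanceImage":
        if not channels:
            raise ValueError("at least one guidance channel required")
        first = channels[0]
        for ch in channels[1:]:
            if not ch.same_grid(first):
                raise ValueError("all guidance channels must share one grid")
        return cls(
            np.stack([ch.data for ch in channels], axis=-1),
            first.spacing,
            first.origin,
        )

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def window_stats(self, params: GifParams) -> "_GuidanceStats":
        key = (params.r, params.epsilon)
        stats = self._stats_cache.get(key)
        if stats is None:
            stats = _GuidanceStats(self, params)
            self._stats_cache[key] = stats
        return stats


class _GuidanceStats:
    """Window means and regularized inverse covariance of a guidance image."""

    def __init__(self, guidance: GuidanceImage, params: GifParams) -> None:
        g = guidance.data
        M = guidance.n_channels
        r = params.r
        self.r = r
        self.means = np.stack(
            [box_mean_array(g[..., k], r) for k in range(M)], axis=-1
        )
        cov = np.empty(g.shape[:3] + (M, M))
        for i in range(M):
            for j in range(i, M):
                cij = box_mean_array(g[..., i] * g[..., j], r) - (
                    self.means[..., i] * self.means[..., j]
                )
                cov[..., i, j] = cij
                cov[..., j, i] = cij
        cov[..., np.arange(M), np.arange(M)] += params.epsilon
        if M == 1:
            self.inv = 1.0 / cov
        else:
            self.inv = np.linalg.inv(cov)


def guided_filter_single(
    guidance: Volume | GuidanceImage, input: Volume, params: GifParams
) -> Volume:
    """Single-channel guided filtering of a scalar volume."""
    if isinstance(guidance, Volume):
        guidance = GuidanceImage(guidance.data, guidance.spacing, guidance.origin)
    if guidance.n_channels != 1:
        raise ValueError("guided_filter_single expects a single-channel guidance")
    return guided_filter_multichannel(guidance, input, params)


def guided_filter_multichannel(
    guidance: GuidanceImage, input: Volume, params: GifParams
) -> Volume:
    """Multichannel guided filtering of a scalar volume."""
    if guidance.shape != input.shape:
        raise ValueError(
            f"grid mismatch: guidance {guidance.shape} vs input {input.shape}"
        )
    data = _filter_array(guidance, input.data, params)
    return input.with_data(data)


def _filter_array(
    guidance: GuidanceImage, arr: np.ndarray, params: GifParams
) -> np.ndarray:
    stats = guidance.window_stats(params)
    g = guidance.data
    M = guidance.n_channels
    r = params.r
    mi = box_mean_array(arr, r)
    cross = np.stack(
        [
            box_mean_array(g[..., k] * arr, r) - stats.means[..., k] * mi
            for k in range(M)
        ],
        axis=-1,
    )
    gamma = np.einsum("...ij,...j->...i", stats.inv, cross)
    beta = mi - np.einsum("...k,...k->...", gamma, stats.means)
    out = box_mean_array(beta, r)
    for k in range(M):
        out += box_mean_array(gamma[..., k], r) * g[..., k]
    return out


def explicit_kernel_weights(
    guidance: GuidanceImage, x: tuple[int, int, int], params: GifParams
) -> np.ndarray:
    """Aggregated kernel weights of the guided filter at voxel ``x``.

    Returns a full-volume weight map W(x, .) computed directly from the
    definition: the summand ``1 + (I_g(x)-mu)^T (Sigma+eps U)^{-1}
    (I_g(y)-mu)`` is averaged over every window containing both voxels,
    with per-window statistics evaluated naively.  The weights sum to 1.
    This O(r^6)-per-voxel path exists as an independent reference for the
    fast box-filter implementation; use the fast path for real filtering.
    """
    g = guidance.data
    M = guidance.n_channels
    r = params.r
    shape = guidance.shape
    x = tuple(int(v) for v in x)
    for v, n in zip(x, shape):
        if not 0 <= v < n:
            raise ValueError(f"voxel {x} out of bounds for shape {shape}")
    W = np.zeros(shape)
    gx = g[x]
    # Windows are indexed by their center voxel k; x is in window k iff k
    # is within the (truncated) cube of radius r around x.
    centers = [
        range(max(0, x[a] - r), min(shape[a], x[a] + r + 1)) for a in range(3)
    ]
    eye = np.eye(M)
    n_x = 0
    for kx in centers[0]:
        for ky in centers[1]:
            for kz in centers[2]:
                n_x += 1
                sl = tuple(
                    slice(max(0, c - r), min(n, c + r + 1))
                    for c, n in zip((kx, ky, kz), shape)
                )
                patch = g[sl].reshape(-1, M)
                n_k = patch.shape[0]
                mu = patch.mean(axis=0)
                centered = patch - mu
                sigma = centered.T @ centered / n_k
                A = np.linalg.inv(sigma + params.epsilon * eye)
                w = 1.0 + centered @ (A @ (gx - mu))
                W[sl] += (w / n_k).reshape(g[sl].shape[:3])
    W /= n_x
    return W


def filter_with_kernel_weights(
    guidance: GuidanceImage, input: Volume, params: GifParams
) -> Volume:
    """Brute-force guided filtering via explicit kernel weights.

    Reference path (quadratic cost); equals the fast path to float
    precision.
    """
    out = np.empty(input.shape)
    for idx in np.ndindex(*input.shape):
        W = explicit_kernel_weights(guidance, idx, params)
        out[idx] = float(np.sum(W * input.data))
    return input.with_data(out)


def regularize_field(
    u: DisplacementField, guidance: GuidanceImage, params: GifParams
) -> DisplacementField:
    """Guided filtering of each displacement component independently.

    This is the structure-transferring regularization step: guidance edges
    (e.g. supervoxel boundaries at a sliding interface) survive in the
    filtered field, while homogeneous-guidance regions are smoothed.
    """
    if u.shape != guidance.shape:
        raise ValueError(f"grid mismatch: field {u.shape} vs guidance {guidance.shape}")
    out = np.empty_like(u.vectors)
    for c in range(3):
        out[..., c] = _filter_array(guidance, u.vectors[..., c], params)
    return u.with_vectors(out)
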
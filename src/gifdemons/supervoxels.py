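"""3-D SLIC supervoxel clustering and supervoxel-based guidance images.

SLIC partitions a volume into approximately K compact, intensity-
homogeneous clusters by localized k-means in a joint spatial+intensity
space.  The distance between a voxel x and a cluster center w combines the
Euclidean spatial distance ``d_xw`` and the intensity distance ``d_I``:

    D = sqrt((d_xw / S)^2 + (d_I / m)^2)

where ``S = (N / K)^(1/3)`` is the initial center sampling interval and
``m`` weights compactness against edge adherence.  Intensities are
internally rescaled to [0, 255] (the 8-bit convention of the original
algorithm) so that the conventional default ``m = 24`` is scale-meaningful
regardless of the input's intensity units.

Guidance images for displacement-field regularization are built by
rendering each clustering as a per-supervoxel mean-intensity volume
(normalized to [0, 1]) and stacking renders as channels:

* random guidance: the clustering is repeated with Gaussian-perturbed
  seed positions; homogeneous regions cluster differently per channel
  (no spurious structure survives averaging) while strong image edges
  are reproduced in every channel;
* multiscale guidance: one channel per cluster count K on a ladder,
  encoding motion structure at several spatial scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .guided_filter import GuidanceImage
from .volume_io import Volume

__all__ = [
    "SlicParams",
    "SupervoxelLabeling",
    "slic_distance",
    "slic_cluster",
    "enforce_connectivity",
    "render_channel",
    "build_random_guidance",
    "build_multiscale_guidance",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SlicParams:
    """SLIC knobs.

    K: target supervoxel count.
    m: compactness weight on the [0, 255] internal intensity scale; larger
        values give more regular, cube-like clusters.
    i_max: maximum k-means iterations (stops early on label convergence).
    sigma_z: std (voxels) of the Gaussian seed perturbation; ``None``
        selects S/4, 0 disables perturbation.
    mu_z: mean (voxels) of the seed perturbation.
    rng_seed: seed for the perturbation RNG (identical seeds give
        bit-identical clusterings).
    """

    K: int = 3750
    m: float = 24.0
    i_max: int = 10
    sigma_z: float | None = None
    mu_z: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.m <= 0:
            raise ValueError("m must be > 0")
        if self.i_max < 1:
            raise ValueError("i_max must be >= 1")
        if self.sigma_z is not None and self.sigma_z < 0:
            raise ValueError("sigma_z must be >= 0")


@dataclass
class SupervoxelLabeling:
    """Integer partition of a volume into supervoxels.

    labels: per-voxel cluster id in [0, n_labels); every label non-empty.
    centers: (L, 3) cluster center positions (voxel coordinates).
    center_intensity: (L,) mean intensity per cluster (internal scale).
    S: initial center sampling interval ``(N/K)^(1/3)`` in voxels.
    """

    labels: np.ndarray
    centers: np.ndarray
    center_intensity: np.ndarray
    S: float
    n_iter: int = 0
    converged: bool = False

    @property
    def n_labels(self) -> int:
        return len(self.centers)


def slic_distance(d_xw: float, d_I: float, S: float, m: float):
    """Joint SLIC distance ``sqrt((d_xw/S)^2 + (d_I/m)^2)``."""
    if np.any(np.asarray(S) <= 0) or np.any(np.asarray(m) <= 0):
        raise ValueError("S and m must be > 0")
    return np.sqrt((np.asarray(d_xw) / S) ** 2 + (np.asarray(d_I) / m) ** 2)


def _rescale_255(data: np.ndarray) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0:
        return np.zeros_like(data)
    return (data - lo) * (255.0 / (hi - lo))


def _initial_centers(
    shape: tuple[int, int, int], S: float, params: SlicParams, rng: np.random.Generator
) -> np.ndarray:
    axes = []
    for n in shape:
        n_seeds = max(1, int(round(n / S)))
        axes.append((np.arange(n_seeds) + 0.5) * (n / n_seeds) - 0.5)
    grid = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([g.ravel() for g in grid], axis=-1)
    sigma = params.sigma_z if params.sigma_z is not None else S / 4.0
    if sigma > 0 or params.mu_z != 0:
        centers = centers + rng.normal(params.mu_z, sigma, size=centers.shape)
    for a in range(3):
        centers[:, a] = np.clip(centers[:, a], 0, shape[a] - 1)
    return centers


def _snap_to_low_gradient(
    centers: np.ndarray, grad_mag: np.ndarray
) -> np.ndarray:
    """Move each seed to the lowest-gradient voxel of its 3^3 neighborhood."""
    shape = grad_mag.shape
    snapped = np.empty_like(centers)
    for idx, c in enumerate(np.rint(centers).astype(int)):
        sl = tuple(
            slice(max(0, c[a] - 1), min(shape[a], c[a] + 2)) for a in range(3)
        )
        patch = grad_mag[sl]
        off = np.unravel_index(int(np.argmin(patch)), patch.shape)
        snapped[idx] = [sl[a].start + off[a] for a in range(3)]
    return snapped


def slic_cluster(volume: Volume, params: SlicParams) -> SupervoxelLabeling:
    """Cluster a volume into ~K compact supervoxels.

    Seeds start on a regular grid with interval S, are optionally perturbed
    by N(mu_z, sigma_z^2) and snapped to the locally flattest voxel;
    assignment is restricted to a 2S search window per center; centers are
    recomputed until the labeling converges or ``i_max`` is reached; 26-
    connectivity is then enforced.
    """
    shape = volume.shape
    N = volume.data.size
    if params.K > N:
        raise ValueError(f"K={params.K} exceeds voxel count {N}")
    S = (N / params.K) ** (1.0 / 3.0)
    intens = _rescale_255(volume.data)
    rng = np.random.default_rng(params.rng_seed)
    centers = _initial_centers(shape, S, params, rng)
    gx, gy, gz = np.gradient(intens)
    grad_mag = gx**2 + gy**2 + gz**2
    centers = _snap_to_low_gradient(centers, grad_mag)
    c_int = intens[tuple(np.rint(centers).astype(int).T)]

    hw = max(1, int(np.ceil(S)))
    labels = np.full(shape, -1, dtype=np.int32)
    prev_labels = None
    converged = False
    n_iter = 0
    inv_S2 = 1.0 / S**2
    inv_m2 = 1.0 / params.m**2
    for n_iter in range(1, params.i_max + 1):
        best = np.full(shape, np.inf)
        labels.fill(-1)
        for li in range(len(centers)):
            cx, cy, cz = centers[li]
            # Voxels within +-hw of the (fractional) center position.
            sl = tuple(
                slice(
                    max(0, int(np.ceil(c - hw))),
                    min(n, int(np.floor(c + hw)) + 1),
                )
                for c, n in zip((cx, cy, cz), shape)
            )
            ax = np.arange(sl[0].start, sl[0].stop, dtype=np.float64) - cx
            ay = np.arange(sl[1].start, sl[1].stop, dtype=np.float64) - cy
            az = np.arange(sl[2].start, sl[2].stop, dtype=np.float64) - cz
            d2 = (
                ax[:, None, None] ** 2
                + ay[None, :, None] ** 2
                + az[None, None, :] ** 2
            ) * inv_S2 + (intens[sl] - c_int[li]) ** 2 * inv_m2
            closer = d2 < best[sl]
            best[sl][closer] = d2[closer]
            labels[sl][closer] = li
        unassigned = labels < 0
        if np.any(unassigned):
            tree = cKDTree(centers)
            pts = np.argwhere(unassigned).astype(np.float64)
            _, nearest = tree.query(pts)
            labels[unassigned] = nearest.astype(np.int32)
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            converged = True
            break
        prev_labels = labels.copy()
        centers, c_int, labels = _recompute_centers(labels, intens, shape)
    labeling = SupervoxelLabeling(labels, centers, c_int, S, n_iter, converged)
    return enforce_connectivity(labeling, intensities=intens)


def _recompute_centers(
    labels: np.ndarray, intens: np.ndarray, shape: tuple[int, int, int]
):
    """Per-label centroid position and mean intensity; drops empty labels."""
    n = int(labels.max()) + 1
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n)
    keep = counts > 0
    remap = -np.ones(n, dtype=np.int32)
    remap[keep] = np.arange(int(keep.sum()), dtype=np.int32)
    labels = remap[labels]
    counts = counts[keep].astype(np.float64)
    flat = labels.ravel()
    coords = np.indices(shape).reshape(3, -1)
    centers = np.stack(
        [np.bincount(flat, weights=coords[a]) / counts for a in range(3)],
        axis=-1,
    )
    c_int = np.bincount(flat, weights=intens.ravel()) / counts
    return centers, c_int, labels


def enforce_connectivity(
    labeling: SupervoxelLabeling, intensities: np.ndarray | None = None
) -> SupervoxelLabeling:
    """Make every label 26-connected.

    The largest component of each label keeps the label; disconnected
    fragments of at least ``S^3 / 4`` voxels become new labels; smaller
    orphan fragments are merged into the dominant adjacent label.
    Idempotent on already-connected labelings.
    """
    labels = labeling.labels
    shape = labels.shape
    comp = np.zeros(shape, dtype=np.int32)
    next_comp = 0
    comp_label: list[int] = []
    bboxes = ndimage.find_objects(labels + 1)
    for li, bbox in enumerate(bboxes):
        if bbox is None:
            continue
        mask = labels[bbox] == li
        lab, n_comp = ndimage.label(mask, structure=_CONN26)
        comp[bbox][mask] = lab[mask] + next_comp
        comp_label.extend([li] * n_comp)
        next_comp += n_comp
    comp -= 1  # component ids now 0-based
    sizes = np.bincount(comp.ravel(), minlength=next_comp)
    threshold = labeling.S**3 / 4.0

    # Decide each component's fate.
    new_label_of_comp = np.full(next_comp, -1, dtype=np.int64)
    largest: dict[int, int] = {}
    for ci in range(next_comp):
        li = comp_label[ci]
        if li not in largest or sizes[ci] > sizes[largest[li]]:
            largest[li] = ci
    next_label = int(labels.max()) + 1
    orphans: list[int] = []
    for ci in range(next_comp):
        if ci == largest[comp_label[ci]]:
            new_label_of_comp[ci] = comp_label[ci]
        elif sizes[ci] >= threshold:
            new_label_of_comp[ci] = next_label
            next_label += 1
        else:
            orphans.append(ci)

    out = new_label_of_comp[comp]
    if orphans:
        slices = ndimage.find_objects(comp + 1)
        pending = list(orphans)
        while pending:
            progressed = False
            deferred = []
            for ci in pending:
                sl = slices[ci]
                pad = tuple(
                    slice(max(0, s.start - 1), min(n, s.stop + 1))
                    for s, n in zip(sl, shape)
                )
                mask = comp[pad] == ci
                ring = ndimage.binary_dilation(mask, structure=_CONN26) & ~mask
                neighbor_labels = out[pad][ring]
                neighbor_labels = neighbor_labels[neighbor_labels >= 0]
                if neighbor_labels.size == 0:
                    deferred.append(ci)
                    continue
                vals, cnts = np.unique(neighbor_labels, return_counts=True)
                out[pad][mask] = vals[np.argmax(cnts)]
                progressed = True
            if not progressed and deferred:
                # Isolated orphan cluster surrounded only by orphans: keep
                # the largest as a fresh label to guarantee termination.
                ci = deferred.pop(0)
                out[comp == ci] = next_label
                next_label += 1
            pending = deferred

    if intensities is None:
        intensities = np.asarray(labeling.center_intensity)[labeling.labels]
    centers, c_int, out = _recompute_centers(
        out.astype(np.int32), intensities, shape
    )
    return SupervoxelLabeling(
        out, centers, c_int, labeling.S, labeling.n_iter, labeling.converged
    )


def render_channel(volume: Volume, labeling: SupervoxelLabeling) -> Volume:
    """Replace each voxel by its supervoxel's mean intensity, scaled to [0,1]."""
    if volume.shape != labeling.labels.shape:
        raise ValueError("labeling grid does not match volume grid")
    flat = labeling.labels.ravel()
    counts = np.bincount(flat)
    means = np.bincount(flat, weights=volume.data.ravel()) / counts
    rendered = means[labeling.labels]
    lo, hi = rendered.min(), rendered.max()
    if hi - lo <= 0:
        return volume.with_data(np.zeros_like(rendered))
    return volume.with_data((rendered - lo) / (hi - lo))


def build_random_guidance(
    volume: Volume, params: SlicParams, M: int = 3
) -> GuidanceImage:
    """M guidance channels from independently seed-perturbed clusterings."""
    if M < 1:
        raise ValueError("M must be >= 1")
    channels = []
    for i in range(M):
        labeling = slic_cluster(volume, replace(params, rng_seed=params.rng_seed + i))
        channels.append(render_channel(volume, labeling))
    return GuidanceImage.from_volumes(channels)


def build_multiscale_guidance(
    volume: Volume, params: SlicParams, K_ladder: list[int]
) -> GuidanceImage:
    """One unperturbed-clustering channel per cluster count on the ladder."""
    if not K_ladder:
        raise ValueError("K_ladder must be non-empty")
    diffs = np.diff(K_ladder)
    if len(K_ladder) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("K_ladder must be strictly monotone")
    channels = []
    for K in K_ladder:
        labeling = slic_cluster(volume, replace(params, K=int(K), sigma_z=0.0))
        channels.append(render_channel(volume, labeling))
    return GuidanceImage.from_volumes(channels)
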
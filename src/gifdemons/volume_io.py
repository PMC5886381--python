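"""Volume and landmark I/O plus basic preprocessing.

Scalar volumes are held in ``Volume`` objects with ``data`` indexed as
``data[x, y, z]`` (0-based voxel indices).  The physical position of voxel
``(i, j, k)`` is ``origin + index * spacing`` (mm).  NIfTI-1 (``.nii``,
``.nii.gz``) and MetaImage (``.mha``, ``.mhd``) files are read and written
through SimpleITK; only axis-aligned volumes (identity direction cosines)
are accepted.

Landmark files are plain text, one point per line, whitespace- or
comma-delimited ``x y z`` in physical mm, optionally followed by a free-text
label; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_field_file",
    "write_field_file",
    "read_landmarks",
    "write_landmarks",
    "resample_isotropic",
    "normalize_intensity",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class Volume:
    """A 3-D scalar image with voxel spacing and physical origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume data must be 3-D, got {self.data.ndim}-D array"
            )
        if any(n < 2 for n in self.data.shape):
            raise ValueError(
                f"Volume must have at least 2 voxels per axis, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite (no NaN/Inf)")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must each have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume on the same grid with different intensities."""
        return Volume(data, self.spacing, self.origin)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LandmarkSet:
    """Ordered physical-space (mm) landmark coordinates with labels."""

    points: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError("landmarks must be 3-D points")
        if not self.labels:
            self.labels = [f"L{i}" for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise ValueError("one label per landmark required")

    def __len__(self) -> int:
        return len(self.points)


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED_EXT):
        raise ValueError(
            f"unsupported volume format for {path!r}; expected one of {_SUPPORTED_EXT}"
        )


def _check_direction(img: sitk.Image, path: Path) -> None:
    direction = np.asarray(img.GetDirection(), dtype=float)
    ident = np.eye(int(round(np.sqrt(direction.size)))).ravel()
    if not np.allclose(direction, ident, atol=1e-6):
        raise ValueError(
            f"{path}: non-identity direction cosines are not supported; "
            "resample the volume to an axis-aligned grid first"
        )


def read_volume(path: str | Path) -> Volume:
    """Read a scalar 3-D volume from a NIfTI or MetaImage file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_extension(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - depends on broken files
        raise ValueError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got {img.GetDimension()}-D content"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(
            f"{path}: expected a scalar volume; use read_field_file for vector data"
        )
    _check_direction(img, path)
    # SimpleITK arrays come back (z, y, x); transpose to our (x, y, z).
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite intensities")
    return Volume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume losslessly (float64) to NIfTI or MetaImage."""
    path = Path(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.data.transpose(2, 1, 0))
    )
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_field_file(path: str | Path):
    """Read a 3-component displacement field written by ``write_field_file``.

    Returns a :class:`~gifdemons.grid_ops.DisplacementField` (vectors in the
    stored units, conventionally voxels).
    """
    from .grid_ops import DisplacementField

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 3:
        raise ValueError(f"{path}: expected a 3-D, 3-component vector volume")
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    vectors = arr.transpose(2, 1, 0, 3).astype(np.float64)
    return DisplacementField(vectors, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_field_file(fieldobj, path: str | Path) -> None:
    """Persist a displacement field as a 3-component vector volume."""
    path = Path(path)
    _check_extension(path)
    arr = np.ascontiguousarray(fieldobj.vectors.transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(fieldobj.spacing)
    img.SetOrigin(fieldobj.origin)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Parse a plain-text landmark file (physical mm coordinates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    points: list[list[float]] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 3 coordinates, got {line!r}"
                )
            try:
                xyz = [float(t) for t in tokens[:3]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                ) from exc
            points.append(xyz)
            labels.append(" ".join(tokens[3:]) or f"L{len(points) - 1}")
    return LandmarkSet(np.asarray(points, dtype=np.float64).reshape(-1, 3), labels)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# x_mm y_mm z_mm label\n")
        for (x, y, z), label in zip(landmarks.points, landmarks.labels):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {label}\n")


def resample_isotropic(volume: Volume, target_spacing: float) -> Volume:
    """Trilinearly resample a volume to isotropic spacing.

    Output dimensions follow ``round(dim * spacing / target)`` per axis
    (minimum 2), which keeps the physical extent within one voxel of the
    input.  Resampling a volume already at the target spacing is the
    identity up to interpolation round-off.
    """
    from scipy.ndimage import map_coordinates

    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    old_shape = volume.shape
    new_shape = tuple(
        max(2, int(round(n * s / target_spacing)))
        for n, s in zip(old_shape, volume.spacing)
    )
    # Voxel-index scale factors between the output and input grids.
    scale = [s_old / target_spacing for s_old in volume.spacing]
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) for n in new_shape], indexing="ij"
    )
    coords = [g / s for g, s in zip(grids, scale)]
    data = map_coordinates(volume.data, coords, order=1, mode="nearest")
    return Volume(data, (target_spacing,) * 3, volume.origin)


def normalize_intensity(volume: Volume, low: float = 0.0, high: float = 100.0) -> Volume:
    """Clip to the [P_low, P_high] percentile range and rescale to [0, 1]."""
    if not (0 <= low < high <= 100):
        raise ValueError("need 0 <= low < high <= 100")
    lo = float(np.percentile(volume.data, low))
    hi = float(np.percentile(volume.data, high))
    if hi - lo <= 0:
        warnings.warn(
            "normalize_intensity: degenerate intensity range, returning zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        return volume.with_data(np.zeros_like(volume.data))
    clipped = np.clip(volume.data, lo, hi)
    return volume.with_data((clipped - lo) / (hi - lo))
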
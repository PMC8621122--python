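"""Scalar volumes, label maps and dynamic sequences with world geometry.

A :class:`Volume` is a 3-D scalar grid (CT-like intensities) together with
its world geometry: spacing (mm/voxel), origin (world position of the centre
of voxel ``(0,0,0)``) and a 3x3 orthonormal direction matrix whose columns
are the world directions of the grid axes.  The world position of voxel
index ``n`` is ``origin + direction @ (spacing * n)``.

Arrays are indexed ``[i, j, k]`` with axis 0 corresponding to the first
world axis (x by convention); all indices are 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "LabelMap",
    "DynamicSequence",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
]

_SUPPORTED_EXTENSIONS = (".mha", ".mhd", ".nii", ".nii.gz")

_ORTHO_TOL = 1e-6


def _check_geometry(spacing: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> None:
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    if origin.shape != (3,) or not np.all(np.isfinite(origin)):
        raise ValueError(f"origin must be 3 finite values, got {origin}")
    if direction.shape != (3, 3):
        raise ValueError("direction must be a 3x3 matrix")
    if not np.allclose(direction.T @ direction, np.eye(3), atol=_ORTHO_TOL):
        raise ValueError("direction matrix is not orthonormal within 1e-6")


@dataclass
class Volume:
    """3-D scalar image with world geometry (mm)."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        _check_geometry(self.spacing, self.origin, self.direction)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_from_index(self, index) -> np.ndarray:
        """World position (mm) of a (possibly fractional) voxel index."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def index_from_world(self, point) -> np.ndarray:
        """Continuous voxel index of a world position (mm)."""
        point = np.asarray(point, dtype=float)
        return ((point - self.origin) @ self.direction) / self.spacing

    def same_grid(self, other: "Volume | LabelMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(self.voxels, (2, 1, 0))))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return cls(
            voxels=arr,
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """New Volume with the same grid geometry but different values."""
        return Volume(voxels=voxels, spacing=self.spacing.copy(),
                      origin=self.origin.copy(), direction=self.direction.copy())


@dataclass
class LabelMap:
    """Integer label volume on a :class:`Volume` grid; 0 is background."""

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValueError("labels must be integer-valued")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        _check_geometry(self.spacing, self.origin, self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    world_from_index = Volume.world_from_index
    index_from_world = Volume.index_from_world
    same_grid = Volume.same_grid

    @property
    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v != 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def to_sitk(self) -> sitk.Image:
        arr = np.ascontiguousarray(np.transpose(self.labels.astype(np.int32), (2, 1, 0)))
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, label_names: dict[int, str] | None = None) -> "LabelMap":
        arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return cls(
            labels=np.round(arr).astype(np.int32),
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
            label_names=dict(label_names or {}),
        )

    def with_labels(self, labels: np.ndarray) -> "LabelMap":
        return LabelMap(labels=labels, spacing=self.spacing.copy(),
                        origin=self.origin.copy(), direction=self.direction.copy(),
                        label_names=dict(self.label_names))

    def as_volume(self) -> Volume:
        return Volume(voxels=self.labels.astype(float), spacing=self.spacing.copy(),
                      origin=self.origin.copy(), direction=self.direction.copy())


@dataclass
class DynamicSequence:
    """Ordered series of 3-D frames sharing one grid, with a reference frame."""

    frames: list[Volume]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("sequence must contain at least one frame")
        if not 0 <= self.reference_index < len(self.frames):
            raise ValueError(
                f"reference_index {self.reference_index} out of range for "
                f"{len(self.frames)} frames"
            )
        ref = self.frames[0]
        for i, f in enumerate(self.frames[1:], start=1):
            if not ref.same_grid(f):
                raise ValueError(f"frame {i} grid geometry differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def reference(self) -> Volume:
        return self.frames[self.reference_index]


# -- file I/O -------------------------------------------------------------

def _check_extension(path: str) -> None:
    if not str(path).endswith(_SUPPORTED_EXTENSIONS):
        raise ValueError(
            f"unsupported volume format for '{path}'; expected one of "
            f"{_SUPPORTED_EXTENSIONS}"
        )


def read_volume(path: str) -> Volume:
    """Read a 3-D volume (MetaImage or NIfTI) with its world geometry."""
    _check_extension(path)
    if not os.path.exists(path):
        raise IOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - message varies by ITK
        raise IOError(f"could not read volume '{path}': {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3-D volume in '{path}', got {img.GetDimension()}-D")
    return Volume.from_sitk(img)


def write_volume(volume: Volume | LabelMap, path: str) -> None:
    """Write a volume or label map losslessly (labels stay integer)."""
    _check_extension(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    try:
        sitk.WriteImage(volume.to_sitk(), str(path))
    except RuntimeError as exc:  # pragma: no cover
        raise IOError(f"could not write volume '{path}': {exc}") from exc


def read_labelmap(path: str, label_names: dict[int, str] | None = None) -> LabelMap:
    """Read an integer label volume."""
    _check_extension(path)
    if not os.path.exists(path):
        raise IOError(f"label file not found: {path}")
    img = sitk.ReadImage(str(path))
    return LabelMap.from_sitk(img, label_names=label_names)


def write_labelmap(labels: LabelMap, path: str) -> None:
    write_volume(labels, path)
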
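"""Grid-level utilities: resampling, mask dilation, bilateral splitting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .transforms import SpatialTransform
from .volume import LabelMap, Volume

__all__ = [
    "resample_volume",
    "resample_labels",
    "dilate_mask",
    "ball_structuring_element",
    "split_bilateral",
    "BilateralSplit",
]


def resample_volume(volume: Volume, transform: SpatialTransform, target_grid: Volume,
                    default_value: float = 0.0) -> Volume:
    """Linearly resample ``volume`` onto ``target_grid``.

    ``transform`` maps target-grid world points into the source volume's
    space (the resampling convention); out-of-domain voxels get
    ``default_value``.
    """
    out = sitk.Resample(
        volume.to_sitk(),
        target_grid.to_sitk(),
        transform.sitk,
        sitk.sitkLinear,
        float(default_value),
        sitk.sitkFloat64,
    )
    return Volume.from_sitk(out)


def resample_labels(labels: LabelMap, transform: SpatialTransform,
                    target_grid: Volume | LabelMap) -> LabelMap:
    """Nearest-neighbour resample of a label map onto ``target_grid``.

    Out-of-domain voxels become background (0); no new labels are invented.
    """
    ref = target_grid.as_volume() if isinstance(target_grid, LabelMap) else target_grid
    out = sitk.Resample(
        labels.to_sitk(),
        ref.to_sitk(),
        transform.sitk,
        sitk.sitkNearestNeighbor,
        0.0,
        sitk.sitkInt32,
    )
    return LabelMap.from_sitk(out, label_names=labels.label_names)


def ball_structuring_element(radius: int) -> np.ndarray:
    """Euclidean ball of the given voxel radius: lattice points with
    ``x^2 + y^2 + z^2 <= radius^2``."""
    r = int(radius)
    grid = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (grid ** 2).sum(axis=0) <= r * r


def dilate_mask(mask: LabelMap, radius_voxels: int) -> LabelMap:
    """Morphological dilation of the foreground with a Euclidean ball.

    The radius is in voxels (isotropic in index space); the result is
    clipped at the image bounds.  Radius 0 is the identity.
    """
    if radius_voxels < 0:
        raise ValueError(f"dilation radius must be >= 0, got {radius_voxels}")
    fg = mask.labels > 0
    if radius_voxels == 0:
        dilated = fg
    else:
        dilated = ndimage.binary_dilation(fg, structure=ball_structuring_element(radius_voxels))
    return mask.with_labels(dilated.astype(np.int32))


@dataclass
class BilateralSplit:
    left: Volume
    right: Volume
    split_index: int          # first index along the split axis in the right half
    degenerate: bool          # True when the profile had no two clear maxima


def _crop(volume: Volume, axis: int, start: int, stop: int) -> Volume:
    """Crop along one grid axis, keeping world coordinates of kept voxels."""
    slicer = [slice(None)] * 3
    slicer[axis] = slice(start, stop)
    offset = np.zeros(3)
    offset[axis] = start
    origin = volume.world_from_index(offset)
    return Volume(voxels=volume.voxels[tuple(slicer)].copy(), spacing=volume.spacing.copy(),
                  origin=origin, direction=volume.direction.copy())


def split_bilateral(volume: Volume, axis: int = 0, smooth_sigma: float = 2.0) -> BilateralSplit:
    """Split a bilateral acquisition (e.g. both knees in the gantry) in two.

    The intensity sum over the two non-split axes gives a 1-D profile along
    the left-right axis; the split plane is the minimum of that profile
    between its two dominant maxima.  A unimodal profile (single object)
    degenerates to a midpoint split, flagged on the result.
    """
    from scipy.signal import find_peaks

    other = tuple(a for a in range(3) if a != axis)
    profile = volume.voxels.sum(axis=other).astype(float)
    smoothed = ndimage.gaussian_filter1d(profile, smooth_sigma) if smooth_sigma > 0 else profile

    n = smoothed.size
    span = smoothed.max() - smoothed.min()
    peaks, props = find_peaks(smoothed, prominence=0.05 * max(span, 1e-12))
    degenerate = len(peaks) < 2
    if not degenerate:
        top2 = peaks[np.argsort(props["prominences"])][-2:]
        lo, hi = int(top2.min()), int(top2.max())
        degenerate = hi - lo < 2

    if degenerate:
        warnings.warn("bilateral split: profile is unimodal, splitting at midpoint",
                      stacklevel=2)
        split = n // 2
    else:
        valley = smoothed[lo:hi + 1]
        at_min = np.flatnonzero(valley <= valley.min() + 1e-6 * max(span, 1e-12))
        # centre of a flat valley, upper-middle on even plateaus
        split = lo + int(at_min[0] + at_min[-1] + 1) // 2

    return BilateralSplit(
        left=_crop(volume, axis, 0, split),
        right=_crop(volume, axis, split, n),
        split_index=split,
        degenerate=degenerate,
    )
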
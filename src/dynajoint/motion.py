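"""Per-bone rigid motion tracking through a dynamic sequence.

Each bone of the reference segmentation is dilated (default 3 voxels) to
include its immediate vicinity and tracked by masked rigid registration
with the MSD metric: fixed image = reference frame, moving image = frame t,
so the resulting transform T_bone,t maps reference-space points into
frame-t space and propagates landmarks directly.  The walk starts at the
reference frame and proceeds outward in both temporal directions, each
registration warm-started from the neighbouring frame's solution; a frame
that fails to register keeps the previous transform and is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gridops import dilate_mask
from .landmarks import LandmarkSet
from .registration import RegistrationError, register_rigid_masked
from .transforms import SpatialTransform
from .volume import DynamicSequence, LabelMap

__all__ = ["RigidMotionSeries", "TrackingEntry", "track_bones",
           "TREResult", "compute_tre"]

logger = logging.getLogger(__name__)


@dataclass
class TrackingEntry:
    final_metric: float = np.nan
    fallback: bool = False


@dataclass
class RigidMotionSeries:
    """Per-bone, per-frame rigid transforms T_bone,t (reference -> frame t)."""

    transforms: dict[int, list[SpatialTransform]]
    metadata: dict[int, list[TrackingEntry]]
    reference_index: int

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.transforms.values()}
        if len(lengths) > 1:
            raise ValueError("all bones must have the same number of frames")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.transforms.values())))

    @property
    def bone_labels(self) -> list[int]:
        return sorted(self.transforms)

    def fallback_flags(self) -> np.ndarray:
        """Per-frame flag: True when any bone fell back at that frame."""
        flags = np.zeros(self.n_frames, dtype=bool)
        for entries in self.metadata.values():
            flags |= np.array([e.fallback for e in entries])
        return flags

    def convergence_table(self) -> pd.DataFrame:
        rows = []
        for lab in self.bone_labels:
            for t, e in enumerate(self.metadata[lab]):
                rows.append({"bone": lab, "frame": t,
                             "final_metric": e.final_metric, "fallback": e.fallback})
        return pd.DataFrame(rows)

    @classmethod
    def identity(cls, bone_labels, n_frames: int, reference_index: int = 0
                 ) -> "RigidMotionSeries":
        return cls(
            transforms={b: [SpatialTransform.identity() for _ in range(n_frames)]
                        for b in bone_labels},
            metadata={b: [TrackingEntry(0.0, False) for _ in range(n_frames)]
                      for b in bone_labels},
            reference_index=reference_index,
        )

    @classmethod
    def from_ground_truth(cls, series: dict[int, list[SpatialTransform]],
                          reference_index: int = 0) -> "RigidMotionSeries":
        return cls(
            transforms=series,
            metadata={b: [TrackingEntry(0.0, False) for _ in v]
                      for b, v in series.items()},
            reference_index=reference_index,
        )


def _frame_order(n: int, reference: int) -> list[int]:
    """Reference first, then outward in both temporal directions."""
    forward = list(range(reference + 1, n))
    backward = list(range(reference - 1, -1, -1))
    return forward + backward


def track_bones(sequence: DynamicSequence, reference_labels: LabelMap,
                dilation_radius: int = 3, seed: int = 0, *,
                max_iterations: int = 1500, n_samples: int | None = None,
                n_resolution_levels: int = 2) -> RigidMotionSeries:
    """Track every labelled bone rigidly through the sequence.

    ``reference_labels`` must live on the grid of the reference frame.  The
    entry at the reference index is the exact identity.  A per-frame
    registration failure falls back to the neighbouring frame's transform
    with the entry flagged; a bone whose every frame fails raises.
    """
    reference = sequence.reference
    if not reference.same_grid(reference_labels):
        raise ValueError("reference labels are not on the reference frame's grid")
    bone_labels = reference_labels.present_labels
    if not bone_labels:
        raise ValueError("reference segmentation contains no bones")

    n = len(sequence)
    ref_idx = sequence.reference_index
    transforms: dict[int, list[SpatialTransform]] = {}
    metadata: dict[int, list[TrackingEntry]] = {}
    for bone in bone_labels:
        mask = dilate_mask(
            reference_labels.with_labels((reference_labels.labels == bone
                                          ).astype(np.int32)),
            dilation_radius)
        t_list: list[SpatialTransform | None] = [None] * n
        e_list = [TrackingEntry() for _ in range(n)]
        t_list[ref_idx] = SpatialTransform.identity()
        e_list[ref_idx] = TrackingEntry(0.0, False)
        n_failed = 0
        for t in _frame_order(n, ref_idx):
            prev = t - 1 if t > ref_idx else t + 1
            init = t_list[prev]
            try:
                result = register_rigid_masked(
                    reference, sequence.frames[t], mask, init=init,
                    seed=seed + 10007 * bone + t, max_iterations=max_iterations,
                    n_samples=n_samples, n_resolution_levels=n_resolution_levels)
                t_list[t] = result
                e_list[t] = TrackingEntry(
                    getattr(result, "final_metric_value", np.nan), False)
            except RegistrationError as exc:
                logger.warning("bone %d frame %d: registration failed (%s); "
                               "keeping previous transform", bone, t, exc)
                t_list[t] = init
                e_list[t] = TrackingEntry(np.nan, True)
                n_failed += 1
        if n_failed == n - 1:
            raise RegistrationError(f"tracking failed at every frame for bone {bone}")
        transforms[bone] = t_list            # type: ignore[assignment]
        metadata[bone] = e_list
    return RigidMotionSeries(transforms=transforms, metadata=metadata,
                             reference_index=ref_idx)


@dataclass
class TREResult:
    """Target registration error: per-landmark distances in mm."""

    names: list[str]
    distances: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def max(self) -> float:
        return float(np.max(self.distances))

    @property
    def median(self) -> float:
        return float(np.median(self.distances))


def compute_tre(reference_points: LandmarkSet, frame_points: LandmarkSet,
                transform: SpatialTransform) -> TREResult:
    """TRE between ``transform``-mapped reference landmarks and their
    observed positions in a frame, matched by name."""
    names = [n for n in reference_points.names if n in frame_points]
    if not names:
        raise ValueError("no landmark pairs shared by name")
    dists = np.array([
        np.linalg.norm(transform.apply_point(reference_points[n].position)
                       - frame_points[n].position)
        for n in names
    ])
    return TREResult(names=names, distances=dists)
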
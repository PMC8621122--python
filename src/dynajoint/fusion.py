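"""Multi-atlas, multi-label segmentation: registration, propagation, fusion.

Every atlas is registered to the target image (rigid -> affine -> B-spline),
its labels propagated onto the target grid, and the candidate labelmaps
fused per voxel:

* MV   — plain majority vote over all atlases;
* GNCC — majority vote over the ``r`` atlases whose registered intensities
  correlate best with the target globally;
* LNCC — per voxel, majority vote over the ``r`` atlases with the highest
  *local* correlation at that voxel (Gaussian window of σ = ``k`` voxels),
  which lets well-registered atlases dominate exactly where they are good.

Votes are counted jointly over the whole label alphabet (background
included), so the fused result is always a partition; ties go to the
smallest label value.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .gridops import resample_labels, resample_volume
from .landmarks import read_landmarks
from .phantom import Atlas
from .registration import (RegistrationConfig, RegistrationError,
                           register_pairwise)
from .transforms import SpatialTransform
from .volume import LabelMap, Volume, read_labelmap, read_volume

__all__ = [
    "Atlas",
    "FusionConfig",
    "CandidateStack",
    "build_candidates",
    "rank_atlases_global",
    "lncc_weight_maps",
    "fuse_labels",
    "segment_multi_atlas",
    "load_atlas_dir",
]

logger = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    method: str = "LNCC"          # MV | GNCC | LNCC
    k: int = 5                    # LNCC kernel size (voxels)
    r: int = 3                    # number of highest-ranked atlases (GNCC/LNCC)
    kernel: str = "gaussian"      # gaussian (sigma = k) | boxcar (edge 2k+1)
    air_threshold: float = 150.0  # intensity above which a voxel counts as foreground

    def __post_init__(self) -> None:
        if self.method not in ("MV", "GNCC", "LNCC"):
            raise ValueError(f"unknown fusion method '{self.method}'")
        if self.k < 1:
            raise ValueError("kernel size k must be >= 1")
        if self.r < 1:
            raise ValueError("atlas count r must be >= 1")
        if self.kernel not in ("gaussian", "boxcar"):
            raise ValueError("kernel must be 'gaussian' or 'boxcar'")


@dataclass
class CandidateStack:
    """Per-atlas propagated labels and registered intensities on the target grid."""

    labels: list[LabelMap]
    images: list[Volume]
    atlas_ids: list[str]
    transforms: list[SpatialTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.images) == len(self.atlas_ids)):
            raise ValueError("labels, images and atlas ids must align")
        if not self.labels:
            raise ValueError("candidate stack is empty")
        ref = self.images[0]
        for i, (lab, img) in enumerate(zip(self.labels, self.images)):
            if not ref.same_grid(img) or not ref.same_grid(lab):
                raise ValueError(f"stack entry {i} is not on the common grid")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def label_alphabet(self) -> np.ndarray:
        values = np.unique(np.stack([lm.labels for lm in self.labels]))
        return values.astype(np.int32)


def build_candidates(target: Volume, atlases: list[Atlas],
                     reg_config: RegistrationConfig | None = None,
                     target_id: str | None = None) -> CandidateStack:
    """Register every atlas to the target and propagate its labels.

    Atlas intensities are resampled linearly and labels nearest-neighbour
    with the same transform.  An atlas whose registration fails is dropped
    with a warning; an atlas whose id equals ``target_id`` is excluded up
    front (cross-validation discipline).  All atlases failing is an error.
    """
    if reg_config is None:
        reg_config = RegistrationConfig()
    atlases = [a for a in atlases if target_id is None or a.id != target_id]
    if not atlases:
        raise ValueError("no atlases to register (after excluding the target)")
    labels, images, ids, transforms = [], [], [], []
    for atlas in atlases:
        try:
            t = register_pairwise(target, atlas.image, reg_config)
        except RegistrationError as exc:
            logger.warning("atlas '%s' dropped: registration failed (%s)", atlas.id, exc)
            continue
        images.append(resample_volume(atlas.image, t, target))
        labels.append(resample_labels(atlas.labels, t, target))
        ids.append(atlas.id)
        transforms.append(t)
    if not labels:
        raise RegistrationError("all atlas registrations failed")
    return CandidateStack(labels=labels, images=images, atlas_ids=ids,
                          transforms=transforms)


def _foreground_bbox(target: Volume, air_threshold: float) -> tuple[slice, slice, slice]:
    fg = target.voxels > air_threshold
    if not fg.any():
        return (slice(None),) * 3
    idx = np.argwhere(fg)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def rank_atlases_global(stack: CandidateStack, target: Volume,
                        air_threshold: float = 150.0) -> list[int]:
    """Atlas indices sorted by descending global NCC with the target.

    Correlation is computed over the target's foreground bounding box to
    avoid inflation by empty background; ties break by stack order.
    """
    box = _foreground_bbox(target, air_threshold)
    t = target.voxels[box].astype(float).ravel()
    t = t - t.mean()
    tn = np.linalg.norm(t)
    scores = []
    for img in stack.images:
        a = img.voxels[box].astype(float).ravel()
        a = a - a.mean()
        denom = tn * np.linalg.norm(a)
        scores.append(float(t @ a / denom) if denom > 0 else 0.0)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return order


def _local_stats(arr: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    # normalized convolution: averages stay unbiased at the image border
    # and converge to plain whole-domain means as the kernel outgrows the image
    if cfg.kernel == "gaussian":
        smooth = ndimage.gaussian_filter(arr, sigma=cfg.k, mode="constant")
        norm = ndimage.gaussian_filter(np.ones_like(arr), sigma=cfg.k,
                                       mode="constant")
    else:
        size = 2 * cfg.k + 1
        smooth = ndimage.uniform_filter(arr, size=size, mode="constant")
        norm = ndimage.uniform_filter(np.ones_like(arr), size=size,
                                      mode="constant")
    return smooth / norm


def lncc_weight_maps(stack: CandidateStack, target: Volume,
                     config: FusionConfig | None = None) -> list[Volume]:
    """Voxelwise local NCC between each candidate intensity and the target.

    Local means, variances and covariance come from smoothing with the
    configured kernel; values are clipped to [-1, 1] and defined as 0
    where either local variance vanishes.
    """
    if config is None:
        config = FusionConfig()
    t = target.voxels.astype(float)
    mt = _local_stats(t, config)
    vt = _local_stats(t * t, config) - mt * mt
    out = []
    for img in stack.images:
        a = img.voxels.astype(float)
        ma = _local_stats(a, config)
        va = _local_stats(a * a, config) - ma * ma
        cov = _local_stats(t * a, config) - mt * ma
        denom = np.sqrt(np.clip(vt, 0, None) * np.clip(va, 0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            lncc = np.where(denom > 1e-12, cov / np.maximum(denom, 1e-300), 0.0)
        out.append(target.with_voxels(np.clip(lncc, -1.0, 1.0)))
    return out


def _vote(label_stack: np.ndarray, alphabet: np.ndarray) -> np.ndarray:
    """Joint majority vote; ties go to the smallest label in ``alphabet``.

    ``label_stack`` is (n_atlas, *vol) or a masked variant where excluded
    votes are -1.
    """
    counts = np.stack([(label_stack == v).sum(axis=0) for v in alphabet])
    winner = np.argmax(counts, axis=0)      # first max -> smallest label
    return alphabet[winner]


def fuse_labels(stack: CandidateStack, target: Volume,
                config: FusionConfig | None = None) -> LabelMap:
    """Fuse candidate labelmaps into one segmentation (see module docs)."""
    if config is None:
        config = FusionConfig()
    n = len(stack)
    if config.method in ("GNCC", "LNCC") and config.r > n:
        raise ValueError(f"r={config.r} exceeds stack size {n}")
    alphabet = stack.label_alphabet
    label_stack = np.stack([lm.labels for lm in stack.labels])

    if config.method == "MV":
        fused = _vote(label_stack, alphabet)
    elif config.method == "GNCC":
        order = rank_atlases_global(stack, target, config.air_threshold)
        chosen = order[: config.r]
        fused = _vote(label_stack[chosen], alphabet)
    else:
        weights = np.stack([w.voxels for w in
                            lncc_weight_maps(stack, target, config)])
        # per voxel: rank atlases by descending weight, stable in stack order
        order = np.argsort(-weights, axis=0, kind="stable")
        selected = order[: config.r]                       # (r, *vol)
        votes = np.take_along_axis(label_stack, selected, axis=0)
        fused = _vote(votes, alphabet)

    names = {}
    for lm in stack.labels:
        names.update(lm.label_names)
    return LabelMap(labels=fused.astype(np.int32), spacing=target.spacing.copy(),
                    origin=target.origin.copy(), direction=target.direction.copy(),
                    label_names=names)


def segment_multi_atlas(target: Volume, atlases: list[Atlas],
                        reg_config: RegistrationConfig | None = None,
                        fusion_config: FusionConfig | None = None,
                        target_id: str | None = None,
                        ) -> tuple[LabelMap, CandidateStack]:
    """End-to-end multi-atlas segmentation of a target image.

    Returns the fused segmentation and the candidate stack (which carries
    the per-atlas transforms needed for landmark propagation).
    """
    stack = build_candidates(target, atlases, reg_config, target_id=target_id)
    fused = fuse_labels(stack, target, fusion_config)
    return fused, stack


def load_atlas_dir(root: str) -> list[Atlas]:
    """Load atlases from ``<root>/<id>/{image,labels}.(mha|mhd|nii|nii.gz)``
    plus ``landmarks.csv`` (optional)."""
    from .landmarks import LandmarkSet

    def find(d: str, stem: str) -> str | None:
        for ext in (".mha", ".mhd", ".nii.gz", ".nii"):
            p = os.path.join(d, stem + ext)
            if os.path.exists(p):
                return p
        return None

    atlases = []
    for entry in sorted(os.listdir(root)):
        d = os.path.join(root, entry)
        if not os.path.isdir(d):
            continue
        image_path, labels_path = find(d, "image"), find(d, "labels")
        if image_path is None or labels_path is None:
            logger.warning("skipping '%s': missing image or labels volume", d)
            continue
        lm_path = os.path.join(d, "landmarks.csv")
        landmarks = read_landmarks(lm_path) if os.path.exists(lm_path) else LandmarkSet([])
        atlases.append(Atlas(image=read_volume(image_path),
                             labels=read_labelmap(labels_path),
                             landmarks=landmarks, id=entry))
    if not atlases:
        raise ValueError(f"no atlases found under '{root}'")
    return atlases
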
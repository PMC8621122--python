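"""Synthetic joint phantoms with exact ground truth.

A phantom emulates a CT of a joint: 2-3 rigid, high-intensity "bones"
(ellipsoids or capsules) with a bright cortical shell around a lower-density
core, on a soft-tissue background, plus additive Gaussian noise.  From one
base phantom the module derives

* atlas populations — the base anatomy warped by random smooth invertible
  B-spline deformations, emulating inter-subject shape variation, with
  labels and landmarks warped consistently, and
* dynamic sequences — per-frame rigid motion of each bone with the exact
  per-frame transforms and landmark positions returned as ground truth.

Default intensities are CT-like but arbitrary: background 50, trabecular
core 300, cortical shell 1200, noise SD 20.  The default grid is 64 voxels
cubed at 1 mm isotropic spacing and dynamic sequences default to 15 frames,
the typical length of a cine CT acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .landmarks import Landmark, LandmarkSet
from .transforms import SpatialTransform
from .volume import DynamicSequence, LabelMap, Volume

__all__ = [
    "BoneSpec",
    "PhantomSpec",
    "MotionSpec",
    "BoneMotion",
    "Atlas",
    "generate_joint_phantom",
    "generate_atlas_population",
    "generate_dynamic_sequence",
    "default_two_bone_spec",
    "default_two_bone_motion",
]

BACKGROUND_INTENSITY = 50.0
CORE_INTENSITY = 300.0
SHELL_INTENSITY = 1200.0
NOISE_SD = 20.0


@dataclass
class Atlas:
    """Annotated dataset: image + bone labels + anatomical landmarks.

    ``clean_image`` optionally carries the noise-free rendering of the same
    anatomy; generators that animate the atlas use it as the source so
    acquisition noise enters each synthetic frame exactly once.
    """

    image: Volume
    labels: LabelMap
    landmarks: LandmarkSet
    id: str = ""
    clean_image: Volume | None = None

    def __post_init__(self) -> None:
        if not self.image.same_grid(self.labels):
            raise ValueError(f"atlas '{self.id}': image and labels grids differ")
        present = set(self.labels.present_labels)
        for lm in self.landmarks:
            if lm.bone_label not in present:
                raise ValueError(
                    f"atlas '{self.id}': landmark '{lm.name}' refers to absent "
                    f"label {lm.bone_label}")


@dataclass
class BoneSpec:
    """One rigid bone: ellipsoid or capsule with a cortical shell.

    ``semi_axes`` are the outer ellipsoid semi-axes in mm; for a capsule
    they are (radius, radius, half_length) with the long axis along local z.
    ``orientation`` rotates the local frame into world axes.  ``lobes`` are
    additional ellipsoids (offset, semi-axes in the bone's local frame)
    unioned into the bone — epiphyses are lobed, not smooth, and the
    asymmetry is what makes rotations observable to an intensity metric.
    Landmarks are named extremal surface points: for each ``(name,
    direction)`` the point of the bone surface farthest along that world
    direction.
    """

    label: int
    shape: str = "ellipsoid"                 # ellipsoid | capsule
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)   # world mm
    semi_axes: tuple[float, float, float] = (10.0, 10.0, 15.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    cortical_shell_thickness: float = 2.0    # mm
    core_intensity: float = CORE_INTENSITY
    shell_intensity: float = SHELL_INTENSITY
    landmark_recipe: list[tuple[str, tuple[float, float, float]]] = field(default_factory=list)
    lobes: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = \
        field(default_factory=list)          # (local offset mm, semi-axes mm)

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "capsule"):
            raise ValueError(f"unknown bone shape '{self.shape}'")
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.shell_intensity <= self.core_intensity:
            raise ValueError("shell intensity must exceed core intensity")

    # -- geometry (all in world mm) --------------------------------------
    def _local(self, points: np.ndarray) -> np.ndarray:
        return (self.orientation.T @ (points - np.asarray(self.center)).T).T

    def contains(self, points: np.ndarray, shrink_mm: float = 0.0) -> np.ndarray:
        """Membership test; ``shrink_mm`` > 0 tests the core region."""
        points = np.atleast_2d(points)
        local = self._local(points)
        if self.shape == "ellipsoid":
            axes = np.maximum(np.asarray(self.semi_axes) - shrink_mm, 1e-3)
            inside = np.sum((local / axes) ** 2, axis=1) <= 1.0
        else:
            radius = max(self.semi_axes[0] - shrink_mm, 1e-3)
            half = max(self.semi_axes[2] - self.semi_axes[0], 0.0)
            z = np.clip(local[:, 2], -half, half)
            seg = local - np.column_stack([np.zeros((len(local), 2)), z])
            inside = np.linalg.norm(seg, axis=1) <= radius
        for offset, semi in self.lobes:
            axes = np.maximum(np.asarray(semi, dtype=float) - shrink_mm, 1e-3)
            rel = local - np.asarray(offset, dtype=float)
            inside |= np.sum((rel / axes) ** 2, axis=1) <= 1.0
        return inside

    def extremal_point(self, direction: np.ndarray) -> np.ndarray:
        """Surface point of the bone (lobes included) farthest along a
        world direction (exact support-point computation)."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        q = self.orientation
        candidates = []
        if self.shape == "ellipsoid":
            # support point of {x : x^T A^-1 x <= 1} in direction d is
            # A d / sqrt(d^T A d) with A = Q diag(a^2) Q^T
            a = q @ np.diag(np.asarray(self.semi_axes) ** 2) @ q.T
            candidates.append(np.asarray(self.center) + (a @ d) / np.sqrt(d @ a @ d))
        else:
            radius = self.semi_axes[0]
            half = max(self.semi_axes[2] - radius, 0.0)
            ends = [np.asarray(self.center) + q @ np.array([0, 0, s * half])
                    for s in (-1.0, 1.0)]
            best = max(ends, key=lambda e: float(d @ e))
            candidates.append(best + radius * d)
        for offset, semi in self.lobes:
            a = q @ np.diag(np.asarray(semi, dtype=float) ** 2) @ q.T
            c = np.asarray(self.center) + q @ np.asarray(offset, dtype=float)
            candidates.append(c + (a @ d) / np.sqrt(d @ a @ d))
        return max(candidates, key=lambda p: float(d @ p))


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bones: list[BoneSpec] = field(default_factory=list)
    background_intensity: float = BACKGROUND_INTENSITY
    noise_sd: float = NOISE_SD

    def __post_init__(self) -> None:
        labels = [b.label for b in self.bones]
        if len(set(labels)) != len(labels):
            raise ValueError("bone labels must be unique")


@dataclass
class BoneMotion:
    """Rigid motion profile of one bone: linear ramps of rotation (about a
    fixed axis through a pivot) and translation, frame 0 = identity."""

    label: int
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_per_frame_deg: float = 0.0
    translation_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pivot: tuple[float, float, float] | None = None   # default: bone center

    def transform_at(self, frame: int, default_pivot) -> SpatialTransform:
        angle = np.deg2rad(self.rotation_per_frame_deg * frame)
        axis = np.asarray(self.rotation_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
        pivot = np.asarray(self.pivot if self.pivot is not None else default_pivot,
                           dtype=float)
        translation = np.asarray(self.translation_per_frame, dtype=float) * frame
        return SpatialTransform.rigid(rot, translation, center=pivot)


@dataclass
class MotionSpec:
    n_frames: int = 15
    bones: list[BoneMotion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _world_grid(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.grid_shape).reshape(3, -1).T.astype(float)
    return np.asarray(spec.origin) + idx * np.asarray(spec.spacing)


def generate_joint_phantom(spec: PhantomSpec, seed: int = 0) -> Atlas:
    """Render a phantom: intensities, bone labels and landmark set.

    Deterministic given ``(spec, seed)``.  Bones must not overlap.
    """
    if not spec.bones:
        raise ValueError("phantom spec must contain at least one bone")
    world = _world_grid(spec)
    voxels = np.full(spec.grid_shape, spec.background_intensity, dtype=float)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    names: dict[int, str] = {}
    for bone in spec.bones:
        inside = bone.contains(world).reshape(spec.grid_shape)
        core = bone.contains(world, shrink_mm=bone.cortical_shell_thickness
                             ).reshape(spec.grid_shape)
        if np.any(labels[inside] != 0):
            raise ValueError(f"bone {bone.label} overlaps another bone")
        labels[inside] = bone.label
        voxels[inside] = bone.shell_intensity
        voxels[core] = bone.core_intensity
        names[bone.label] = f"bone{bone.label}"
    geometry = dict(spacing=np.asarray(spec.spacing),
                    origin=np.asarray(spec.origin), direction=np.eye(3))
    clean = Volume(voxels=voxels.copy(), **geometry)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sd, voxels.shape)
    landmarks = [
        Landmark(name, bone.label, bone.extremal_point(np.asarray(direction)))
        for bone in spec.bones for name, direction in bone.landmark_recipe
    ]
    return Atlas(
        image=Volume(voxels=voxels, **geometry),
        labels=LabelMap(labels=labels, label_names=names, **geometry),
        landmarks=LandmarkSet(landmarks),
        id=f"phantom-{seed}",
        clean_image=clean,
    )


def _random_bspline_warp(image: Volume, deformation_sd: float, control_spacing: float,
                         rng: np.random.Generator) -> SpatialTransform:
    physical = (np.asarray(image.shape) - 1) * image.spacing
    mesh = np.maximum(2, np.round(physical / control_spacing)).astype(int)
    tx = sitk.BSplineTransformInitializer(image.to_sitk(), [int(m) for m in mesh], 3)
    coeffs = rng.normal(0.0, deformation_sd, len(tx.GetParameters()))
    tx.SetParameters(tuple(coeffs))
    return SpatialTransform("bspline", tx)


def _min_jacobian(transform: SpatialTransform, image: Volume) -> float:
    field = sitk.TransformToDisplacementField(
        transform.sitk, sitk.sitkVectorFloat64, image.shape,
        tuple(image.origin), tuple(image.spacing), tuple(image.direction.ravel()))
    jac = sitk.DisplacementFieldJacobianDeterminant(field)
    return float(sitk.GetArrayViewFromImage(jac).min())


def generate_atlas_population(base: PhantomSpec, n: int, deformation_sd: float = 3.0,
                              seed: int = 0, control_spacing: float = 16.0,
                              max_resample: int = 20) -> list[Atlas]:
    """Warp the base phantom by random smooth invertible deformations.

    Each atlas gets an independent B-spline displacement with control-point
    coefficients ~ N(0, ``deformation_sd`` mm) on a grid of
    ``control_spacing`` mm; fields with non-positive Jacobian determinant
    anywhere are rejected and redrawn.  Image (linear), labels (nearest
    neighbour) and landmarks are warped consistently; fresh noise per atlas.
    """
    if n < 2:
        raise ValueError("population needs n >= 2")
    if control_spacing < 4 * max(base.spacing):
        raise ValueError("control spacing must be >= 4x voxel spacing for smoothness")
    clean = generate_joint_phantom(replace(base, noise_sd=0.0), seed=seed)
    rng = np.random.default_rng(seed)
    atlases: list[Atlas] = []
    rejected = 0
    for i in range(n):
        for _ in range(max_resample):
            warp = _random_bspline_warp(clean.image, deformation_sd, control_spacing, rng)
            if deformation_sd == 0 or _min_jacobian(warp, clean.image) > 0.05:
                break
            rejected += 1
        else:
            raise RuntimeError("could not sample an invertible deformation")
        # warp maps warped-space points into base space (resampling convention)
        ref = clean.image.to_sitk()
        img = sitk.Resample(ref, ref, warp.sitk, sitk.sitkBSpline,
                            base.background_intensity, sitk.sitkFloat64)
        lab = sitk.Resample(clean.labels.to_sitk(), ref, warp.sitk,
                            sitk.sitkNearestNeighbor, 0.0, sitk.sitkInt32)
        clean_warped = Volume.from_sitk(img)
        voxels = clean_warped.voxels
        if base.noise_sd > 0:
            voxels = voxels + rng.normal(0.0, base.noise_sd, voxels.shape)
        image = clean.image.with_voxels(voxels)
        labels = LabelMap.from_sitk(lab, label_names=clean.labels.label_names)
        # landmark x in base space sits at warp^-1(x) in the warped atlas
        moved = []
        for lm in clean.landmarks:
            pos, ok = warp.invert_point(lm.position, tol=1e-6, max_iter=200)
            if not ok:
                raise RuntimeError(f"landmark '{lm.name}' inverse did not converge")
            moved.append(Landmark(lm.name, lm.bone_label, pos))
        atlases.append(Atlas(image=image, labels=labels,
                             landmarks=LandmarkSet(moved), id=f"atlas-{seed}-{i}",
                             clean_image=clean_warped))
    if rejected:
        import logging
        logging.getLogger(__name__).info(
            "atlas population: redrew %d non-invertible deformation(s)", rejected)
    return atlases


def generate_dynamic_sequence(
        atlas: Atlas, motion: MotionSpec, seed: int = 0,
        background_intensity: float = BACKGROUND_INTENSITY,
        noise_sd: float = NOISE_SD,
) -> tuple[DynamicSequence, dict[int, list[SpatialTransform]], list[LandmarkSet]]:
    """Animate an atlas: per-frame rigid motion of each bone.

    Frame ``t`` contains every bone's region rigidly moved by its
    ground-truth transform (reference space -> frame-t space), composited
    over the background in descending label order, with fresh noise per
    frame.  Returns the sequence (reference index 0), the exact per-bone
    transform series and the exact per-frame landmark positions.

    A bone pushed outside the grid raises a ``ValueError`` naming the frame.
    """
    rng = np.random.default_rng(seed)
    labels = atlas.labels
    bone_labels = labels.present_labels
    motion_by_label = {m.label: m for m in motion.bones}
    unknown = set(motion_by_label) - set(bone_labels)
    if unknown:
        raise ValueError(f"motion refers to absent bone labels {sorted(unknown)}")

    centers = {}
    for lab in bone_labels:
        idx = np.argwhere(labels.labels == lab)
        centers[lab] = atlas.image.world_from_index(idx.mean(axis=0))

    shape = np.asarray(atlas.image.shape)
    frames: list[Volume] = []
    series: dict[int, list[SpatialTransform]] = {lab: [] for lab in bone_labels}
    frame_landmarks: list[LandmarkSet] = []
    source = atlas.clean_image if atlas.clean_image is not None else atlas.image
    ref_img = source.to_sitk()

    for t in range(motion.n_frames):
        voxels = np.full(atlas.image.shape, background_intensity, dtype=float)
        for lab in sorted(bone_labels, reverse=True):
            bm = motion_by_label.get(lab)
            transform = (bm.transform_at(t, centers[lab]) if bm is not None
                         else SpatialTransform.identity())
            series[lab].append(transform)
            # bounding-box corners of the bone must stay on the grid
            idx = np.argwhere(labels.labels == lab)
            lo, hi = idx.min(axis=0), idx.max(axis=0)
            corners = np.array([[lo[i] if b & (1 << i) == 0 else hi[i] for i in range(3)]
                                for b in range(8)], dtype=float)
            moved = transform.apply_points(atlas.image.world_from_index(corners))
            moved_idx = atlas.image.index_from_world(moved)
            if np.any(moved_idx < -0.5) or np.any(moved_idx > shape - 0.5):
                raise ValueError(f"bone {lab} leaves the grid at frame {t}")
            inv = transform.inverse()
            # cubic interpolation: linear rendering biases the intensity
            # pattern enough to shift the registration optimum measurably
            img_t = sitk.Resample(ref_img, ref_img, inv.sitk, sitk.sitkBSpline,
                                  background_intensity, sitk.sitkFloat64)
            lab_t = sitk.Resample(labels.to_sitk(), ref_img, inv.sitk,
                                  sitk.sitkNearestNeighbor, 0.0, sitk.sitkInt32)
            arr = np.transpose(sitk.GetArrayFromImage(img_t), (2, 1, 0))
            mask = np.transpose(sitk.GetArrayFromImage(lab_t), (2, 1, 0)) == lab
            voxels[mask] = arr[mask]
        if noise_sd > 0:
            voxels = voxels + rng.normal(0.0, noise_sd, voxels.shape)
        frames.append(atlas.image.with_voxels(voxels))
        moved_lms = [
            Landmark(lm.name, lm.bone_label,
                     series[lm.bone_label][t].apply_point(lm.position))
            for lm in atlas.landmarks
        ]
        frame_landmarks.append(LandmarkSet(moved_lms))

    return DynamicSequence(frames=frames, reference_index=0), series, frame_landmarks


# ---------------------------------------------------------------------------
# ready-made two-bone joint
# ---------------------------------------------------------------------------

def default_two_bone_spec(grid: int = 64, spacing: float = 1.0) -> PhantomSpec:
    """A desk-scale two-bone joint: a 'proximal' capsule shaft entering from
    above and a 'distal' ellipsoid below, separated by a soft-tissue gap."""
    extent = grid * spacing
    c = extent / 2.0
    axes = [("+x", (1, 0, 0)), ("+y", (0, 1, 0)), ("-x", (-1, 0, 0))]
    proximal = BoneSpec(
        label=2, shape="capsule", center=(c, c, 0.66 * extent),
        semi_axes=(0.13 * extent, 0.13 * extent, 0.24 * extent),
        cortical_shell_thickness=2.0 * spacing,
        landmark_recipe=[(f"prox_{n}", d) for n, d in axes] + [("prox_top", (0, 0, 1))],
        lobes=[((0.07 * extent, 0.04 * extent, -0.16 * extent),
                (0.06 * extent, 0.05 * extent, 0.06 * extent))],
    )
    distal = BoneSpec(
        label=1, shape="ellipsoid", center=(c, c, 0.23 * extent),
        semi_axes=(0.19 * extent, 0.15 * extent, 0.12 * extent),
        cortical_shell_thickness=2.0 * spacing,
        landmark_recipe=[(f"dist_{n}", d) for n, d in axes] + [("dist_bottom", (0, 0, -1))],
        # condyle-like lobes: break rotational symmetry of the epiphysis
        lobes=[((0.10 * extent, 0.06 * extent, -0.02 * extent),
                (0.07 * extent, 0.06 * extent, 0.08 * extent)),
               ((-0.09 * extent, -0.05 * extent, -0.04 * extent),
                (0.06 * extent, 0.07 * extent, 0.06 * extent))],
    )
    return PhantomSpec(grid_shape=(grid,) * 3, spacing=(spacing,) * 3,
                       bones=[distal, proximal])


def default_two_bone_motion(n_frames: int = 15, rotation_per_frame_deg: float = 2.0,
                            translation_per_frame: tuple[float, float, float]
                            = (0.0, 0.0, 0.0)) -> MotionSpec:
    """Distal bone rotates about z through its centre (and optionally
    translates); the proximal bone stays put — a stylized flexion ramp."""
    return MotionSpec(n_frames=n_frames, bones=[
        BoneMotion(label=1, rotation_axis=(0, 0, 1),
                   rotation_per_frame_deg=rotation_per_frame_deg,
                   translation_per_frame=translation_per_frame),
    ])
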
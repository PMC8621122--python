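"""Bone-embedded reference frames and cardan-angle joint kinematics.

A bone-embedded frame is an orthonormal triad (i, j, k) built from three
anatomical landmarks: a primary axis from one landmark to another, a
temporary in-plane vector to a third landmark, and cross products to
complete a right-handed basis.  Following the usual direction-cosine
convention, the rows of the frame's rotation matrix R are the unit vectors
i, j, k expressed in the global (scanner) coordinate system, so R maps
global coordinates into bone-local coordinates.

The relative rotation between a distal and a proximal segment is

    R_relative = R_distal · R_proximal⁻¹

and joint motion is reported as cardan angles of the rotation relative to
the joint's posture at the reference frame, so the reference time point is
(0, 0, 0) by construction.  Cardan sequences are intrinsic (mobile-axes)
ZXY (thumb base) or ZYX (knee), angles in degrees, middle angle in
[-90°, 90°].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .landmarks import Landmark, LandmarkSet

__all__ = [
    "FrameDefinition",
    "ReferenceFrame",
    "CardanAngles",
    "KinematicSeries",
    "build_frame",
    "relative_rotation",
    "cardan_from_rotation",
    "rotation_from_cardan",
    "propagate_landmarks_time",
    "propagate_atlas_landmarks",
    "kinematics_pipeline",
    "load_frame_definition",
]

_AXES = {"i": 0, "j": 1, "k": 2}
_ELEMENTARY_AXIS = {"X": 0, "Y": 1, "Z": 2}


@dataclass
class FrameDefinition:
    """How to build a bone-embedded frame from named landmarks.

    The primary axis runs from ``axis_from`` to ``axis_to`` and is assigned
    to ``axis_name`` (one of i/j/k); ``plane_landmark`` (relative to the
    origin landmark) spans the primary plane and its cross-product
    completes the triad; the remaining axis is assigned ``plane_axis``.
    ``signs`` lets a definition flip reported angle signs (left/right
    mirror consistency).
    """

    bone_label: int
    origin_landmark: str
    axis_from: str
    axis_to: str
    axis_name: str                  # i | j | k
    plane_landmark: str
    plane_axis: str                 # i | j | k, distinct from axis_name
    signs: tuple[int, int, int] = (1, 1, 1)
    name: str = ""

    def __post_init__(self) -> None:
        if self.axis_name not in _AXES or self.plane_axis not in _AXES:
            raise ValueError("axes must be named i, j or k")
        if self.axis_name == self.plane_axis:
            raise ValueError("primary and plane axes must differ")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +-1")


@dataclass
class ReferenceFrame:
    """Orthonormal bone frame: rows of R are i, j, k in global coordinates."""

    origin: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9) or \
                not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
            raise ValueError("frame rotation must be orthonormal with det +1")


@dataclass
class CardanAngles:
    sequence: str                 # ZXY | ZYX
    angles: tuple[float, float, float]   # degrees, in sequence order
    gimbal_flag: bool = False


@dataclass
class KinematicSeries:
    """Per-frame cardan angles of distal-vs-proximal motion relative to the
    reference posture; invalid frames flagged (tracking fallback or
    geometry failure)."""

    sequence: str
    angles: np.ndarray            # (n_frames, 3) degrees
    valid: np.ndarray             # (n_frames,) bool
    reference_index: int = 0

    def to_frame(self) -> pd.DataFrame:
        a1, a2, a3 = (f"theta_{c.lower()}" for c in self.sequence)
        return pd.DataFrame({
            "frame": np.arange(len(self.angles)),
            a1: self.angles[:, 0], a2: self.angles[:, 1], a3: self.angles[:, 2],
            "valid": self.valid.astype(bool),
        })


def _unit(v: np.ndarray, context: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-6:
        raise ValueError(f"degenerate geometry: {context} has near-zero length")
    return v / n


def build_frame(landmarks: LandmarkSet, definition: FrameDefinition) -> ReferenceFrame:
    """Construct the bone-embedded frame from landmarks (world mm).

    Raises ``ValueError`` when required landmarks are missing or collinear.
    """
    try:
        origin = landmarks[definition.origin_landmark].position
        a_from = landmarks[definition.axis_from].position
        a_to = landmarks[definition.axis_to].position
        planep = landmarks[definition.plane_landmark].position
    except KeyError as exc:
        raise ValueError(f"frame '{definition.name}': {exc.args[0]}") from exc

    primary = _unit(a_to - a_from, "primary axis")
    temp = planep - origin
    third = np.cross(primary, temp)
    if np.linalg.norm(third) < 1e-6:
        raise ValueError(
            f"frame '{definition.name}': landmarks are collinear "
            "(cross product vanishes)")
    third = third / np.linalg.norm(third)
    second = np.cross(third, primary)

    i_primary = _AXES[definition.axis_name]
    i_plane = _AXES[definition.plane_axis]
    i_third = 3 - i_primary - i_plane
    rows = np.empty((3, 3))
    rows[i_primary] = primary
    rows[i_plane] = second
    rows[i_third] = third
    if np.linalg.det(rows) < 0:          # enforce right-handedness
        rows[i_third] = -rows[i_third]
    return ReferenceFrame(origin=origin, R=rows)


def relative_rotation(distal: ReferenceFrame, proximal: ReferenceFrame) -> np.ndarray:
    """R_relative = R_distal · R_proximal⁻¹ (orthonormal inverse)."""
    return distal.R @ proximal.R.T


def _elementary(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(3)
    a, b = [x for x in range(3) if x != axis]
    m[a, a] = c
    m[b, b] = c
    m[a, b] = -s if (b - a) % 3 == 1 else s
    m[b, a] = -m[a, b]
    return m


def rotation_from_cardan(angles_deg, sequence: str) -> np.ndarray:
    """Compose an intrinsic cardan sequence: R = R1(θ1)·R2(θ2)·R3(θ3)."""
    if sequence not in ("ZXY", "ZYX"):
        raise ValueError("sequence must be ZXY or ZYX")
    r = np.eye(3)
    for letter, angle in zip(sequence, angles_deg):
        r = r @ _elementary(_ELEMENTARY_AXIS[letter], np.deg2rad(angle))
    return r


_GIMBAL_EPS = 1e-9


def cardan_from_rotation(R: np.ndarray, sequence: str) -> CardanAngles:
    """Intrinsic cardan decomposition (degrees).

    Solves ``R = R1(θ1)·R2(θ2)·R3(θ3)`` for the stated axis sequence with
    θ2 ∈ [-90°, 90°].  At gimbal lock (|sin argument| → 1) θ1 and θ3 are
    not separable; θ3 is set to 0 and the result flagged.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise ValueError("input is not orthonormal within 1e-6")
    if sequence == "ZXY":
        s2 = R[2, 1]
    elif sequence == "ZYX":
        s2 = -R[2, 0]
    else:
        raise ValueError("sequence must be ZXY or ZYX")

    gimbal = abs(s2) > 1.0 - _GIMBAL_EPS
    theta2 = np.arcsin(np.clip(s2, -1.0, 1.0))
    if gimbal:
        warnings.warn(f"gimbal lock in {sequence} decomposition; third angle set to 0",
                      stacklevel=2)
        # with θ3 = 0 the composition reduces to a single rotation in the
        # θ1 plane whichever sequence is used
        if sequence == "ZXY":
            theta1 = np.arctan2(R[1, 0], R[0, 0])
        else:
            theta1 = np.arctan2(-R[0, 1], R[1, 1])
        theta3 = 0.0
    elif sequence == "ZXY":
        theta1 = np.arctan2(-R[0, 1], R[1, 1])
        theta3 = np.arctan2(-R[2, 0], R[2, 2])
    else:
        theta1 = np.arctan2(R[1, 0], R[0, 0])
        theta3 = np.arctan2(R[2, 1], R[2, 2])
    return CardanAngles(
        sequence=sequence,
        angles=tuple(np.rad2deg([theta1, theta2, theta3])),
        gimbal_flag=bool(gimbal),
    )


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def propagate_landmarks_time(landmarks: LandmarkSet, motion,
                             frame: int) -> LandmarkSet:
    """Landmark positions at one time point: ``T_bone,t`` applied per bone."""
    moved = []
    for lm in landmarks:
        if lm.bone_label not in motion.transforms:
            raise KeyError(
                f"landmark '{lm.name}': no motion series for bone {lm.bone_label}")
        t = motion.transforms[lm.bone_label][frame]
        moved.append(Landmark(lm.name, lm.bone_label, t.apply_point(lm.position)))
    return LandmarkSet(moved)


def propagate_atlas_landmarks(atlases, transforms, weight_maps, target,
                              ) -> tuple[LandmarkSet, list[str]]:
    """Transfer atlas landmarks onto the target image by weighted vote.

    Each atlas proposes one candidate position per landmark name via the
    inverse of its registration transform (which maps target space into
    atlas space).  The winning candidate is the one whose atlas has the
    highest local similarity weight at the candidate's voxel.  An atlas
    abstains for a landmark when the candidate falls outside the target
    domain; if every atlas abstains the landmark is reported missing.

    Returns ``(landmarks, missing_names)``.
    """
    if not (len(atlases) == len(transforms) == len(weight_maps)):
        raise ValueError("atlases, transforms and weight maps must align")
    shape = np.asarray(target.shape)
    candidates: dict[str, list[tuple[float, Landmark]]] = {}
    for atlas, transform, wmap in zip(atlases, transforms, weight_maps):
        for lm in atlas.landmarks:
            pos, converged = transform.invert_point(lm.position)
            if not converged:
                continue
            idx = np.round(target.index_from_world(pos)).astype(int)
            if np.any(idx < 0) or np.any(idx >= shape):
                continue
            weight = float(wmap.voxels[tuple(idx)])
            candidates.setdefault(lm.name, []).append(
                (weight, Landmark(lm.name, lm.bone_label, pos)))
    names = sorted({lm.name for a in atlases for lm in a.landmarks})
    winners, missing = [], []
    for name in names:
        if name not in candidates:
            missing.append(name)
            continue
        _, best = max(candidates[name], key=lambda t: t[0])
        winners.append(best)
    return LandmarkSet(winners), missing


def kinematics_pipeline(motion, landmarks: LandmarkSet,
                        distal_def: FrameDefinition,
                        proximal_def: FrameDefinition,
                        sequence: str = "ZYX") -> KinematicSeries:
    """Cardan-angle series of distal-vs-proximal motion across a sequence.

    Per frame: propagate landmarks with the tracked rigid transforms, build
    both bone frames, form the relative rotation, express it relative to
    the reference posture and decompose into cardan angles.  The angle at
    the reference frame is (0, 0, 0) by construction.  Frames whose
    tracking fell back or whose geometry degenerates are flagged invalid
    (angles NaN) without aborting the series.
    """
    n = motion.n_frames
    ref = motion.reference_index
    rel = [None] * n
    valid = np.ones(n, dtype=bool)
    for t in range(n):
        try:
            lms_t = propagate_landmarks_time(landmarks, motion, t)
            distal = build_frame(lms_t, distal_def)
            proximal = build_frame(lms_t, proximal_def)
            rel[t] = relative_rotation(distal, proximal)
        except (ValueError, KeyError):
            valid[t] = False
    if rel[ref] is None:
        raise ValueError("reference frame geometry is invalid; cannot normalize")
    flags = motion.fallback_flags()
    angles = np.full((n, 3), np.nan)
    signs = np.asarray(distal_def.signs, dtype=float)
    for t in range(n):
        if rel[t] is None:
            continue
        if flags is not None and flags[t]:
            valid[t] = False
        # motion relative to the reference posture, expressed in the
        # reference bone axes: +θ for a physical +θ rotation of the distal
        # bone about its own axis
        m = rel[ref] @ rel[t].T
        card = cardan_from_rotation(m, sequence)
        angles[t] = signs * np.asarray(card.angles)
    return KinematicSeries(sequence=sequence, angles=angles, valid=valid,
                           reference_index=ref)


# ---------------------------------------------------------------------------
# YAML frame definitions
# ---------------------------------------------------------------------------

def load_frame_definition(path: str) -> FrameDefinition:
    """Read a frame definition from YAML (see the shipped joint files)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return FrameDefinition(
            bone_label=int(doc["bone_label"]),
            origin_landmark=doc["origin"],
            axis_from=doc["axis"]["from"],
            axis_to=doc["axis"]["to"],
            axis_name=doc["axis"]["name"],
            plane_landmark=doc["plane"]["landmark"],
            plane_axis=doc["plane"]["name"],
            signs=tuple(doc.get("signs", (1, 1, 1))),
            name=doc.get("name", ""),
        )
    except KeyError as exc:
        raise ValueError(f"frame definition '{path}' missing key {exc}") from exc
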
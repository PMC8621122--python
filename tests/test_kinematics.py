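"""Cardan angles, bone-embedded frames and landmark propagation."""

import numpy as np
import pytest

from dynajoint import (CardanAngles, FrameDefinition, Landmark, LandmarkSet,
                       ReferenceFrame, SpatialTransform, build_frame,
                       cardan_from_rotation, kinematics_pipeline,
                       load_frame_definition, propagate_atlas_landmarks,
                       propagate_landmarks_time, relative_rotation,
                       rotation_from_cardan)
from dynajoint.motion import RigidMotionSeries

from conftest import rigid_z


def _rot(axis, deg):
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler(axis, deg, degrees=True).as_matrix()


# -- cardan ----------------------------------------------------------------

@pytest.mark.parametrize("sequence", ["ZXY", "ZYX"])
def test_identity_decomposes_to_zero(sequence):
    c = cardan_from_rotation(np.eye(3), sequence)
    assert np.allclose(c.angles, 0.0)
    assert not c.gimbal_flag


def test_pure_z_rotation_zyx():
    c = cardan_from_rotation(_rot("z", 30.0), "ZYX")
    assert np.allclose(c.angles, (30.0, 0.0, 0.0), atol=1e-12)


def test_explicit_composition_round_trip():
    r = rotation_from_cardan((10.0, 20.0, 30.0), "ZXY")
    c = cardan_from_rotation(r, "ZXY")
    assert np.allclose(c.angles, (10.0, 20.0, 30.0), atol=1e-9)


@pytest.mark.parametrize("sequence", ["ZXY", "ZYX"])
def test_cardan_round_trips_random(sequence):
    rng = np.random.default_rng(33)
    for _ in range(300):
        angles = rng.uniform((-179, -89, -179), (179, 89, 179))
        r = rotation_from_cardan(angles, sequence)
        c = cardan_from_rotation(r, sequence)
        # angle space: decompose(compose) is the identity within ranges
        assert np.allclose(c.angles, angles, atol=1e-9), (angles, c.angles)
        # rotation space: compose(decompose) reproduces the matrix
        assert np.allclose(rotation_from_cardan(c.angles, sequence), r,
                           atol=1e-9)


@pytest.mark.parametrize("sequence", ["ZXY", "ZYX"])
def test_cardan_matches_scipy(sequence):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(7)
    for _ in range(50):
        r = Rotation.random(rng=rng).as_matrix()
        ours = cardan_from_rotation(r, sequence).angles
        theirs = Rotation.from_matrix(r).as_euler(sequence, degrees=True)
        assert np.allclose(ours, theirs, atol=1e-9)


def test_gimbal_lock_flagged():
    r = rotation_from_cardan((25.0, 90.0, 0.0), "ZYX")
    with pytest.warns(UserWarning, match="gimbal"):
        c = cardan_from_rotation(r, "ZYX")
    assert c.gimbal_flag
    assert c.angles[2] == 0.0


def test_non_orthonormal_input_rejected():
    with pytest.raises(ValueError):
        cardan_from_rotation(np.diag([1.0, 2.0, 1.0]), "ZYX")


# -- frames ----------------------------------------------------------------

def _triad(origin=(0, 0, 0)):
    o = np.asarray(origin, dtype=float)
    return LandmarkSet([
        Landmark("O", 1, o),
        Landmark("X", 1, o + (1, 0, 0)),
        Landmark("Y", 1, o + (0, 1, 0)),
    ])


def _definition():
    return FrameDefinition(1, "O", "O", "X", "i", "Y", "j", name="test")


def test_frame_from_axis_aligned_triad_is_identity():
    f = build_frame(_triad(), _definition())
    np.testing.assert_allclose(f.R, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(f.origin, (0, 0, 0))


def test_frame_equivariance_under_rotation():
    q = _rot("zxy", [40.0, 10.0, -25.0])
    lms = _triad()
    rotated = lms.with_positions((q @ lms.positions().T).T)
    f = build_frame(rotated, _definition())
    base = build_frame(lms, _definition())
    # rows are axis vectors: rotating the landmarks by Q maps each row
    # through Q
    np.testing.assert_allclose(f.R, base.R @ q.T, atol=1e-12)


def test_collinear_landmarks_rejected():
    lms = LandmarkSet([Landmark("O", 1, (0, 0, 0)),
                       Landmark("X", 1, (1, 0, 0)),
                       Landmark("Y", 1, (2, 0, 0))])
    with pytest.raises(ValueError, match="collinear"):
        build_frame(lms, _definition())


def test_missing_landmark_named_in_error():
    lms = LandmarkSet([Landmark("O", 1, (0, 0, 0)),
                       Landmark("X", 1, (1, 0, 0))])
    with pytest.raises(ValueError, match="Y"):
        build_frame(lms, _definition())


def test_frame_always_right_handed():
    rng = np.random.default_rng(12)
    for _ in range(25):
        pts = rng.normal(size=(3, 3)) * 10
        lms = LandmarkSet([Landmark(n, 1, p) for n, p in zip("OXY", pts)])
        try:
            f = build_frame(lms, _definition())
        except ValueError:
            continue
        assert np.isclose(np.linalg.det(f.R), 1.0, atol=1e-9)


def test_relative_rotation_examples():
    rz40 = ReferenceFrame((0, 0, 0), _rot("z", 40.0))
    rz10 = ReferenceFrame((0, 0, 0), _rot("z", 10.0))
    np.testing.assert_allclose(relative_rotation(rz40, rz10), _rot("z", 30.0),
                               atol=1e-12)
    ident = ReferenceFrame((0, 0, 0), np.eye(3))
    np.testing.assert_allclose(relative_rotation(rz40, rz40), np.eye(3),
                               atol=1e-12)
    np.testing.assert_allclose(relative_rotation(rz40, ident), _rot("z", 40.0))


# -- propagation -----------------------------------------------------------

def _motion_series(transforms_by_bone, ref=0):
    return RigidMotionSeries.from_ground_truth(transforms_by_bone, ref)


def test_propagate_time_identity_and_translation():
    lms = _triad()
    ident = _motion_series({1: [SpatialTransform.identity()] * 3})
    for t in range(3):
        out = propagate_landmarks_time(lms, ident, t)
        np.testing.assert_allclose(out.positions(), lms.positions())
    shift = _motion_series({1: [rigid_z(0, (t * 2.0, 0, 0)) for t in range(3)]})
    out = propagate_landmarks_time(lms, shift, 2)
    np.testing.assert_allclose(out.positions(), lms.positions() + (4, 0, 0))


def test_propagation_preserves_inter_landmark_distances():
    lms = _triad(origin=(5, 5, 5))
    centroid = lms.positions().mean(axis=0)
    series = _motion_series({1: [rigid_z(30.0 * t, (0.5 * t, 0, 0),
                                         center=centroid) for t in range(4)]})
    d0 = np.linalg.norm(lms.positions()[:, None] - lms.positions()[None], axis=2)
    out = propagate_landmarks_time(lms, series, 3)
    d3 = np.linalg.norm(out.positions()[:, None] - out.positions()[None], axis=2)
    np.testing.assert_allclose(d3, d0, atol=1e-9)


def test_propagate_missing_bone_rejected():
    series = _motion_series({2: [SpatialTransform.identity()]})
    with pytest.raises(KeyError):
        propagate_landmarks_time(_triad(), series, 0)


def test_atlas_landmark_vote_picks_highest_local_weight(small_atlas):
    from dynajoint import Volume

    target = small_atlas.image
    good = small_atlas
    # corrupt copy of the atlas offsets its landmark by 3 mm
    bad_lms = LandmarkSet([Landmark(lm.name, lm.bone_label,
                                    lm.position + (3.0, 0, 0))
                           for lm in small_atlas.landmarks])
    bad = type(small_atlas)(image=small_atlas.image, labels=small_atlas.labels,
                            landmarks=bad_lms, id="bad")
    ident = SpatialTransform.identity()
    w_good = target.with_voxels(np.full(target.shape, 0.9))
    w_bad = target.with_voxels(np.full(target.shape, 0.2))
    result, missing = propagate_atlas_landmarks(
        [good, bad], [ident, ident], [w_good, w_bad], target)
    assert not missing
    for lm in good.landmarks:
        np.testing.assert_allclose(result[lm.name].position, lm.position,
                                   atol=1e-9)


def test_atlas_landmarks_all_outside_reported_missing(small_atlas):
    target = small_atlas.image
    far = SpatialTransform.rigid(translation=(-500.0, 0, 0))
    w = target.with_voxels(np.ones(target.shape))
    result, missing = propagate_atlas_landmarks([small_atlas], [far], [w],
                                                target)
    assert len(result) == 0
    assert set(missing) == set(small_atlas.landmarks.names)


# -- pipeline-level properties --------------------------------------------

def _two_bone_landmarks():
    return LandmarkSet([
        Landmark("O1", 1, (10.0, 10.0, 10.0)),
        Landmark("X1", 1, (20.0, 10.0, 10.0)),
        Landmark("Y1", 1, (10.0, 20.0, 10.0)),
        Landmark("O2", 2, (10.0, 10.0, 40.0)),
        Landmark("X2", 2, (20.0, 10.0, 40.0)),
        Landmark("Y2", 2, (10.0, 20.0, 40.0)),
    ])


def _defs():
    distal = FrameDefinition(1, "O1", "O1", "X1", "i", "Y1", "j")
    proximal = FrameDefinition(2, "O2", "O2", "X2", "i", "Y2", "j")
    return distal, proximal


def test_static_series_gives_zero_angles():
    series = _motion_series({1: [SpatialTransform.identity()] * 5,
                             2: [SpatialTransform.identity()] * 5})
    distal, proximal = _defs()
    ks = kinematics_pipeline(series, _two_bone_landmarks(), distal, proximal)
    np.testing.assert_allclose(ks.angles, 0.0, atol=1e-12)
    assert ks.valid.all()


def test_known_distal_z_rotation_recovered_with_positive_sign():
    lms = _two_bone_landmarks()
    centroid = lms.subset(1).positions().mean(axis=0)
    angles = [0.0, 5.0, 12.5, 30.0]
    series = _motion_series({
        1: [rigid_z(a, center=centroid) for a in angles],
        2: [SpatialTransform.identity()] * 4,
    })
    distal, proximal = _defs()
    ks = kinematics_pipeline(series, lms, distal, proximal, "ZYX")
    np.testing.assert_allclose(ks.angles[:, 0], angles, atol=1e-9)
    np.testing.assert_allclose(ks.angles[:, 1:], 0.0, atol=1e-9)


def test_common_rigid_motion_leaves_angles_unchanged():
    rng = np.random.default_rng(19)
    from scipy.spatial.transform import Rotation

    lms = _two_bone_landmarks()
    centroid = lms.subset(1).positions().mean(axis=0)
    base = {
        1: [rigid_z(7.0 * t, center=centroid) for t in range(4)],
        2: [SpatialTransform.identity()] * 4,
    }
    distal, proximal = _defs()
    ks0 = kinematics_pipeline(_motion_series(base), lms, distal, proximal)

    q = Rotation.random(rng=rng).as_matrix()
    common = SpatialTransform.rigid(q, rng.normal(size=3) * 10,
                                    center=(15, 15, 25))
    moved = {b: [SpatialTransform.composite([t, common])
                 for t in series] for b, series in base.items()}
    ks1 = kinematics_pipeline(_motion_series(moved), lms, distal, proximal)
    np.testing.assert_allclose(ks1.angles, ks0.angles, atol=1e-9)


def test_sign_mask_flips_reported_angles():
    lms = _two_bone_landmarks()
    centroid = lms.subset(1).positions().mean(axis=0)
    series = _motion_series({1: [rigid_z(a, center=centroid)
                                 for a in (0.0, 10.0)],
                             2: [SpatialTransform.identity()] * 2})
    distal, proximal = _defs()
    flipped = FrameDefinition(1, "O1", "O1", "X1", "i", "Y1", "j",
                              signs=(-1, 1, 1))
    ks = kinematics_pipeline(series, lms, flipped, proximal, "ZYX")
    np.testing.assert_allclose(ks.angles[1, 0], -10.0, atol=1e-9)


def test_build_then_rotate_commutes_with_rotate_then_build():
    rng = np.random.default_rng(3)
    from scipy.spatial.transform import Rotation

    lms = _triad(origin=(4, 2, 1))
    q = Rotation.random(rng=rng)
    t = SpatialTransform.rigid(q.as_matrix(), (3, -1, 2), center=(0, 0, 0))
    moved = lms.with_positions(np.stack([t.apply_point(p)
                                         for p in lms.positions()]))
    f_after = build_frame(moved, _definition())
    f_before = build_frame(lms, _definition())
    np.testing.assert_allclose(f_after.R, f_before.R @ q.as_matrix().T,
                               atol=1e-9)


def test_shipped_frame_definitions_load():
    import importlib.resources as resources

    for name in ("knee_femur", "knee_tibia", "thumb_first_metacarpal",
                 "thumb_trapezium", "phantom_distal", "phantom_proximal"):
        with resources.as_file(resources.files("dynajoint") / "data" /
                               f"{name}.yaml") as path:
            d = load_frame_definition(str(path))
        assert d.axis_name != d.plane_axis
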
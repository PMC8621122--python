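"""Shared fixtures: small synthetic phantoms generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from dynajoint import Volume
from dynajoint.phantom import (BoneSpec, PhantomSpec, default_two_bone_spec,
                               generate_joint_phantom)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """32³ two-bone phantom spec for cheap unit tests."""
    return default_two_bone_spec(grid=32)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return generate_joint_phantom(small_spec, seed=42)


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    """The default 64³ phantom used by the deeper simulation tests."""
    return default_two_bone_spec()


@pytest.fixture(scope="session")
def desk_atlas(desk_spec):
    return generate_joint_phantom(desk_spec, seed=3)


@pytest.fixture
def single_sphere_volume() -> Volume:
    """One bright sphere on dark background, 24³ at 1 mm."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 24), spacing=(1, 1, 1), noise_sd=0.0,
        bones=[BoneSpec(label=1, shape="ellipsoid", center=(12, 12, 12),
                        semi_axes=(6, 6, 6), cortical_shell_thickness=1.5)])
    return generate_joint_phantom(spec, seed=0).image


def rigid_z(angle_deg: float, translation=(0.0, 0.0, 0.0), center=(0.0, 0.0, 0.0)):
    from dynajoint import SpatialTransform
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0],
                    [0, 0, 1]])
    return SpatialTransform.rigid(rot, translation, center=center)
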
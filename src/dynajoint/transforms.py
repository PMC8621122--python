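"""Rigid / affine / B-spline / composite spatial transforms.

All transforms map world points (mm) to world points (mm).  A registration
result follows the resampling convention: it maps FIXED-space points into
MOVING space.  Propagating points that live in the moving image into fixed
space therefore uses the inverse; for B-spline (and composites containing
one) the inverse is solved numerically per point by fixed-point iteration.

Composite transforms apply their stages in declared order: ``composite([a,
b])`` maps ``x`` to ``b(a(x))``.

Transforms serialize to a small JSON dialect carrying the kind, parameter
vector and (for B-spline) the control-point grid metadata.
"""

from __future__ import annotations

import json

import numpy as np
import SimpleITK as sitk

__all__ = ["SpatialTransform", "read_transform", "write_transform"]

_RIGID_TOL = 1e-9


def _rotation_ok(matrix: np.ndarray, tol: float = _RIGID_TOL) -> bool:
    return (
        np.allclose(matrix.T @ matrix, np.eye(3), atol=tol)
        and abs(np.linalg.det(matrix) - 1.0) < tol
    )


class SpatialTransform:
    """Wrapper around a SimpleITK transform with a declared kind.

    ``kind`` is one of ``rigid``, ``affine``, ``bspline``, ``composite``.
    """

    def __init__(self, kind: str, transform: sitk.Transform):
        if kind not in ("rigid", "affine", "bspline", "composite"):
            raise ValueError(f"unknown transform kind '{kind}'")
        self.kind = kind
        self.sitk = transform
        if kind == "rigid":
            matrix = np.asarray(transform.GetMatrix()).reshape(3, 3)
            if not _rotation_ok(matrix, tol=1e-6):
                raise ValueError("rigid transform rotation block is not a proper rotation")

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls("rigid", sitk.Euler3DTransform())

    @classmethod
    def rigid(cls, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0),
              center=(0.0, 0.0, 0.0)) -> "SpatialTransform":
        """Rigid transform x -> R (x - c) + c + t."""
        t = sitk.Euler3DTransform()
        t.SetCenter(tuple(np.asarray(center, dtype=float)))
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            if not _rotation_ok(rotation, tol=1e-6):
                raise ValueError("rotation must be orthonormal with det +1")
            t.SetMatrix(tuple(rotation.ravel()), 1e-8)
        t.SetTranslation(tuple(np.asarray(translation, dtype=float)))
        return cls("rigid", t)

    @classmethod
    def affine(cls, matrix: np.ndarray, translation=(0.0, 0.0, 0.0),
               center=(0.0, 0.0, 0.0)) -> "SpatialTransform":
        t = sitk.AffineTransform(3)
        t.SetCenter(tuple(np.asarray(center, dtype=float)))
        t.SetMatrix(tuple(np.asarray(matrix, dtype=float).ravel()))
        t.SetTranslation(tuple(np.asarray(translation, dtype=float)))
        return cls("affine", t)

    @classmethod
    def composite(cls, stages: "list[SpatialTransform]") -> "SpatialTransform":
        """Compose stages; ``stages[0]`` is applied first to points."""
        if not stages:
            raise ValueError("composite requires at least one stage")
        flat: list[SpatialTransform] = []
        for s in stages:
            flat.extend(s.stages if s.kind == "composite" else [s])
        # SimpleITK applies the LAST transform in the queue first.
        ct = sitk.CompositeTransform([s.sitk for s in reversed(flat)])
        out = cls("composite", ct)
        out._stages = flat
        return out

    @property
    def stages(self) -> "list[SpatialTransform]":
        if self.kind != "composite":
            return [self]
        return list(self._stages)

    # -- point mapping ----------------------------------------------------
    def apply_point(self, point) -> np.ndarray:
        return np.asarray(self.sitk.TransformPoint(tuple(np.asarray(point, dtype=float))))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.stack([self.apply_point(p) for p in points])

    def invert_point(self, point, tol: float = 1e-3, max_iter: int = 100):
        """Solve ``T(x) = point`` for ``x``.

        Exact for rigid/affine; composites invert their stages in reverse
        order; the B-spline inverse is a fixed-point iteration (it is a
        near-identity displacement, so the iteration contracts).  Returns
        ``(x, converged)``.
        """
        if self.kind in ("rigid", "affine"):
            inv = self.inverse()
            return inv.apply_point(point), True
        if self.kind == "composite":
            x = np.asarray(point, dtype=float)
            converged = True
            for stage in reversed(self.stages):
                x, ok = stage.invert_point(x, tol=tol, max_iter=max_iter)
                converged = converged and ok
            return x, converged
        y = np.asarray(point, dtype=float)
        x = y.copy()
        for _ in range(max_iter):
            residual = y - self.apply_point(x)
            x = x + residual
            if np.linalg.norm(residual) < tol:
                return x, True
        return x, False

    def inverse(self) -> "SpatialTransform":
        """Exact inverse; only available for rigid/affine (and composites of them)."""
        if self.kind == "rigid":
            return SpatialTransform("rigid", sitk.Euler3DTransform(self.sitk.GetInverse()))
        if self.kind == "affine":
            return SpatialTransform("affine", sitk.AffineTransform(self.sitk.GetInverse()))
        if self.kind == "composite":
            inv_stages = [s.inverse() for s in reversed(self.stages)]
            return SpatialTransform.composite(inv_stages)
        raise ValueError("B-spline transforms have no closed-form inverse; use invert_point")

    # -- introspection ----------------------------------------------------
    @property
    def parameters(self) -> np.ndarray:
        return np.asarray(self.sitk.GetParameters())

    def rigid_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(R, t) of a rigid/affine transform as the homogeneous map x -> R x + t."""
        if self.kind not in ("rigid", "affine"):
            raise ValueError("matrix form only defined for rigid/affine transforms")
        matrix = np.asarray(self.sitk.GetMatrix()).reshape(3, 3)
        center = np.asarray(self.sitk.GetCenter())
        translation = np.asarray(self.sitk.GetTranslation())
        offset = center + translation - matrix @ center
        return matrix, offset

    def max_displacement(self, volume, n_probe: int = 5) -> float:
        """Largest displacement (mm) over a probe lattice of the volume's domain."""
        shape = np.asarray(volume.shape)
        axes = [np.linspace(0, s - 1, n_probe) for s in shape]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        world = volume.world_from_index(grid)
        mapped = self.apply_points(world)
        return float(np.max(np.linalg.norm(mapped - world, axis=1)))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        if self.kind == "composite":
            return {"kind": "composite", "stages": [s.to_dict() for s in self.stages]}
        d: dict = {"kind": self.kind, "parameters": list(self.sitk.GetParameters())}
        if self.kind in ("rigid", "affine"):
            d["matrix"] = list(np.asarray(self.sitk.GetMatrix()))
            d["center"] = list(self.sitk.GetCenter())
            d["translation"] = list(self.sitk.GetTranslation())
        elif self.kind == "bspline":
            d["fixed_parameters"] = list(self.sitk.GetFixedParameters())
            d["order"] = self.sitk.GetOrder()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpatialTransform":
        kind = d["kind"]
        if kind == "composite":
            return cls.composite([cls.from_dict(s) for s in d["stages"]])
        if kind == "rigid":
            matrix = np.asarray(d["matrix"]).reshape(3, 3)
            return cls.rigid(matrix, d["translation"], d["center"])
        if kind == "affine":
            matrix = np.asarray(d["matrix"]).reshape(3, 3)
            return cls.affine(matrix, d["translation"], d["center"])
        if kind == "bspline":
            t = sitk.BSplineTransform(3, d.get("order", 3))
            t.SetFixedParameters(tuple(d["fixed_parameters"]))
            t.SetParameters(tuple(d["parameters"]))
            return cls("bspline", t)
        raise ValueError(f"unknown transform kind '{kind}'")


def write_transform(transform: SpatialTransform, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=1)


def read_transform(path: str) -> SpatialTransform:
    with open(path) as fh:
        return SpatialTransform.from_dict(json.load(fh))
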
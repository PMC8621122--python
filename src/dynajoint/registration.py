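"""Intensity-based registration: three-stage pairwise (rigid/affine/FFD) and
masked rigid registration.

The pairwise scheme follows the classic multi-atlas recipe: a rigid stage,
an affine stage initialized from it, and a final cubic B-spline free-form
deformation, each run multi-resolution with randomly sampled similarity
(MSD, NCC or MI) and a gradient-descent optimizer.  The optimization itself
is delegated to SimpleITK's registration framework; similarity values for
atlas ranking and diagnostics are computed independently in numpy by
:func:`compute_similarity`.

All registrations run single-threaded so that a given ``rng_seed`` yields a
bit-reproducible parameter trajectory.

Returned transforms map fixed-space world points into moving space (the
resampling convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .landmarks import LandmarkSet
from .transforms import SpatialTransform
from .volume import LabelMap, Volume

__all__ = [
    "StageConfig",
    "RegistrationConfig",
    "SimilarityValue",
    "RegistrationError",
    "DegenerateOverlapError",
    "compute_similarity",
    "register_stage",
    "register_pairwise",
    "register_rigid_masked",
    "map_points",
]


class RegistrationError(RuntimeError):
    """Registration failed; carries the last valid transform when available."""

    def __init__(self, message: str, last_transform: SpatialTransform | None = None):
        super().__init__(message)
        self.last_transform = last_transform


class DegenerateOverlapError(RegistrationError):
    """Too few similarity samples fell inside both image domains."""


@dataclass
class StageConfig:
    transform_kind: str            # rigid | affine | bspline
    metric: str = "MSD"            # MSD | NCC | MI
    max_iterations: int = 1000
    n_samples: int = 2000
    n_resolution_levels: int = 4
    initial_step: float = 2.0      # mm, largest optimizer step
    min_step: float = 1e-4         # mm, convergence threshold
    relaxation: float = 0.6        # step shrink factor on gradient sign change
    sampling: str = "random"       # random | dense

    def __post_init__(self) -> None:
        if self.transform_kind not in ("rigid", "affine", "bspline"):
            raise ValueError(f"unknown transform kind '{self.transform_kind}'")
        if self.metric not in ("MSD", "NCC", "MI"):
            raise ValueError(f"unknown metric '{self.metric}'")
        if self.n_resolution_levels < 1:
            raise ValueError("n_resolution_levels must be >= 1")
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")
        if self.sampling not in ("random", "dense"):
            raise ValueError("sampling must be 'random' or 'dense'")


def default_stages(metric: str = "MSD", *, max_iterations: tuple[int, int, int] = (2000, 1000, 1000),
                   n_samples: int = 2000, n_resolution_levels: int = 4) -> list[StageConfig]:
    """Rigid -> affine -> B-spline stage list with the standard caps
    (2000/1000/1000 iterations, 2000 random samples, 4 levels)."""
    return [
        StageConfig("rigid", metric, max_iterations[0], n_samples, n_resolution_levels),
        StageConfig("affine", metric, max_iterations[1], n_samples, n_resolution_levels),
        StageConfig("bspline", metric, max_iterations[2], n_samples, n_resolution_levels),
    ]


def desk_stages(metric: str = "MSD") -> list[StageConfig]:
    """Reduced-cost stage list for desk-scale volumes (~64³ voxels).

    Same three-stage structure as :func:`default_stages` with iteration
    caps and pyramid depth sized to small phantoms, where full clinical
    caps only add runtime.
    """
    return [
        StageConfig("rigid", metric, 150, 2000, 4, min_step=5e-3),
        StageConfig("affine", metric, 100, 2000, 4, min_step=5e-3),
        StageConfig("bspline", metric, 80, 2000, 2, min_step=1e-2),
    ]


@dataclass
class RegistrationConfig:
    stages: list[StageConfig] = field(default_factory=default_stages)
    mi_bins: int = 32
    rng_seed: int = 0
    bspline_final_grid_spacing: float = 16.0   # mm between control points

    def __post_init__(self) -> None:
        if self.mi_bins < 8:
            raise ValueError("mi_bins must be >= 8")
        if self.bspline_final_grid_spacing <= 0:
            raise ValueError("bspline_final_grid_spacing must be positive")


@dataclass
class SimilarityValue:
    metric: str
    value: float
    n_samples_used: int


# ---------------------------------------------------------------------------
# similarity (numpy path, independent of the SimpleITK optimizer)
# ---------------------------------------------------------------------------

def _interpolate(volume: Volume, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation at continuous voxel indices; returns
    (values, valid) where valid marks indices inside the domain."""
    shape = np.asarray(volume.shape)
    valid = np.all((indices >= 0) & (indices <= shape - 1), axis=1)
    values = np.full(len(indices), np.nan)
    if valid.any():
        values[valid] = ndimage.map_coordinates(
            volume.voxels.astype(float), indices[valid].T, order=1, mode="nearest")
    return values, valid


def _sample_indices(fixed: Volume, n_samples: int | None, mask: LabelMap | None,
                    rng: np.random.Generator) -> np.ndarray:
    if mask is not None:
        candidates = np.argwhere(mask.labels > 0)
        if candidates.size == 0:
            raise ValueError("similarity mask is empty")
    else:
        candidates = None
    if n_samples is None:
        if candidates is None:
            grid = np.indices(fixed.shape).reshape(3, -1).T
            return grid
        return candidates
    if candidates is None:
        shape = np.asarray(fixed.shape)
        return np.column_stack([rng.integers(0, s, n_samples) for s in shape])
    pick = rng.integers(0, len(candidates), n_samples)
    return candidates[pick]


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def compute_similarity(fixed: Volume, moving: Volume, transform: SpatialTransform,
                       metric: str = "MSD", n_samples: int | None = None,
                       mask: LabelMap | None = None, mi_bins: int = 32,
                       seed: int = 0) -> SimilarityValue:
    """Similarity between ``fixed`` and ``transform``-warped ``moving``.

    Samples ``n_samples`` random fixed-domain voxels (or every voxel when
    ``None``, optionally restricted to ``mask``), maps them into moving
    space, and evaluates MSD (intensity² units), NCC (Pearson correlation,
    in [-1, 1]) or MI (nats, from a ``mi_bins``² joint histogram with hard
    bin assignment).  Samples mapping outside the moving domain are
    excluded; fewer than 50% valid raises :class:`DegenerateOverlapError`.
    """
    if metric not in ("MSD", "NCC", "MI"):
        raise ValueError(f"unknown metric '{metric}'")
    rng = np.random.default_rng(seed)
    indices = _sample_indices(fixed, n_samples, mask, rng)
    world = fixed.world_from_index(indices)
    mapped = transform.apply_points(world)
    moving_idx = moving.index_from_world(mapped)
    moving_vals, valid = _interpolate(moving, moving_idx)
    if valid.sum() < 0.5 * len(indices):
        raise DegenerateOverlapError(
            f"only {int(valid.sum())}/{len(indices)} similarity samples fell "
            "inside the moving image domain")
    f = fixed.voxels[tuple(indices[valid].T)].astype(float)
    m = moving_vals[valid]
    n = int(valid.sum())
    if metric == "MSD":
        value = float(np.mean((f - m) ** 2))
    elif metric == "NCC":
        fs, ms = f - f.mean(), m - m.mean()
        denom = np.sqrt((fs ** 2).sum() * (ms ** 2).sum())
        value = float(np.clip(fs @ ms / denom, -1.0, 1.0)) if denom > 0 else 0.0
    else:
        value = _mutual_information(f, m, mi_bins)
    return SimilarityValue(metric=metric, value=value, n_samples_used=n)


# ---------------------------------------------------------------------------
# optimization (SimpleITK path)
# ---------------------------------------------------------------------------

def _single_threaded() -> None:
    # bit-reproducibility: summation order must not depend on scheduling
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    sitk.ProcessObject.GlobalWarningDisplayOff()


def _set_metric(reg: sitk.ImageRegistrationMethod, metric: str, mi_bins: int) -> None:
    if metric == "MSD":
        reg.SetMetricAsMeanSquares()
    elif metric == "NCC":
        reg.SetMetricAsCorrelation()
    else:
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=mi_bins)


def _pyramid(levels: int) -> tuple[list[int], list[float]]:
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    sigmas = [s / 2.0 for s in shrink[:-1]] + [0.0]
    return shrink, sigmas


def _initial_linear(kind: str, fixed: Volume, moving: Volume,
                    init: SpatialTransform | None,
                    center: np.ndarray | None = None) -> sitk.Transform:
    """Initial transform for a linear stage, re-centred at ``center``.

    The rotation centre strongly conditions the optimization: rotating
    about a far-away point couples rotation and translation.  The incoming
    transform's mapping is preserved exactly while its centre is moved.
    """
    if init is not None and init.kind == "composite":
        raise ValueError("linear stages cannot absorb a composite initializer")
    if center is None:
        center = fixed.world_from_index((np.asarray(fixed.shape) - 1) / 2.0)
    if kind == "rigid":
        if init is None:
            t = sitk.Euler3DTransform()
            t0 = sitk.CenteredTransformInitializer(
                fixed.to_sitk(), moving.to_sitk(), t,
                sitk.CenteredTransformInitializerFilter.GEOMETRY)
            init = SpatialTransform("rigid", sitk.Euler3DTransform(t0))
        elif init.kind != "rigid":
            raise ValueError("a rigid stage can only be initialized from a rigid transform")
        matrix, offset = init.rigid_matrix()       # x -> R x + o
        t = sitk.Euler3DTransform()
        t.SetCenter(tuple(center))
        t.SetMatrix(tuple(matrix.ravel()), 1e-8)
        t.SetTranslation(tuple(offset - center + matrix @ center))
        return t
    t = sitk.AffineTransform(3)
    t.SetCenter(tuple(center))
    if init is not None:
        matrix, offset = init.rigid_matrix()
        t.SetMatrix(tuple(matrix.ravel()))
        t.SetTranslation(tuple(offset - center + matrix @ center))
    return t


def _wrap_degenerate(exc: RuntimeError, last: SpatialTransform | None) -> RegistrationError:
    msg = str(exc)
    if "outside" in msg or "samples" in msg.lower() or "Joint PDF" in msg:
        return DegenerateOverlapError(msg, last)
    return RegistrationError(msg, last)


def _build_method(stage: StageConfig, mi_bins: int, seed: int, n_domain_voxels: int,
                  shrink: list[int]) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    _set_metric(reg, stage.metric, mi_bins)
    if stage.sampling == "dense":
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        # the percentage applies to each pyramid level's own voxel count
        pcts = [min(1.0, stage.n_samples / max(1, n_domain_voxels // s ** 3))
                for s in shrink]
        reg.SetMetricSamplingPercentagePerLevel(pcts, int(seed) % (2 ** 31 - 1) + 1)
    reg.SetInterpolator(sitk.sitkLinear)
    sigmas = [s / 2.0 for s in shrink[:-1]] + [0.0]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=stage.initial_step,
        minStep=stage.min_step,
        numberOfIterations=stage.max_iterations,
        relaxationFactor=stage.relaxation,
        gradientMagnitudeTolerance=1e-10,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    return reg


def register_stage(fixed: Volume, moving: Volume, stage: StageConfig,
                   init: SpatialTransform | None = None, *, mi_bins: int = 32,
                   seed: int = 0, bspline_final_grid_spacing: float = 16.0,
                   mask: LabelMap | None = None) -> SpatialTransform:
    """Run one registration stage; deterministic given ``seed``.

    For linear stages the initializer is absorbed and a single transform of
    the stage's kind is returned.  For the B-spline stage ``init`` is used
    as the moving initial transform and only the B-spline component is
    returned; the caller composes (B-spline applied first, then ``init``).
    """
    _single_threaded()
    if mask is not None and not np.any(mask.labels > 0):
        raise ValueError("registration mask is empty")
    n_domain = int(np.count_nonzero(mask.labels)) if mask is not None \
        else int(np.prod(fixed.shape))
    shrink, _ = _pyramid(stage.n_resolution_levels)
    reg = _build_method(stage, mi_bins, seed, n_domain, shrink)
    if mask is not None:
        reg.SetMetricFixedMask(sitk.Cast(mask.to_sitk() > 0, sitk.sitkUInt8))

    if stage.transform_kind == "bspline":
        physical = (np.asarray(fixed.shape) - 1) * fixed.spacing
        mesh = np.maximum(1, np.round(physical / bspline_final_grid_spacing)).astype(int)
        bspline = sitk.BSplineTransformInitializer(fixed.to_sitk(), [int(m) for m in mesh], 3)
        if init is not None:
            reg.SetMovingInitialTransform(init.sitk)
        reg.SetInitialTransform(bspline, inPlace=True)
        kind = "bspline"
        optimized: sitk.Transform = bspline
    else:
        if mask is not None:
            center = fixed.world_from_index(
                np.argwhere(mask.labels > 0).mean(axis=0))
        else:
            center = None
        optimized = _initial_linear(stage.transform_kind, fixed, moving, init, center)
        reg.SetInitialTransform(optimized, inPlace=True)
        kind = stage.transform_kind

    # the optimizer silently stalls when the initialization leaves no
    # overlap, so check explicitly before spending iterations
    if stage.transform_kind == "bspline":
        probe = init if init is not None else SpatialTransform.identity()
    else:
        probe = SpatialTransform(stage.transform_kind, optimized)
    compute_similarity(fixed, moving, probe, "MSD", n_samples=500,
                       mask=mask, seed=seed)

    fixed_img = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat64)
    moving_img = sitk.Cast(moving.to_sitk(), sitk.sitkFloat64)
    try:
        reg.Execute(fixed_img, moving_img)
    except RuntimeError as exc:
        raise _wrap_degenerate(exc, init) from exc
    result = SpatialTransform(kind, optimized)
    result.final_metric_value = float(reg.GetMetricValue())
    return result


def register_pairwise(fixed: Volume, moving: Volume,
                      config: RegistrationConfig) -> SpatialTransform:
    """Multi-stage registration; each stage initialized from the previous.

    Returns the transform mapping fixed-space points into moving space
    (composite when a B-spline stage is present), suitable for resampling
    moving-image labels onto the fixed grid.
    """
    if fixed.voxels.size == 0 or moving.voxels.size == 0:
        raise ValueError("cannot register empty volumes")
    current: SpatialTransform | None = None
    for i, stage in enumerate(config.stages):
        try:
            result = register_stage(
                fixed, moving, stage, init=current, mi_bins=config.mi_bins,
                seed=config.rng_seed + 1009 * i,
                bspline_final_grid_spacing=config.bspline_final_grid_spacing)
        except RegistrationError as exc:
            raise type(exc)(
                f"stage {i} ({stage.transform_kind}/{stage.metric}) failed: {exc}",
                current) from exc
        if stage.transform_kind == "bspline" and current is not None:
            current = SpatialTransform.composite([result, current])
        else:
            current = result
    assert current is not None
    return current


def register_rigid_masked(fixed: Volume, moving: Volume, mask: LabelMap,
                          init: SpatialTransform | None = None, *, seed: int = 0,
                          max_iterations: int = 1500, n_samples: int | None = None,
                          n_resolution_levels: int = 2) -> SpatialTransform:
    """Rigid registration with MSD similarity restricted to ``mask``.

    Used for intra-subject, mono-modal tracking of one bone through a
    dynamic sequence; the mask is the (already dilated) bone region on the
    fixed grid.
    """
    if not isinstance(mask, LabelMap):
        raise TypeError("mask must be a LabelMap")
    if not np.any(mask.labels > 0):
        raise ValueError("mask is empty")
    # dense in-mask sampling by default: the mask is small, and removing
    # the sampling noise lets the step-halving optimizer anneal to the
    # sub-degree optimum instead of stalling on gradient noise
    stage = StageConfig("rigid", "MSD", max_iterations,
                        n_samples if n_samples is not None else 10 ** 6,
                        n_resolution_levels, initial_step=1.0, min_step=1e-5,
                        relaxation=0.7,
                        sampling="dense" if n_samples is None else "random")
    return register_stage(fixed, moving, stage, init=init, seed=seed, mask=mask)


def map_points(transform: SpatialTransform, points: LandmarkSet,
               direction: str = "forward") -> tuple[LandmarkSet, dict[str, bool]]:
    """Map landmarks through a transform.

    ``forward`` applies the transform; ``inverse`` solves ``T(x) = p`` per
    point (exact for rigid/affine, fixed-point iteration to 1e-3 mm for
    B-spline/composites).  Returns the mapped set and a per-name
    convergence flag; a non-convergent point is kept but flagged False.
    """
    if direction not in ("forward", "inverse"):
        raise ValueError("direction must be 'forward' or 'inverse'")
    mapped, ok = [], {}
    for e in points:
        if direction == "forward":
            pos, converged = transform.apply_point(e.position), True
        else:
            pos, converged = transform.invert_point(e.position)
        mapped.append(type(e)(e.name, e.bone_label, pos))
        ok[e.name] = converged
    return LandmarkSet(mapped), ok
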
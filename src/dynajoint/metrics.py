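"""Segmentation overlap and surface-distance metrics, LOOCV driver, and
agreement statistics (Bland-Altman limits of agreement, ICC(2,k)).

Overlap metrics follow the standard definitions for a ground-truth mask A
and a test mask B:

    Dice = 2|A∩B| / (|A| + |B|)
    FP   = |B\\A| / |B|        (false-positive volume fraction)
    FN   = |A\\B| / |A|        (false-negative volume fraction)

Surface distances are Euclidean distances (mm, honouring anisotropic
spacing) between boundary voxels (6-connectivity); the Hausdorff distance
is the maximum of the two directed farthest-nearest-point distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .landmarks import LandmarkSet
from .volume import LabelMap

__all__ = [
    "SegmentationScores",
    "AgreementResult",
    "overlap_scores",
    "surface_distances",
    "score_segmentation",
    "loocv_segmentation",
    "bland_altman",
    "icc",
    "icc_2k",
    "landmark_error",
]


@dataclass
class SegmentationScores:
    label: int
    dice: float
    fp_fraction: float
    fn_fraction: float
    mean_surface_distance: float
    max_surface_distance: float
    sd_surface_distance: float
    hausdorff: float


@dataclass
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float


def _masks(truth: LabelMap, test: LabelMap, label: int) -> tuple[np.ndarray, np.ndarray]:
    if not truth.same_grid(test):
        raise ValueError("truth and test label maps are on different grids")
    a = truth.labels == label
    if not a.any():
        raise ValueError(f"label {label} absent from ground truth")
    return a, test.labels == label


def overlap_scores(truth: LabelMap, test: LabelMap, label: int
                   ) -> tuple[float, float, float]:
    """(Dice, FP fraction, FN fraction) for one label.

    A label absent from the test segmentation scores Dice 0, FP 0, FN 1.
    """
    a, b = _masks(truth, test, label)
    na, nb = int(a.sum()), int(b.sum())
    if nb == 0:
        return 0.0, 0.0, 1.0
    inter = int(np.count_nonzero(a & b))
    dice = 2.0 * inter / (na + nb)
    fp = int(np.count_nonzero(b & ~a)) / nb
    fn = int(np.count_nonzero(a & ~b)) / na
    return dice, fp, fn


_FACES = ndimage.generate_binary_structure(3, 1)   # 6-connectivity


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask minus its 6-connected erosion."""
    return mask & ~ndimage.binary_erosion(mask, structure=_FACES, border_value=0)


def _directed_distances(src: np.ndarray, dst: np.ndarray,
                        spacing: np.ndarray) -> np.ndarray:
    """Distance (mm) from every src surface voxel to the nearest dst surface
    voxel, via an exact Euclidean distance transform of the dst surface."""
    edt = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return edt[src]


def surface_distances(truth: LabelMap, test: LabelMap, label: int) -> SegmentationScores:
    """Symmetric surface-distance statistics and overlap scores for a label.

    Mean/max/SD are taken over the pooled set of both directed distance
    sets (truth-surface -> test-surface and back); Hausdorff is the max of
    the two directed maxima — numerically the same as the pooled max, both
    reported.
    """
    a, b = _masks(truth, test, label)
    if not b.any():
        raise ValueError(f"label {label} absent from test segmentation")
    sa, sb = _surface(a), _surface(b)
    d_ab = _directed_distances(sa, sb, truth.spacing)
    d_ba = _directed_distances(sb, sa, truth.spacing)
    pooled = np.concatenate([d_ab, d_ba])
    dice, fp, fn = overlap_scores(truth, test, label)
    return SegmentationScores(
        label=label,
        dice=dice, fp_fraction=fp, fn_fraction=fn,
        mean_surface_distance=float(pooled.mean()),
        max_surface_distance=float(pooled.max()),
        sd_surface_distance=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        hausdorff=float(max(d_ab.max(), d_ba.max())),
    )


def score_segmentation(truth: LabelMap, test: LabelMap,
                       labels: list[int] | None = None) -> list[SegmentationScores]:
    if labels is None:
        labels = truth.present_labels
    return [surface_distances(truth, test, lab) for lab in labels]


def loocv_segmentation(atlases, reg_config=None, fusion_config=None,
                       progress: bool = False) -> pd.DataFrame:
    """Leave-one-out cross-validation over an atlas population.

    Each atlas in turn is the target: it is segmented from the remaining
    atlases and scored against its own labels.  Returns one row per
    (held-out subject, bone) with overlap and distance scores; a failed
    fold is recorded with NaN scores rather than aborting.
    """
    from .fusion import segment_multi_atlas

    if len(atlases) < 3:
        raise ValueError("LOOCV needs at least 3 atlases")
    rows = []
    for held_out in atlases:
        rest = [a for a in atlases if a.id != held_out.id]
        try:
            fused, _ = segment_multi_atlas(held_out.image, rest, reg_config,
                                           fusion_config, target_id=held_out.id)
            scores = score_segmentation(held_out.labels, fused)
        except Exception as exc:  # a bad fold must not kill the experiment
            import logging
            logging.getLogger(__name__).warning("fold '%s' failed: %s",
                                                held_out.id, exc)
            for lab in held_out.labels.present_labels:
                rows.append({"subject": held_out.id, "label": lab,
                             **{k: np.nan for k in ("dice", "fp_fraction",
                                                    "fn_fraction",
                                                    "mean_surface_distance",
                                                    "max_surface_distance",
                                                    "sd_surface_distance",
                                                    "hausdorff")}})
            continue
        for s in scores:
            rows.append({"subject": held_out.id, "label": s.label,
                         "dice": s.dice, "fp_fraction": s.fp_fraction,
                         "fn_fraction": s.fn_fraction,
                         "mean_surface_distance": s.mean_surface_distance,
                         "max_surface_distance": s.max_surface_distance,
                         "sd_surface_distance": s.sd_surface_distance,
                         "hausdorff": s.hausdorff})
    return pd.DataFrame(rows)


def loocv_compare_fusion(atlases, reg_config, fusion_configs: dict,
                         ) -> pd.DataFrame:
    """LOOCV with several fusion strategies sharing one registration pass.

    The expensive pairwise registrations are identical across fusion
    methods, so each fold builds its candidate stack once and fuses it
    with every config in ``fusion_configs`` (name -> FusionConfig).
    Returns rows (subject, method, label, dice, ...).
    """
    from .fusion import build_candidates, fuse_labels

    if len(atlases) < 3:
        raise ValueError("LOOCV needs at least 3 atlases")
    rows = []
    for held_out in atlases:
        rest = [a for a in atlases if a.id != held_out.id]
        stack = build_candidates(held_out.image, rest, reg_config,
                                 target_id=held_out.id)
        for method, cfg in fusion_configs.items():
            fused = fuse_labels(stack, held_out.image, cfg)
            for s in score_segmentation(held_out.labels, fused):
                rows.append({"subject": held_out.id, "method": method,
                             "label": s.label, "dice": s.dice,
                             "fp_fraction": s.fp_fraction,
                             "fn_fraction": s.fn_fraction,
                             "mean_surface_distance": s.mean_surface_distance,
                             "max_surface_distance": s.max_surface_distance,
                             "sd_surface_distance": s.sd_surface_distance,
                             "hausdorff": s.hausdorff})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def bland_altman(series_a, series_b) -> AgreementResult:
    """Bland-Altman bias and 95% limits of agreement of two paired series.

    bias = mean(a - b); limits = bias ± 1.96 · SD(a - b) with the sample
    (n-1) standard deviation.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=bias, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd)


def icc(ratings: np.ndarray, kind: str = "average") -> float:
    """Absolute-agreement intraclass correlation from a two-way model.

    ``ratings`` is subjects x raters with no missing cells.  The two-way
    ANOVA decomposition gives mean squares for rows (MSR), columns (MSC)
    and error (MSE); the average-measures absolute-agreement coefficient
    (ICC(2,k)) is

        (MSR - MSE) / (MSR + (MSC - MSE) / n_subjects)

    ``kind='single'`` returns the single-measures variant ICC(2,1).
    Degenerate inputs (zero total variance) return NaN.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n_subjects x n_raters matrix, both >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings must not contain missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        return float("nan")
    if kind == "average":
        denom = msr + (msc - mse) / n
    elif kind == "single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError("kind must be 'average' or 'single'")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_2k(ratings: np.ndarray) -> float:
    """ICC(2,k): average-measures, absolute agreement (see :func:`icc`)."""
    return icc(ratings, kind="average")


def landmark_error(auto: LandmarkSet, reference: LandmarkSet) -> pd.DataFrame:
    """Per-name Euclidean distance (mm) between two landmark sets.

    Only names present in both sets are compared; none shared is an error.
    The returned frame has one row per landmark plus ``median``/``max``
    available via the usual DataFrame reductions.
    """
    names = [n for n in auto.names if n in reference]
    if not names:
        raise ValueError("landmark sets share no names")
    dist = [float(np.linalg.norm(auto[n].position - reference[n].position))
            for n in names]
    return pd.DataFrame({"name": names, "error_mm": dist})
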
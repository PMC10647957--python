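"""Registration quality metrics: landmark TRE, Dice, Jaccard, Hausdorff.

Landmarks live in physical units (mm = pixel coordinate x spacing); masks
are binary rasters aligned to their image.  The canonical landmark schema
is nine skull/midline/center points always present — up, dp, lp, rp
(extremal skull points), midd (falx cerebri), cntr (image center), B4,
B9, B0 (inner-skull points) — plus five tumor points (tmr1..tmr4 at the
tumor's extremes and ctmr at its center) present only for tumor cases.

Conventions fixed here (and relied on by the synthetic ground truth):
TRE aggregates per-landmark Euclidean distances by their mean; the
recovered affine forward-maps fixed-space landmarks into moving space,
where they are compared with the annotated moving landmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .spatial_transformer import AffineParams, ImageGrid

__all__ = [
    "SKULL_LANDMARKS",
    "TUMOR_LANDMARKS",
    "LandmarkSet",
    "SegmentationMask",
    "transform_landmarks",
    "tre",
    "dice",
    "jaccard",
    "hausdorff",
    "evaluate_pair",
]

SKULL_LANDMARKS = ("up", "dp", "lp", "rp", "midd", "cntr", "B4", "B9", "B0")
TUMOR_LANDMARKS = ("tmr1", "tmr2", "tmr3", "tmr4", "ctmr")
CANONICAL_LANDMARKS = SKULL_LANDMARKS + TUMOR_LANDMARKS


@dataclass
class LandmarkSet:
    """Named 2D points in mm, ordered (x=row-axis mm, y=col-axis mm)."""

    points: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, xy in self.points.items():
            if name not in CANONICAL_LANDMARKS:
                raise ValueError(
                    f"unknown landmark name {name!r}; expected one of "
                    f"{CANONICAL_LANDMARKS}"
                )
            clean[name] = (float(xy[0]), float(xy[1]))
        missing = [n for n in SKULL_LANDMARKS if n not in clean]
        if missing:
            raise ValueError(f"missing required skull/midline landmarks: {missing}")
        self.points = clean

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    @property
    def has_tumor(self) -> bool:
        return any(n in self.points for n in TUMOR_LANDMARKS)

    def as_array(self, names=None) -> np.ndarray:
        names = names or self.names
        return np.array([self.points[n] for n in names])


@dataclass
class SegmentationMask:
    """Binary raster aligned to an image; role is 'whole-brain' or 'tumor'."""

    mask: np.ndarray
    role: str = "whole-brain"
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.mask = arr.astype(bool)
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))


def _mask_of(m) -> np.ndarray:
    return m.mask if isinstance(m, SegmentationMask) else np.asarray(m).astype(bool)


def _spacing_of(m, spacing) -> tuple[float, float]:
    if spacing is not None:
        return (float(spacing[0]), float(spacing[1]))
    if isinstance(m, SegmentationMask):
        return m.spacing
    return (1.0, 1.0)


def transform_landmarks(lm: LandmarkSet, params: AffineParams,
                        image_shape: tuple[int, int],
                        spacing: tuple[float, float] = (1.0, 1.0)) -> LandmarkSet:
    """Forward-map landmarks through the centered affine the resampler uses.

    The resampler pulls: warped(x) = moving(A(x - c) + c + t).  The map
    from fixed-space to moving-space positions is therefore
    x -> A(x - c) + c + t, applied here in pixel coordinates (mm are
    converted in and back out through ``spacing``).
    """
    a = params.matrix
    t = params.translation
    c = (np.array(image_shape, dtype=np.float64) - 1.0) / 2.0
    sp = np.asarray(spacing, dtype=np.float64)
    out = {}
    for name, xy in lm.points.items():
        px = np.asarray(xy) / sp
        mapped = a @ (px - c) + c + t
        out[name] = tuple(mapped * sp)
    return LandmarkSet(out)


def tre(lm_a: LandmarkSet, lm_b: LandmarkSet) -> tuple[dict[str, float], float]:
    """Per-landmark Euclidean distances (mm) and their mean over shared names.

    Both sets must carry exactly the same landmark names.
    """
    missing = set(lm_a.names) ^ set(lm_b.names)
    if missing:
        raise ValueError(f"landmark name mismatch, unmatched names: {sorted(missing)}")
    per = {
        n: float(np.linalg.norm(np.array(lm_a.points[n]) - np.array(lm_b.points[n])))
        for n in lm_a.names
    }
    return per, float(np.mean(list(per.values())))


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) in [0, 1]; two empty masks score 1."""
    ma, mb = _mask_of(a), _mask_of(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    denom = ma.sum() + mb.sum()
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1", stacklevel=2)
        return 1.0
    return float(2.0 * np.logical_and(ma, mb).sum() / denom)


def jaccard(a, b) -> float:
    """Jaccard overlap |A∩B| / |A∪B| in [0, 1]; two empty masks score 1."""
    ma, mb = _mask_of(a), _mask_of(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        warnings.warn("both masks empty; Jaccard defined as 1", stacklevel=2)
        return 1.0
    return float(np.logical_and(ma, mb).sum() / union)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """8-connected boundary pixel coordinates of a binary mask."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    boundary = mask & ~eroded
    return np.argwhere(boundary)


def hausdorff(a, b, spacing: tuple[float, float] | None = None) -> float:
    """Symmetric Hausdorff distance (mm) between two masks' boundaries.

    Masks must be nonempty; pixel coordinates are scaled by ``spacing``
    (taken from the masks when omitted) before the max-min distance.
    """
    ma, mb = _mask_of(a), _mask_of(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    if ma.sum() == 0 or mb.sum() == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    sp = np.asarray(_spacing_of(a, spacing))
    pa = _boundary_points(ma) * sp
    pb = _boundary_points(mb) * sp
    return float(max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0]))


def evaluate_pair(fixed: ImageGrid, moving: ImageGrid, params: AffineParams,
                  lm_fixed: LandmarkSet, lm_moving: LandmarkSet,
                  mask_fixed=None, mask_moving_warped=None,
                  tumor_mask_fixed=None, tumor_mask_warped=None) -> dict:
    """Assemble one pair's metric record, pre- and post-registration.

    TRE-pre compares the annotated fixed and moving landmarks directly;
    TRE-post forward-maps the fixed landmarks through the recovered
    affine first.  Mask metrics compare the fixed mask against the
    moving mask before (``mask_fixed`` vs the moving-space mask) and
    after warping, when those masks are supplied.
    """
    if fixed.shape != moving.shape:
        raise ValueError(f"image shapes differ: {fixed.shape} vs {moving.shape}")
    spacing = fixed.spacing
    stratum = "tumor" if lm_fixed.has_tumor else "healthy"

    shared = [n for n in lm_fixed.names if n in lm_moving.names]
    lm_f = LandmarkSet({n: lm_fixed.points[n] for n in shared})
    lm_m = LandmarkSet({n: lm_moving.points[n] for n in shared})

    _, tre_pre = tre(lm_f, lm_m)
    mapped = transform_landmarks(lm_f, params, fixed.shape, spacing)
    per_post, tre_post = tre(mapped, lm_m)

    record = {
        "stratum": stratum,
        "tre_pre_mm": tre_pre,
        "tre_post_mm": tre_post,
        "tre_post_per_landmark_mm": per_post,
    }
    if mask_fixed is not None and mask_moving_warped is not None:
        record["dice_post"] = dice(mask_fixed, mask_moving_warped)
        record["jaccard_post"] = jaccard(mask_fixed, mask_moving_warped)
        if _mask_of(mask_fixed).sum() and _mask_of(mask_moving_warped).sum():
            record["hausdorff_post_mm"] = hausdorff(
                mask_fixed, mask_moving_warped, spacing
            )
    if tumor_mask_fixed is not None and tumor_mask_warped is not None:
        record["dice_tumor_post"] = dice(tumor_mask_fixed, tumor_mask_warped)
        record["jaccard_tumor_post"] = jaccard(tumor_mask_fixed, tumor_mask_warped)
    return record
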
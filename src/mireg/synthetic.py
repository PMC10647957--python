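"""Seeded multimodal brain-phantom generator with known ground truth.

Real CT/MR pairs with radiologist landmarks are private clinical data, so
every stage of this package is exercised on a synthetic stand-in: one
shared elliptical "anatomy" (skull ring, brain interior, ventricles, a
falx midline, optionally a tumor blob) rendered through two different
label-to-intensity maps whose orderings disagree — so the CT-like and
MR-like images are related by no linear (or even monotone) intensity
mapping, and mutual information rather than correlation carries the
alignment signal.  The moving image is the MR-like rendering resampled
through a known affine, which gives exact ground-truth parameters,
landmarks in both spaces, and masks in both spaces.

The generator is a pure function of its seed: identical seeds yield
byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .metrics import LandmarkSet, SegmentationMask
from .spatial_transformer import AffineParams, ImageGrid, affine_to_field, resample

__all__ = [
    "PhantomSpec",
    "AffineRanges",
    "GroundTruth",
    "render_anatomy",
    "apply_modality",
    "place_landmarks",
    "draw_affine",
    "make_pair",
    "make_corpus",
    "assign_splits",
]

# label codes of the rendered anatomy
BG, SKULL, BRAIN, VENTRICLE, FALX, TUMOR = 0, 1, 2, 3, 4, 5

# label -> intensity maps; deliberately differently *ordered* so the
# cross-modality relation is non-monotone (correlation-defeating)
_CT_LEVELS = {BG: 0.02, SKULL: 1.00, BRAIN: 0.30, VENTRICLE: 0.20, FALX: 0.40, TUMOR: 0.45}
_MR_LEVELS = {BG: 0.05, SKULL: 0.08, BRAIN: 0.65, VENTRICLE: 0.95, FALX: 0.50, TUMOR: 0.90}


@dataclass
class PhantomSpec:
    """Geometry + noise of one phantom; all lengths are fractions of size."""

    size: int = 128
    spacing: tuple[float, float] = (1.0, 1.0)
    skull_outer: tuple[float, float] = (0.42, 0.36)  # semi-axes (row, col)
    skull_thickness: float = 0.035
    ventricle_offset: float = 0.07  # lateral offset of each ventricle
    ventricle_axes: tuple[float, float] = (0.10, 0.035)
    ventricle_asymmetry: float = 1.15  # left/right size ratio (anatomy is not mirror-symmetric)
    texture_amplitude: float = 0.15  # gyral-like intra-brain modulation depth
    texture_freq: float = 3.0  # cycles across the image
    falx_length: float = 0.22  # anterior falx line length
    tumor: bool = False
    tumor_center: tuple[float, float] = (0.12, 0.10)  # offset from center
    tumor_axes: tuple[float, float] = (0.080, 0.060)
    noise_ct: float = 0.02
    noise_mr: float = 0.02
    smooth_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("phantom size must be >= 32")
        if max(self.skull_outer) >= 0.5 or (
            self.tumor
            and max(
                abs(self.tumor_center[0]) + self.tumor_axes[0],
                abs(self.tumor_center[1]) + self.tumor_axes[1],
            )
            >= min(self.skull_outer) - self.skull_thickness
        ):
            raise ValueError("phantom geometry does not fit inside the frame")


@dataclass
class AffineRanges:
    """Uniform draw bounds for ground-truth misalignments."""

    max_translation: float = 10.0  # pixels, each axis
    max_rotation_deg: float = 15.0
    scale: tuple[float, float] = (0.9, 1.1)
    max_shear: float = 0.05

    def identity(self) -> bool:
        return (
            self.max_translation == 0
            and self.max_rotation_deg == 0
            and self.scale == (1.0, 1.0)
            and self.max_shear == 0
        )


@dataclass
class GroundTruth:
    """Everything the private dataset's annotations would have provided."""

    params: AffineParams
    landmarks_fixed: LandmarkSet
    landmarks_moving: LandmarkSet
    mask_fixed: SegmentationMask
    mask_moving: SegmentationMask
    tumor_mask_fixed: SegmentationMask | None = None
    tumor_mask_moving: SegmentationMask | None = None


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def render_anatomy(spec: PhantomSpec) -> np.ndarray:
    """Integer label raster of the phantom anatomy; deterministic per spec."""
    s = spec.size
    c = ((s - 1) / 2.0, (s - 1) / 2.0)
    outer = (spec.skull_outer[0] * s, spec.skull_outer[1] * s)
    inner = (outer[0] - spec.skull_thickness * s, outer[1] - spec.skull_thickness * s)

    labels = np.full((s, s), BG, dtype=np.int64)
    labels[_ellipse((s, s), c, outer)] = SKULL
    brain = _ellipse((s, s), c, inner)
    labels[brain] = BRAIN

    for sign, asym in ((-1.0, spec.ventricle_asymmetry), (1.0, 1.0)):
        vc = (c[0], c[1] + sign * spec.ventricle_offset * s)
        labels[_ellipse((s, s), vc, (spec.ventricle_axes[0] * s * asym,
                                     spec.ventricle_axes[1] * s * asym)) & brain] = VENTRICLE

    r0 = int(round(c[0] - inner[0] + 0.04 * s))
    r1 = int(round(r0 + spec.falx_length * s))
    col = int(round(c[1]))
    falx = np.zeros((s, s), dtype=bool)
    falx[r0:r1, col] = True
    labels[falx & brain] = FALX

    if spec.tumor:
        tc = (c[0] + spec.tumor_center[0] * s, c[1] + spec.tumor_center[1] * s)
        tumor = _ellipse((s, s), tc, (spec.tumor_axes[0] * s, spec.tumor_axes[1] * s))
        if not (tumor <= brain).all():
            raise ValueError("tumor extends outside the brain region")
        labels[tumor] = TUMOR
    return labels


def apply_modality(labels: np.ndarray, modality: str, noise: float = 0.02,
                   seed: int = 0, smooth_sigma: float = 1.0,
                   spacing: tuple[float, float] = (1.0, 1.0),
                   texture_amplitude: float = 0.15,
                   texture_freq: float = 3.0) -> ImageGrid:
    """Render a label raster through one modality's intensity map + noise.

    A deterministic low-frequency "gyral" modulation is applied to the
    soft tissue inside the skull.  It is part of the shared anatomy —
    the same spatial pattern is rendered by both modalities — which is
    what makes the full linear part of a misalignment identifiable: on
    featureless ellipses, rotation is nearly degenerate with shear.
    """
    if modality == "ct-like":
        levels = _CT_LEVELS
    elif modality == "mr-like":
        levels = _MR_LEVELS
    else:
        raise ValueError(f"unknown modality {modality!r}; use 'ct-like' or 'mr-like'")
    img = np.zeros(labels.shape, dtype=np.float64)
    for lab, level in levels.items():
        img[labels == lab] = level
    if texture_amplitude > 0:
        s = labels.shape[0]
        rr, cc = np.meshgrid(np.arange(labels.shape[0]), np.arange(labels.shape[1]),
                             indexing="ij")
        pattern = np.sin(2 * np.pi * texture_freq * rr / s + 0.7) * np.sin(
            2 * np.pi * texture_freq * cc / s + 1.3
        )
        soft = (labels != BG) & (labels != SKULL)
        img[soft] *= 1.0 + texture_amplitude * pattern[soft]
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    if noise > 0:
        img += np.random.default_rng(seed).normal(0.0, noise, size=img.shape)
    return ImageGrid(img, spacing=spacing)


def background_level(modality: str) -> float:
    return (_CT_LEVELS if modality == "ct-like" else _MR_LEVELS)[BG]


def place_landmarks(labels: np.ndarray, spec: PhantomSpec) -> LandmarkSet:
    """Geometric stand-ins for the radiologist's 12-landmark schema.

    up/dp/lp/rp: extremal skull pixels; midd: falx centroid; cntr: image
    center; B0/B4/B9: top/right/left extremes of the inner-skull (brain)
    region; tmr1..tmr4: tumor extremes, ctmr: tumor centroid (the 1 mm
    tumor-center circle reduced to its center point).
    """
    sp = np.asarray(spec.spacing)

    def mm(rc):
        return (float(rc[0] * sp[0]), float(rc[1] * sp[1]))

    skull = np.argwhere(labels == SKULL)
    interior = np.argwhere((labels != BG) & (labels != SKULL))
    falx = np.argwhere(labels == FALX)
    if len(skull) == 0 or len(interior) == 0 or len(falx) == 0:
        raise ValueError("anatomy raster is missing skull, interior, or falx")

    def extreme(pts, axis, take_max):
        i = pts[:, axis].argmax() if take_max else pts[:, axis].argmin()
        level = pts[i, axis]
        other = pts[pts[:, axis] == level][:, 1 - axis].mean()
        return (float(level), float(other)) if axis == 0 else (float(other), float(level))

    c = ((labels.shape[0] - 1) / 2.0, (labels.shape[1] - 1) / 2.0)
    points = {
        "up": mm(extreme(skull, 0, False)),
        "dp": mm(extreme(skull, 0, True)),
        "lp": mm(extreme(skull, 1, False)),
        "rp": mm(extreme(skull, 1, True)),
        "midd": mm(falx.mean(axis=0)),
        "cntr": mm(c),
        "B0": mm(extreme(interior, 0, False)),
        "B4": mm(extreme(interior, 1, True)),
        "B9": mm(extreme(interior, 1, False)),
    }
    tumor = np.argwhere(labels == TUMOR)
    if spec.tumor:
        if len(tumor) == 0:
            raise ValueError("tumor landmarks requested but no tumor rendered")
        points.update(
            tmr1=mm(extreme(tumor, 0, False)),
            tmr2=mm(extreme(tumor, 0, True)),
            tmr3=mm(extreme(tumor, 1, True)),
            tmr4=mm(extreme(tumor, 1, False)),
            ctmr=mm(tumor.mean(axis=0)),
        )
    return LandmarkSet(points)


def draw_affine(ranges: AffineRanges, rng: np.random.Generator) -> AffineParams:
    """One uniform draw of a ground-truth misalignment within the bounds."""
    theta = np.radians(rng.uniform(-ranges.max_rotation_deg, ranges.max_rotation_deg))
    sr = rng.uniform(*ranges.scale)
    sc = rng.uniform(*ranges.scale)
    shear = rng.uniform(-ranges.max_shear, ranges.max_shear)
    t = rng.uniform(-ranges.max_translation, ranges.max_translation, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    sc_m = np.diag([sr, sc])
    a = rot @ sh @ sc_m
    return AffineParams(a[0, 0], a[0, 1], a[1, 0], a[1, 1], t[0], t[1])


def _warp_mask(mask: np.ndarray, inv_field: np.ndarray) -> np.ndarray:
    warped = resample(mask.astype(np.float64), inv_field, fill=0.0)
    return (warped >= 0.5).astype(np.int64)


def make_pair(spec: PhantomSpec, ranges: AffineRanges | None = None,
              seed: int | None = None) -> tuple[ImageGrid, ImageGrid, GroundTruth]:
    """One fixed (CT-like) / moving (misaligned MR-like) pair + ground truth.

    The moving image is the aligned MR-like rendering resampled through
    the *inverse* of the drawn affine, so that warping it back with the
    drawn parameters re-aligns it to the fixed image — i.e. the drawn
    parameters are exactly what a perfect registration should recover,
    and the moving-space landmarks are the forward-mapped fixed ones.
    """
    ranges = ranges or AffineRanges()
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    labels = render_anatomy(spec)
    fixed = apply_modality(labels, "ct-like", spec.noise_ct, seed * 3 + 1,
                           spec.smooth_sigma, spec.spacing,
                           spec.texture_amplitude, spec.texture_freq)
    mr_aligned = apply_modality(labels, "mr-like", spec.noise_mr, seed * 3 + 2,
                                spec.smooth_sigma, spec.spacing,
                                spec.texture_amplitude, spec.texture_freq)

    params = (AffineParams.identity() if ranges.identity()
              else draw_affine(ranges, rng))
    h, w = labels.shape
    inv_field = affine_to_field(params.invert(), h, w)
    moving = ImageGrid(
        resample(mr_aligned.pixels, inv_field, fill=background_level("mr-like")),
        spacing=spec.spacing,
    )

    lm_fixed = place_landmarks(labels, spec)
    from .metrics import transform_landmarks  # local import avoids cycle at module load

    lm_moving = transform_landmarks(lm_fixed, params, (h, w), spec.spacing)

    whole = (labels != BG).astype(np.int64)
    mask_fixed = SegmentationMask(whole, "whole-brain", spec.spacing)
    mask_moving = SegmentationMask(_warp_mask(whole, inv_field), "whole-brain",
                                   spec.spacing)
    tm_f = tm_m = None
    if spec.tumor:
        tumor = (labels == TUMOR).astype(np.int64)
        tm_f = SegmentationMask(tumor, "tumor", spec.spacing)
        tm_m = SegmentationMask(_warp_mask(tumor, inv_field), "tumor", spec.spacing)

    truth = GroundTruth(params, lm_fixed, lm_moving, mask_fixed, mask_moving,
                        tm_f, tm_m)
    return fixed, moving, truth


def assign_splits(n: int, fractions: tuple[float, float, float] = (6 / 11, 2 / 11, 3 / 11)
                  ) -> list[str]:
    """Deterministic train/val/test assignment by floor + leftover-to-front.

    Default fractions mirror a 60/20/30-of-110 patient split.  Counts are
    floor(n * fraction); leftover pairs go to train, then val, then test.
    """
    names = ("train", "val", "test")
    counts = [int(np.floor(n * f + 1e-9)) for f in fractions]
    i = 0
    while sum(counts) < n:
        counts[i % 3] += 1
        i += 1
    out: list[str] = []
    for name, k in zip(names, counts):
        out.extend([name] * k)
    return out[:n]


def make_corpus(n_pairs: int, tumor_fraction: float = 0.5,
                spec: PhantomSpec | None = None,
                ranges: AffineRanges | None = None, seed: int = 0,
                split: bool = True):
    """n seeded pairs with the stated tumor fraction, plus a manifest.

    Returns ``(pairs, manifest)`` where pairs is a list of
    ``(fixed, moving, truth)`` and manifest a pandas DataFrame with one
    row per pair (seed, stratum, split, true parameters).  Tumor pairs
    are the first ``round(n * fraction)`` by index; per-pair seeds are
    derived from the master seed so the corpus is reproducible
    byte-for-byte.
    """
    import pandas as pd

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    spec = spec or PhantomSpec()
    ranges = ranges or AffineRanges()
    n_tumor = int(round(n_pairs * tumor_fraction))
    splits = assign_splits(n_pairs) if split else ["train"] * n_pairs

    pairs = []
    rows = []
    for i in range(n_pairs):
        pair_seed = seed * 100003 + i
        pspec = replace(spec, tumor=i < n_tumor, seed=pair_seed)
        fixed, moving, truth = make_pair(pspec, ranges, seed=pair_seed)
        pairs.append((fixed, moving, truth))
        p = truth.params
        rows.append(
            {
                "pair_id": i,
                "seed": pair_seed,
                "stratum": "tumor" if pspec.tumor else "healthy",
                "split": splits[i],
                "a11": p.a11, "a12": p.a12, "a21": p.a21, "a22": p.a22,
                "tx": p.tx, "ty": p.ty,
            }
        )
    return pairs, pd.DataFrame(rows)
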
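"""Intensity normalization and the differentiable mutual-information loss.

Mutual information is the similarity metric of choice for CT/MR pairs
because the two modalities map the same tissue to unrelated intensity
ranges: MI rewards a *consistent* statistical relationship between the
intensities of overlapping pixels without assuming it is linear or even
monotone.

The classical estimator bins intensities into a joint histogram, which
has zero gradient almost everywhere.  Here each pixel pair instead
deposits its mass into neighbouring bins through a triangular (linear
B-spline) Parzen kernel, making the joint table — and hence MI — smooth
in the warped image's intensities, so the loss can supervise the
spatial transformer end to end.

    MI(F, M) = sum_{f,m} p(f,m) log[ p(f,m) / (p(f) p(m)) ]

with 0 log 0 = 0.  Logs are base 2 by default (MI in bits); 64 bins by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .spatial_transformer import ImageGrid

__all__ = [
    "NormalizationStats",
    "JointHistogram",
    "normalize",
    "soft_joint_histogram",
    "soft_histogram",
    "mutual_information",
    "entropy",
    "mi_loss",
    "MILossConfig",
]

_EPS = 1e-12


@dataclass
class NormalizationStats:
    """Mean/std used to standardize intensities; scope records their origin."""

    mean: float
    std: float
    scope: str = "per-image"  # or "per-modality-dataset"

    def __post_init__(self):
        if not np.isfinite(self.mean) or not np.isfinite(self.std):
            raise ValueError("normalization stats must be finite")
        if self.std <= 0:
            raise ValueError(f"std must be strictly positive, got {self.std}")

    @classmethod
    def from_image(cls, image) -> "NormalizationStats":
        pix = image.pixels if isinstance(image, ImageGrid) else np.asarray(image)
        std = float(pix.std())
        if std == 0.0:
            raise ValueError("constant image: std is zero, cannot normalize")
        return cls(mean=float(pix.mean()), std=std, scope="per-image")

    @classmethod
    def from_images(cls, images) -> "NormalizationStats":
        """Dataset-level stats pooled over all pixels of all images."""
        flat = np.concatenate(
            [
                (im.pixels if isinstance(im, ImageGrid) else np.asarray(im)).ravel()
                for im in images
            ]
        )
        std = float(flat.std())
        if std == 0.0:
            raise ValueError("constant dataset: std is zero, cannot normalize")
        return cls(mean=float(flat.mean()), std=std, scope="per-modality-dataset")


@dataclass
class JointHistogram:
    """Soft joint intensity probability table of a fixed/warped image pair."""

    probs: np.ndarray  # (n_bins, n_bins), sums to 1
    edges_fixed: np.ndarray  # (2,) intensity range spanned by the fixed bins
    edges_moving: np.ndarray
    bandwidth: float  # Parzen kernel half-width, in bin units

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise ValueError(f"probs must be square, got {self.probs.shape}")
        if np.any(self.probs < -1e-12):
            raise ValueError("joint histogram has negative entries")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"joint histogram must sum to 1, sums to {self.probs.sum()!r}"
            )

    @property
    def n_bins(self) -> int:
        return self.probs.shape[0]

    def marginal_fixed(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def marginal_moving(self) -> np.ndarray:
        return self.probs.sum(axis=0)


def normalize(image, stats: NormalizationStats | None = None):
    """Standardize intensities to zero mean / unit variance.

    When ``stats`` is omitted they are computed from the image itself
    (per-image scope); a constant image is rejected because its std is
    zero.
    """
    if stats is None:
        stats = NormalizationStats.from_image(image)
    if isinstance(image, ImageGrid):
        return ImageGrid((image.pixels - stats.mean) / stats.std, spacing=image.spacing)
    return (np.asarray(image, dtype=np.float64) - stats.mean) / stats.std


def _bin_positions(data: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Epsilon-widened intensity range so edge pixels stay inside the bins.

    A constant image maps onto the center of bin 0 (rather than splitting
    its mass between two middle bins)."""
    lo, hi = float(data.min()), float(data.max())
    span = hi - lo
    if span == 0.0:
        return lo, lo + 1.0
    pad = 1e-6 * span
    return lo - pad, hi + pad


def _soft_weights(values: Tensor, lo: float, hi: float, n_bins: int,
                  bandwidth: float) -> Tensor:
    """(n_pixels, n_bins) per-pixel-normalized triangular kernel weights.

    Each pixel's row sums to exactly 1: the raw triangular weights
    (half-width ``bandwidth`` in bin units) are divided by their sum, and
    a pixel falling outside every kernel's support (possible only for
    bandwidth < 1) is assigned wholly to its nearest bin.  At the default
    bandwidth of 1 the triangular kernels already form a partition of
    unity, so the normalization is a no-op; as the bandwidth shrinks the
    rows become one-hot nearest-bin assignments — the hard histogram.
    """
    scale = (n_bins - 1) / (hi - lo)
    u = (values - lo) * scale  # bin-unit coordinate in [0, n_bins-1]
    centers = np.arange(n_bins, dtype=np.float64)
    n = u.data.size
    dist = (u.reshape(n, 1) - centers).abs() * (1.0 / bandwidth)
    w = (1.0 - dist).relu()
    dead = w.data.sum(axis=1) < 1e-12
    if dead.any():
        onehot = np.zeros((n, n_bins))
        nearest = np.clip(np.rint(u.data.ravel()), 0, n_bins - 1).astype(int)
        onehot[dead, nearest[dead]] = 1.0
        w = w + onehot
    return w / w.sum(axis=1, keepdims=True)


def _joint_table(fixed, warped, n_bins: int, bandwidth: float):
    """Shared soft-binning core; returns (probs tensor, ranges)."""
    f = as_tensor(fixed.pixels if isinstance(fixed, ImageGrid) else fixed)
    m = as_tensor(warped.pixels if isinstance(warped, ImageGrid) else warped)
    if f.data.shape != m.data.shape:
        raise ValueError(
            f"image shapes differ: {f.data.shape} vs {m.data.shape}"
        )
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")

    lo_f, hi_f = _bin_positions(f.data, n_bins)
    lo_m, hi_m = _bin_positions(m.data, n_bins)
    n = f.data.size
    wf = _soft_weights(f.reshape(n), lo_f, hi_f, n_bins, bandwidth)
    wm = _soft_weights(m.reshape(n), lo_m, hi_m, n_bins, bandwidth)
    joint_t = Tensor._result(
        wf.data.T @ wm.data,
        [
            (wf, lambda g: (g @ wm.data.T).T),
            (wm, lambda g: wf.data @ g),
        ],
    )
    total = joint_t.sum()
    probs = joint_t / total
    return probs, (lo_f, hi_f), (lo_m, hi_m)


def soft_joint_histogram(fixed, warped, n_bins: int = 64,
                         bandwidth: float = 1.0) -> JointHistogram:
    """Parzen-window joint intensity histogram of a same-shape image pair.

    Each pixel pair contributes triangular-kernel weights (half-width
    ``bandwidth``, in bin units) to the neighbouring bins of both axes;
    the table is normalized to total mass 1.  As ``bandwidth`` shrinks and
    intensities sit at bin centers this converges to the hard-count joint
    histogram.
    """
    probs, ef, em = _joint_table(fixed, warped, n_bins, bandwidth)
    return JointHistogram(
        probs=probs.data,
        edges_fixed=np.array(ef),
        edges_moving=np.array(em),
        bandwidth=float(bandwidth),
    )


def mutual_information(hist: JointHistogram, base: float = 2.0) -> float:
    """MI of a joint probability table, in bits by default; >= 0."""
    p = hist.probs
    pf = hist.marginal_fixed()[:, None]
    pm = hist.marginal_moving()[None, :]
    mask = p > 0  # wherever p(f,m) > 0 both marginals are > 0
    terms = p[mask] * np.log(p[mask] / (pf * pm)[mask])
    return float(terms.sum() / np.log(base))


def soft_histogram(image, n_bins: int = 64, bandwidth: float = 1.0) -> np.ndarray:
    """Soft 1D intensity histogram (probabilities) of a single image."""
    arr = np.asarray(
        image.pixels if isinstance(image, ImageGrid) else image, dtype=np.float64
    )
    if n_bins < 2 or bandwidth <= 0:
        raise ValueError("n_bins must be >= 2 and bandwidth > 0")
    lo, hi = _bin_positions(arr, n_bins)
    w = _soft_weights(as_tensor(arr.ravel()), lo, hi, n_bins, bandwidth)
    return w.data.sum(axis=0) / arr.size


def entropy(image_or_marginal, n_bins: int = 64, bandwidth: float = 1.0,
            base: float = 2.0) -> float:
    """Shannon entropy of an image's soft intensity histogram (or of a
    probability vector passed directly)."""
    arr = np.asarray(
        image_or_marginal.pixels
        if isinstance(image_or_marginal, ImageGrid)
        else image_or_marginal,
        dtype=np.float64,
    )
    if arr.ndim == 1 and abs(arr.sum() - 1.0) < 1e-6:
        p = arr
    else:
        p = soft_histogram(arr, n_bins=n_bins, bandwidth=bandwidth)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


@dataclass
class MILossConfig:
    """Loss block of the run configuration."""

    n_bins: int = 64
    bandwidth: float = 1.0
    log_base: float = 2.0
    normalized: bool = False  # normalized MI: 2*MI / (H(F) + H(M))

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.bandwidth <= 0 or self.log_base <= 1:
            raise ValueError("bandwidth must be > 0 and log_base > 1")


def _mi_from_probs(probs: Tensor, base: float) -> Tensor:
    pf = probs.sum(axis=1, keepdims=True)
    pm = probs.sum(axis=0, keepdims=True)
    log_ratio = (probs + _EPS).log() - (pf @ pm + _EPS).log()
    return (probs * log_ratio).sum() * (1.0 / np.log(base))


def mi_loss(fixed, warped, config: MILossConfig | None = None):
    """Negated (optionally normalized) mutual information of a pair.

    Returns a scalar autodiff :class:`Tensor` when either input is a
    Tensor — the path used in training, where gradients flow through the
    warped intensities into the resampler and the affine parameters —
    and a plain float otherwise.
    """
    cfg = config or MILossConfig()
    probs, _, _ = _joint_table(fixed, warped, cfg.n_bins, cfg.bandwidth)
    mi = _mi_from_probs(probs, cfg.log_base)
    if cfg.normalized:
        pf = probs.sum(axis=1)
        pm = probs.sum(axis=0)
        hf = -(pf * (pf + _EPS).log()).sum() * (1.0 / np.log(cfg.log_base))
        hm = -(pm * (pm + _EPS).log()).sum() * (1.0 / np.log(cfg.log_base))
        mi = mi * 2.0 / (hf + hm + _EPS)
    loss = -mi
    if isinstance(fixed, Tensor) or isinstance(warped, Tensor):
        return loss
    return loss.item()
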
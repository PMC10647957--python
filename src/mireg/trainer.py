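"""Unsupervised end-to-end training and inference.

Training minimizes, over the localization network's weights θ,

    mean over pairs of  [ -MI(F, M ∘ T_μ) + λ R(field(μ)) ],   μ = g_θ(F, M)

with Adam — no ground-truth transforms anywhere.  The affine-to-field
layer makes the regularizer R possible: it acts on the dense displacement
field decoded from μ, not on the encrypted 6-vector itself.  Two field
regularizers are provided: mean squared displacement ("l2") and bending
energy ("bending", mean squared second finite differences).  Bending
energy vanishes identically on affine fields — its null space is exactly
the transform family being predicted — so it penalizes only decoding
pathologies while leaving every legitimate affine untouched.

Also here: ``register_pair`` (one-shot inference) and
``optimize_single_pair``, a network-free gradient ascent of MI over the
six parameters of one pair.  The latter doubles as the independent
oracle for the loss/transform stack and as a classical registration
baseline.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .autodiff import Adam, Tensor
from .localization_network import (
    NetworkConfig,
    NetworkParams,
    build_network,
    concatenate_pair,
    forward,
)
from .mi_loss import MILossConfig, NormalizationStats, mi_loss, normalize
from .spatial_transformer import (
    AffineParams,
    ImageGrid,
    affine_to_field,
    resample,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "field_regularizer",
    "train",
    "register_pair",
    "optimize_single_pair",
]

_IDENTITY = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 500
    batch_size: int = 4
    reg_kind: str = "bending"  # or "l2"
    reg_weight: float = 0.01
    seed: int = 0
    loss: MILossConfig = dc_field(default_factory=MILossConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.reg_weight < 0:
            raise ValueError("regularizer weight must be >= 0")
        if self.reg_kind not in ("bending", "l2"):
            raise ValueError(f"unknown regularizer kind {self.reg_kind!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = dc_field(default_factory=list)
    val_loss: list[float] = dc_field(default_factory=list)
    epoch_seconds: list[float] = dc_field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        data = {"epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "epoch_seconds": self.epoch_seconds}
        if self.val_loss:
            data["val_loss"] = self.val_loss
        return pd.DataFrame(data)


def field_regularizer(field, kind: str = "bending"):
    """Smoothness penalty on a displacement field; 0 for the identity.

    "l2": mean over pixels of the squared displacement magnitude.
    "bending": mean over pixels of the squared second finite differences
    (d_rr^2 + 2 d_rc^2 + d_cc^2, summed over the two vector components);
    affine fields lie exactly in its null space.  Differentiable: pass a
    Tensor to obtain a Tensor.
    """
    f = field if isinstance(field, Tensor) else Tensor(np.asarray(field, float))
    if f.data.ndim != 3 or f.data.shape[-1] != 2:
        raise ValueError(f"expected an (H, W, 2) field, got shape {f.data.shape}")
    if kind == "l2":
        out = (f**2.0).sum(axis=2).mean()
    elif kind == "bending":
        f_rr = f[2:, :, :] - 2.0 * f[1:-1, :, :] + f[:-2, :, :]
        f_cc = f[:, 2:, :] - 2.0 * f[:, 1:-1, :] + f[:, :-2, :]
        f_rc = (f[1:, 1:, :] - f[1:, :-1, :]) - (f[:-1, 1:, :] - f[:-1, :-1, :])
        out = (
            (f_rr**2.0).sum(axis=2).mean()
            + 2.0 * (f_rc**2.0).sum(axis=2).mean()
            + (f_cc**2.0).sum(axis=2).mean()
        )
    else:
        raise ValueError(f"unknown regularizer kind {kind!r}")
    return out if isinstance(field, Tensor) else out.item()


def _pair_arrays(corpus) -> tuple[list[np.ndarray], list[np.ndarray]]:
    fixed, moving = [], []
    for f, m in corpus:
        fa = f.pixels if isinstance(f, ImageGrid) else np.asarray(f, float)
        ma = m.pixels if isinstance(m, ImageGrid) else np.asarray(m, float)
        if fa.shape != ma.shape:
            raise ValueError(f"pair shapes differ: {fa.shape} vs {ma.shape}")
        fixed.append(fa)
        moving.append(ma)
    shapes = {a.shape for a in fixed}
    if len(shapes) != 1:
        raise ValueError(f"corpus images must share one shape, got {shapes}")
    return fixed, moving


def _pair_loss(net_out_row: Tensor, fixed_norm: np.ndarray, moving_norm: np.ndarray,
               cfg: TrainConfig) -> Tensor:
    """-MI + λR for one pair, as a scalar Tensor; gradients reach net_out_row."""
    h, w = fixed_norm.shape
    mu = net_out_row + _IDENTITY
    fld = affine_to_field(mu, h, w)
    warped = resample(Tensor(moving_norm), fld, fill=float(moving_norm.min()))
    loss = mi_loss(Tensor(fixed_norm), warped, cfg.loss)
    if cfg.reg_weight > 0:
        loss = loss + cfg.reg_weight * field_regularizer(fld, cfg.reg_kind)
    return loss


def train(corpus, net_cfg: NetworkConfig, cfg: TrainConfig,
          val_corpus=None, verbose: bool = False
          ) -> tuple[NetworkParams, TrainHistory]:
    """Unsupervised MI-driven training over a corpus of (fixed, moving) pairs.

    Images are standardized with dataset-level statistics per modality
    (all fixed images pool into one NormalizationStats, all moving into
    another) before being concatenated for the network.  Deterministic
    given ``cfg.seed``.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    fixed_raw, moving_raw = _pair_arrays(corpus)
    if fixed_raw[0].shape != net_cfg.input_size:
        raise ValueError(
            f"corpus image shape {fixed_raw[0].shape} does not match network "
            f"input_size {net_cfg.input_size}"
        )
    stats_f = NormalizationStats.from_images(fixed_raw)
    stats_m = NormalizationStats.from_images(moving_raw)
    fixed = [normalize(a, stats_f) for a in fixed_raw]
    moving = [normalize(a, stats_m) for a in moving_raw]
    pairs = [np.stack([f, m], axis=-1) for f, m in zip(fixed, moving)]

    val = None
    if val_corpus:
        vf, vm = _pair_arrays(val_corpus)
        val = [(normalize(a, stats_f), normalize(b, stats_m)) for a, b in zip(vf, vm)]

    rng = np.random.default_rng(cfg.seed)
    net = build_network(net_cfg, seed=cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()

    n = len(pairs)
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = np.stack([pairs[i] for i in idx])
            out = forward(net, batch)  # (B, 6) residuals
            losses = [
                _pair_loss(out[int(j)], fixed[i], moving[i], cfg)
                for j, i in enumerate(idx)
            ]
            total = losses[0]
            for term in losses[1:]:
                total = total + term
            total = total * (1.0 / len(losses))
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(total.item())
        history.train_loss.append(float(np.mean(epoch_losses)))
        if val is not None:
            vlosses = []
            for f, m in val:
                pair = np.stack([f, m], axis=-1)
                out = forward(net, pair)
                vlosses.append(_pair_loss(out, f, m, cfg).item())
            history.val_loss.append(float(np.mean(vlosses)))
        history.epoch_seconds.append(time.perf_counter() - t0)
        if verbose:
            msg = f"epoch {epoch:4d}  train {history.train_loss[-1]:+.4f}"
            if val is not None:
                msg += f"  val {history.val_loss[-1]:+.4f}"
            print(msg)
    return net, history


def register_pair(net: NetworkParams, fixed: ImageGrid, moving: ImageGrid
                  ) -> tuple[ImageGrid, AffineParams, np.ndarray]:
    """One-shot registration: a single forward pass, then warp.

    Normalization here is per-image (inference must work on a lone pair).
    The returned field is exactly ``affine_to_field(params)`` and the
    warped image exactly ``resample(moving, field)``, both on the
    *original* (un-normalized) moving intensities.
    """
    f = fixed.pixels if isinstance(fixed, ImageGrid) else np.asarray(fixed, float)
    m = moving.pixels if isinstance(moving, ImageGrid) else np.asarray(moving, float)
    if f.shape != m.shape:
        raise ValueError(f"pair shapes differ: {f.shape} vs {m.shape}")
    pair = concatenate_pair(f, m)
    from .localization_network import predict_affine

    params = predict_affine(net, pair)
    fld = affine_to_field(params, *f.shape)
    warped = resample(m, fld, fill=float(m.min()))
    spacing = fixed.spacing if isinstance(fixed, ImageGrid) else (1.0, 1.0)
    return ImageGrid(warped, spacing=spacing), params, fld


def _smooth_and_decimate(img: np.ndarray, sigma: float, step: int) -> np.ndarray:
    out = ndimage.gaussian_filter(img, sigma) if sigma > 0 else img
    return out[::step, ::step]


def _coarse_search(fixed: np.ndarray, moving: np.ndarray,
                   cfg: TrainConfig, max_shift: float,
                   max_rotation_deg: float) -> np.ndarray:
    """Deterministic coarse sweep at half resolution: translation grid,
    then rotation grid at the best translation, then a fine translation
    grid at the best rotation.  Returns a 6-parameter starting point."""
    f2 = _smooth_and_decimate(fixed, 1.0, 2)
    m2 = _smooth_and_decimate(moving, 1.0, 2)
    h, w = f2.shape
    fill = float(m2.min())

    def score(a11, a12, a21, a22, tr, tc):
        params = AffineParams(a11, a12, a21, a22, tr / 2.0, tc / 2.0)
        warped = resample(m2, affine_to_field(params, h, w), fill=fill)
        return mi_loss(f2, warped, cfg.loss)

    best, best_t = np.inf, np.zeros(2)
    shifts = np.arange(-max_shift, max_shift + 1e-9, 2.0)
    for tr in shifts:
        for tc in shifts:
            s = score(1, 0, 0, 1, tr, tc)
            if s < best:
                best, best_t = s, np.array([tr, tc])

    # rotation x per-axis scale, jointly: the two couple through the
    # elliptical anatomy, so a pure-rotation sweep can lock onto the
    # wrong angle
    best_lin = np.eye(2)
    for theta in np.radians(np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, 2.0)):
        ct, st = np.cos(theta), np.sin(theta)
        rot = np.array([[ct, -st], [st, ct]])
        for sr in (0.92, 1.0, 1.08):
            for sc in (0.92, 1.0, 1.08):
                lin = rot @ np.diag([sr, sc])
                s = score(lin[0, 0], lin[0, 1], lin[1, 0], lin[1, 1], *best_t)
                if s < best:
                    best, best_lin = s, lin

    for tr in best_t[0] + np.arange(-2.0, 2.0 + 1e-9, 1.0):
        for tc in best_t[1] + np.arange(-2.0, 2.0 + 1e-9, 1.0):
            s = score(best_lin[0, 0], best_lin[0, 1], best_lin[1, 0],
                      best_lin[1, 1], tr, tc)
            if s < best:
                best, best_t = s, np.array([tr, tc])

    return np.array([best_lin[0, 0], best_lin[0, 1], best_lin[1, 0],
                     best_lin[1, 1], best_t[0], best_t[1]])


# per-stage (decimation step, gaussian sigma at full res, Adam lr, iterations)
_STAGES = ((2, 1.5, 0.08, 120), (1, 0.5, 0.03, 50), (1, 0.0, 0.01, 30))
# residual scale: Adam steps of lr move linear entries by 0.02*lr, translations by lr
_RES_SCALE = np.array([0.02, 0.02, 0.02, 0.02, 1.0, 1.0])


def optimize_single_pair(fixed, moving, cfg: TrainConfig | None = None,
                         coarse_search: bool = True,
                         max_shift: float = 12.0,
                         max_rotation_deg: float = 18.0) -> AffineParams:
    """Network-free registration: gradient ascent of MI over the 6 parameters.

    From an identity start (optionally preceded by a deterministic coarse
    translation-and-rotation sweep at half resolution), Adam refines the
    parameters through a smoothed, coarse-to-fine schedule; the smoothing
    widens the MI basin so draws of up to ~15 degrees rotation and ~10 px
    translation stay inside the capture range.  Raises on a non-finite
    loss.
    """
    cfg = cfg or TrainConfig()
    f = normalize(fixed.pixels if isinstance(fixed, ImageGrid) else np.asarray(fixed, float))
    m = normalize(moving.pixels if isinstance(moving, ImageGrid) else np.asarray(moving, float))
    if f.shape != m.shape:
        raise ValueError(f"pair shapes differ: {f.shape} vs {m.shape}")

    res = Tensor(np.zeros(6), requires_grad=True)
    if coarse_search:
        start = _coarse_search(f, m, cfg, max_shift, max_rotation_deg)
        res.data[:] = (start - _IDENTITY) / _RES_SCALE

    for step, sigma, lr, iters in _STAGES:
        fs = _smooth_and_decimate(f, sigma, step)
        ms = _smooth_and_decimate(m, sigma, step)
        h, w = fs.shape
        # translations live in full-resolution pixels; rescale for this stage
        stage_scale = _RES_SCALE * np.array([1, 1, 1, 1, 1 / step, 1 / step])
        fill = float(ms.min())
        opt = Adam([res], lr=lr)
        for _ in range(iters):
            mu = res * stage_scale + _IDENTITY
            fld = affine_to_field(mu, h, w)
            warped = resample(Tensor(ms), fld, fill=fill)
            loss = mi_loss(Tensor(fs), warped, cfg.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"MI loss became non-finite at parameters "
                    f"{(res.data * _RES_SCALE + _IDENTITY)!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
    return AffineParams.from_array(res.data * _RES_SCALE + _IDENTITY)
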
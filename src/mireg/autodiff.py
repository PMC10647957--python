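"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the package's compute engine: every differentiable stage of the
registration pipeline (localization CNN, affine-to-field layer, bilinear
resampler, soft-histogram mutual information) is expressed as a graph of
:class:`Tensor` operations so that one call to :meth:`Tensor.backward`
yields exact gradients with respect to network weights and affine
parameters.

The op set is deliberately small — elementwise arithmetic, matmul,
reductions, slicing, a stride-``s`` "same"-padded 2D convolution and a
bilinear grid sampler — which keeps every backward rule short enough to be
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # list of (parent_tensor, fn mapping out-grad -> parent-grad)
        self._parents: list[tuple["Tensor", object]] = []

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _result(data, parents):
        parents = [(p, fn) for p, fn in parents if p.requires_grad]
        out = Tensor(data, requires_grad=bool(parents))
        out._parents = parents
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._result(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._result(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._result(
            self.data / other.data,
            [
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / other.data**2, other.data.shape
                    ),
                ),
            ],
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._result(
            self.data**e,
            [(self, lambda g: g * e * self.data ** (e - 1.0))],
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor._result(
            self.data @ other.data,
            [
                (self, lambda g: g @ other.data.swapaxes(-1, -2)),
                (other, lambda g: self.data.swapaxes(-1, -2) @ g),
            ],
        )

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._result(
            self.data.reshape(shape), [(self, lambda g: g.reshape(orig))]
        )

    def __getitem__(self, key):
        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return full

        return Tensor._result(self.data[key], [(self, back)])

    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            g = np.asarray(g)
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.data.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), [(self, back)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._result(out_data, [(self, lambda g: g * out_data)])

    def log(self):
        return Tensor._result(np.log(self.data), [(self, lambda g: g / self.data)])

    def abs(self):
        return Tensor._result(
            np.abs(self.data), [(self, lambda g: g * np.sign(self.data))]
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._result(self.data * mask, [(self, lambda g: g * mask)])

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor._result(self.data * factor, [(self, lambda g: g * factor)])

    # -- structured ops --------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 2) -> "Tensor":
        """Stride-``s`` 2D convolution with "same" output size ceil(n/s).

        ``self``: (N, H, W, Cin); ``weight``: (k, k, Cin, Cout); ``bias``:
        (Cout,).  Padding follows the convention that pads more on the
        bottom/right when the total is odd, so a 256 input halves to 128.
        """
        x = self.data
        n, h, w, cin = x.shape
        k = weight.data.shape[0]
        s = int(stride)
        oh, ow = -(-h // s), -(-w // s)
        ph = max((oh - 1) * s + k - h, 0)
        pw = max((ow - 1) * s + k - w, 0)
        pt, pl = ph // 2, pw // 2
        xp = np.pad(x, ((0, 0), (pt, ph - pt), (pl, pw - pl), (0, 0)))

        out = np.zeros((n, oh, ow, weight.data.shape[3]))
        for dy in range(k):
            for dx in range(k):
                patch = xp[:, dy : dy + s * oh : s, dx : dx + s * ow : s, :]
                out += patch @ weight.data[dy, dx]
        out += bias.data

        def back_x(g):
            dxp = np.zeros_like(xp)
            for dy in range(k):
                for dx in range(k):
                    dxp[:, dy : dy + s * oh : s, dx : dx + s * ow : s, :] += (
                        g @ weight.data[dy, dx].T
                    )
            return dxp[:, pt : pt + h, pl : pl + w, :]

        def back_w(g):
            dw = np.zeros_like(weight.data)
            for dy in range(k):
                for dx in range(k):
                    patch = xp[:, dy : dy + s * oh : s, dx : dx + s * ow : s, :]
                    dw[dy, dx] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
            return dw

        return Tensor._result(
            out,
            [
                (self, back_x),
                (weight, back_w),
                (bias, lambda g: g.sum(axis=(0, 1, 2))),
            ],
        )

    def grid_sample(self, coords: "Tensor", fill: float = 0.0) -> "Tensor":
        """Bilinearly sample a 2D image at per-pixel source coordinates.

        ``self``: image (H, W); ``coords``: (H, W, 2) in (row, col) pixel
        units.  Source positions outside the image blend toward ``fill``
        corner-wise, which keeps the output continuous (and differentiable)
        across the image border.
        """
        img = self.data
        h, w = img.shape
        r = coords.data[..., 0]
        c = coords.data[..., 1]
        r0 = np.floor(r).astype(np.int64)
        c0 = np.floor(c).astype(np.int64)
        fr = r - r0
        fc = c - c0

        corner_vals = []
        corner_info = []
        for dr in (0, 1):
            for dc in (0, 1):
                ri, ci = r0 + dr, c0 + dc
                valid = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
                v = np.where(
                    valid, img[np.clip(ri, 0, h - 1), np.clip(ci, 0, w - 1)], fill
                )
                wgt = (fr if dr else 1.0 - fr) * (fc if dc else 1.0 - fc)
                corner_vals.append((v, wgt))
                corner_info.append((ri, ci, valid, v, dr, dc))
        out = sum(v * wgt for v, wgt in corner_vals)

        def back_img(g):
            dimg = np.zeros_like(img)
            for (ri, ci, valid, _v, dr, dc), (_, wgt) in zip(corner_info, corner_vals):
                contrib = g * wgt
                np.add.at(
                    dimg,
                    (np.clip(ri, 0, h - 1)[valid], np.clip(ci, 0, w - 1)[valid]),
                    contrib[valid],
                )
            return dimg

        def back_coords(g):
            d_r = np.zeros_like(r)
            d_c = np.zeros_like(c)
            vals = {(i[4], i[5]): i[3] for i in corner_info}
            d_r += (1.0 - fc) * (vals[(1, 0)] - vals[(0, 0)]) + fc * (
                vals[(1, 1)] - vals[(0, 1)]
            )
            d_c += (1.0 - fr) * (vals[(0, 1)] - vals[(0, 0)]) + fr * (
                vals[(1, 1)] - vals[(1, 0)]
            )
            return np.stack([g * d_r, g * d_c], axis=-1)

        return Tensor._result(out, [(self, back_img), (coords, back_coords)])

    # -- backward pass ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every ancestor's ``.grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                pg = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


class Adam:
    """Adam optimizer over a list of leaf :class:`Tensor` parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
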
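"""Grid generation, the affine-to-field layer, and the bilinear resampler.

These three stages form the geometric half of the registration network:
the localization CNN emits six affine parameters, the affine-to-field
layer decrypts them into a dense per-pixel displacement field (so that
field-space regularizers can act on them), and the resampler warps the
moving image by pulling intensities from the displaced source positions.

Conventions, fixed once for the whole package:

* coordinates are 0-based and pixel-centered, ordered (row, col);
* displacement fields have shape ``(H, W, 2)`` with components ordered
  (row-displacement, col-displacement), in pixels;
* the linear part of an affine acts about the geometric image center by
  default (``center=True``), so rotations and scalings do not drag the
  anatomy off-frame;
* the resampler *pulls*: ``warped[x] = moving[x + field[x]]`` with
  bilinear interpolation and a constant fill outside the source frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "ImageGrid",
    "AffineParams",
    "make_identity_grid",
    "affine_to_field",
    "resample",
    "warp_with_affine",
]

IDENTITY_PARAMS = (1.0, 0.0, 0.0, 1.0, 0.0, 0.0)


@dataclass
class ImageGrid:
    """A 2D grayscale raster with physical spacing (mm/pixel, per axis)."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError(
                f"ImageGrid needs a 2D raster with every dimension >= 2, "
                f"got shape {self.pixels.shape}"
            )
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AffineParams:
    """The six scalars of a 2D affine map: linear part + pixel translation.

    Ordered (a11, a12, a21, a22, tx, ty) where the 2x2 block acts on
    (row, col) coordinates and (tx, ty) is the (row, col) translation in
    pixels.  The identity is (1, 0, 0, 1, 0, 0).
    """

    a11: float = 1.0
    a12: float = 0.0
    a21: float = 0.0
    a22: float = 1.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"affine parameters must be finite, got {vals}")
        if abs(self.a11 * self.a22 - self.a12 * self.a21) < 1e-12:
            raise ValueError("affine linear part is singular")

    def as_array(self) -> np.ndarray:
        return np.array([self.a11, self.a12, self.a21, self.a22, self.tx, self.ty])

    @classmethod
    def from_array(cls, arr) -> "AffineParams":
        arr = np.asarray(arr, dtype=np.float64).ravel()
        if arr.shape != (6,):
            raise ValueError(f"expected 6 affine parameters, got shape {arr.shape}")
        return cls(*arr)

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear block."""
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def invert(self) -> "AffineParams":
        """Parameters of the inverse map (about the same center convention)."""
        ainv = np.linalg.inv(self.matrix)
        tinv = -ainv @ self.translation
        return AffineParams(ainv[0, 0], ainv[0, 1], ainv[1, 0], ainv[1, 1], *tinv)

    def compose(self, other: "AffineParams") -> "AffineParams":
        """Map applying ``other`` first, then ``self`` (both center-anchored)."""
        a = self.matrix @ other.matrix
        t = self.matrix @ other.translation + self.translation
        return AffineParams(a[0, 0], a[0, 1], a[1, 0], a[1, 1], t[0], t[1])

    def rotation_deg(self) -> float:
        """Rotation angle of the polar decomposition of the linear block."""
        return float(
            np.degrees(np.arctan2(self.a21 - self.a12, self.a11 + self.a22))
        )


def make_identity_grid(height: int, width: int) -> np.ndarray:
    """Per-pixel source coordinates of the identity map, shape (H, W, 2).

    ``grid[i, j] == (i, j)`` exactly, in 0-based pixel coordinates.
    """
    if height < 1 or width < 1:
        raise ValueError(f"grid dimensions must be positive, got {height}x{width}")
    rows, cols = np.meshgrid(
        np.arange(height, dtype=np.float64),
        np.arange(width, dtype=np.float64),
        indexing="ij",
    )
    return np.stack([rows, cols], axis=-1)


def _check_params(params) -> np.ndarray | Tensor:
    if isinstance(params, AffineParams):
        return params.as_array()
    if isinstance(params, Tensor):
        if params.data.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {params.data.shape}")
        return params
    arr = np.asarray(params, dtype=np.float64).ravel()
    if arr.shape != (6,):
        raise ValueError(f"expected 6 parameters, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("affine parameters must be finite")
    return arr


def affine_to_field(params, height: int, width: int, center: bool = True):
    """Decrypt six affine parameters into a dense displacement field.

    With ``x`` the pixel coordinate and ``c`` the image center (or the
    origin when ``center=False``), the field is

        field[x] = A (x - c) + c + t - x ,

    shape ``(H, W, 2)``.  Accepts an :class:`AffineParams`, a plain
    6-vector, or an autodiff :class:`Tensor` of shape (6,); in the latter
    case the returned field is a Tensor and gradients flow to all six
    parameters.
    """
    if height < 2 or width < 2:
        raise ValueError(f"field dimensions must be >= 2, got {height}x{width}")
    p = _check_params(params)

    cr = (height - 1) / 2.0 if center else 0.0
    cc = (width - 1) / 2.0 if center else 0.0
    grid = make_identity_grid(height, width)
    rc = grid[..., 0] - cr  # centered row coordinate
    cc_ = grid[..., 1] - cc

    if isinstance(p, Tensor):
        dr = (p[0] - 1.0) * rc + p[1] * cc_ + p[4]
        dc = p[2] * rc + (p[3] - 1.0) * cc_ + p[5]
        h, w = rc.shape
        return (
            dr.reshape(h, w, 1) * np.array([1.0, 0.0])
            + dc.reshape(h, w, 1) * np.array([0.0, 1.0])
        )
    dr = (p[0] - 1.0) * rc + p[1] * cc_ + p[4]
    dc = p[2] * rc + (p[3] - 1.0) * cc_ + p[5]
    return np.stack([dr, dc], axis=-1)


def _as_pixels(image) -> np.ndarray | Tensor:
    if isinstance(image, ImageGrid):
        return image.pixels
    if isinstance(image, Tensor):
        return image
    return np.asarray(image, dtype=np.float64)


def resample(moving, field, fill: float = 0.0):
    """Warp ``moving`` by a displacement field: out[x] = moving[x + field[x]].

    Bilinear interpolation; source positions outside the frame blend toward
    the constant ``fill``.  Works on numpy arrays / :class:`ImageGrid`
    (returns the same kind) or on autodiff Tensors (returns a Tensor with
    gradients flowing to both the field and the image intensities).
    """
    pix = _as_pixels(moving)
    fld = field if isinstance(field, Tensor) else np.asarray(field, dtype=np.float64)
    pix_shape = pix.shape if not isinstance(pix, Tensor) else pix.data.shape
    fld_shape = fld.shape if not isinstance(fld, Tensor) else fld.data.shape
    if fld_shape != pix_shape + (2,):
        raise ValueError(
            f"field shape {fld_shape} does not match image shape {pix_shape}"
        )

    grid = make_identity_grid(*pix_shape)
    coords = as_tensor(fld) + grid
    out = as_tensor(pix).grid_sample(coords, fill=fill)

    if isinstance(moving, Tensor) or isinstance(field, Tensor):
        return out
    if isinstance(moving, ImageGrid):
        return ImageGrid(out.data, spacing=moving.spacing)
    return out.data


def warp_with_affine(moving, params, center: bool = True, fill: float = 0.0):
    """Apply an affine transform to an image: resample over its decrypted field."""
    pix = _as_pixels(moving)
    shape = pix.shape if not isinstance(pix, Tensor) else pix.data.shape
    fld = affine_to_field(params, shape[0], shape[1], center=center)
    return resample(moving, fld, fill=fill)
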
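"""Readers and writers for the package's on-disk formats.

Images: NIfTI-1 (``.nii``/``.nii.gz``, spacing from the header) or PNG
(spacing defaults to 1 mm/px with a warning).  Landmarks: CSV with
columns ``name,x_mm,y_mm`` validated against the canonical schema.
Affine parameters: a 6-value JSON record in the order
(a11, a12, a21, a22, tx, ty).  Displacement fields: NPZ.

Physical-coordinate policy, applied package-wide: transforms operate in
pixels, metrics in mm, and the conversion happens exactly once — at the
landmark/metric boundary — using the image header's spacing.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .metrics import CANONICAL_LANDMARKS, LandmarkSet, SKULL_LANDMARKS
from .spatial_transformer import AffineParams, ImageGrid

__all__ = [
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "read_affine",
    "write_affine",
    "read_field",
    "write_field",
]

_PARAM_ORDER = ("a11", "a12", "a21", "a22", "tx", "ty")


def read_image(path, slice_index: int | None = None) -> ImageGrid:
    """Load a NIfTI or PNG image as a float ImageGrid.

    3D NIfTI volumes require ``slice_index`` (taken along the last axis,
    mirroring slice-based acquisition); PNGs carry no spacing and default
    to 1 mm/px with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        zooms = img.header.get_zooms()
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                raise IOError(
                    f"{path} is a 3D volume; pass slice_index to pick a slice"
                )
            data = data[..., int(slice_index)]
        elif data.ndim != 2:
            raise IOError(f"{path}: unsupported dimensionality {data.ndim}")
        return ImageGrid(data, spacing=(float(zooms[0]), float(zooms[1])))
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path), dtype=np.float64)
        if data.ndim == 3:  # collapse color/alpha channels
            data = data[..., :3].mean(axis=-1)
        warnings.warn(
            f"{path.name}: PNG carries no spacing; assuming 1 mm/pixel",
            stacklevel=2,
        )
        return ImageGrid(data, spacing=(1.0, 1.0))
    raise IOError(f"unsupported image format: {path} (use .nii, .nii.gz or .png)")


def write_image(image: ImageGrid, path) -> None:
    """Write NIfTI (float, spacing in the affine) or PNG (16-bit, [0,1] range)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.astype(np.float64), affine), str(path))
        return
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        scaled = np.clip(image.pixels, 0.0, 1.0) * 65535.0
        iio.imwrite(path, scaled.round().astype(np.uint16))
        return
    raise IOError(f"unsupported image format: {path}")


def read_landmarks(path) -> LandmarkSet:
    """CSV with header name,x_mm,y_mm; validated against the canonical names."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise IOError(f"landmark file not found: {path}")
    df = pd.read_csv(path)
    required = {"name", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    names = list(df["name"])
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate landmark names {dupes}")
    unknown = sorted(set(names) - set(CANONICAL_LANDMARKS))
    if unknown:
        raise ValueError(
            f"{path}: unknown landmark names {unknown}; "
            f"canonical names are {CANONICAL_LANDMARKS}"
        )
    return LandmarkSet(
        {row.name: (row.x_mm, row.y_mm) for row in df.itertuples(index=False)}
    )


def write_landmarks(lm: LandmarkSet, path) -> None:
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"name": n, "x_mm": xy[0], "y_mm": xy[1]} for n, xy in lm.points.items()]
    ).to_csv(path, index=False)


def write_affine(params: AffineParams, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps({k: getattr(params, k) for k in _PARAM_ORDER}, indent=2) + "\n"
    )


def read_affine(path) -> AffineParams:
    payload = json.loads(Path(path).read_text())
    return AffineParams(**{k: float(payload[k]) for k in _PARAM_ORDER})


def write_field(field: np.ndarray, path, spacing=(1.0, 1.0)) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, field=np.asarray(field), spacing=np.asarray(spacing))


def read_field(path) -> np.ndarray:
    with np.load(Path(path)) as data:
        return data["field"]
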
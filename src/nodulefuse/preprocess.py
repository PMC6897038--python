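"""Patch loading, intensity normalisation and resizing.

Every consumer of a patch declares its own working size: the hand-crafted
descriptors operate on 28x28 patches, the convolutional network on 50x50.
Loading maps any supported source (8/16-bit PNG or TIFF, single-frame DICOM)
onto a float grid in [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skimage.transform import resize as _skimage_resize


class PatchIOError(IOError):
    """Raised when a patch file cannot be read as a 2-D grayscale image."""


def _normalize_integer(img: np.ndarray) -> np.ndarray:
    info = np.iinfo(img.dtype)
    return img.astype(np.float64) / float(info.max)


def _normalize_minmax(img: np.ndarray) -> np.ndarray:
    img = img.astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        # degenerate range: defined as all zeros
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def load_patch(path: str | Path, format: str | None = None) -> np.ndarray:
    """Load a 2-D grayscale patch with intensities rescaled to [0, 1].

    Integer PNG/TIFF pixels are divided by the dtype maximum (so an 8-bit
    value of 255 maps to exactly 1.0); float images and DICOM slices (after
    applying rescale slope/intercept) are min-max normalised over the patch,
    with a degenerate (constant) range mapping to all zeros.

    Parameters
    ----------
    path : file path
    format : {"png", "tiff", "dicom"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"png": "png", "tif": "tiff", "tiff": "tiff",
                  "dcm": "dicom", "dicom": "dicom"}.get(suffix)
        if format is None:
            raise PatchIOError(f"cannot infer format of {path}")

    if format == "dicom":
        import pydicom

        try:
            ds = pydicom.dcmread(str(path), force=True)
            img = ds.pixel_array.astype(np.float64)
        except Exception as exc:  # pragma: no cover - backend-specific messages
            raise PatchIOError(f"unreadable DICOM file {path}: {exc}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        img = img * slope + intercept
        if img.ndim != 2:
            raise PatchIOError(f"{path}: expected a single-frame 2-D slice, got shape {img.shape}")
        return _normalize_minmax(img)

    import imageio.v3 as iio

    try:
        img = np.asarray(iio.imread(path))
    except Exception as exc:
        raise PatchIOError(f"unreadable image file {path}: {exc}") from exc
    if img.ndim == 3 and img.shape[2] in (3, 4):
        # tolerate RGB(A) sources: collapse to luminance
        img = img[..., :3].mean(axis=2).astype(img.dtype)
    if img.ndim != 2:
        raise PatchIOError(f"{path}: expected a 2-D grayscale image, got shape {img.shape}")
    if np.issubdtype(img.dtype, np.integer):
        return _normalize_integer(img)
    return _normalize_minmax(img)


def resize(patch: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize of a 2-D patch to ``target`` x ``target``.

    Constant patches are preserved exactly and the output range never
    exceeds the input range.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ValueError(f"expected a 2-D patch, got shape {patch.shape}")
    if target < 2:
        raise ValueError(f"target size must be >= 2, got {target}")
    if patch.shape == (target, target):
        return patch.copy()
    if patch.max() == patch.min():
        return np.full((target, target), patch.flat[0])
    out = _skimage_resize(patch, (target, target), order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
    return np.clip(out, patch.min(), patch.max())
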
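"""Grayscale image I/O: PNG/TIFF/PGM in, PNG/PGM/TIFF out.

Integer images are rescaled to [0, 1] by their bit-depth maximum; RGB(A)
input collapses to luma with the BT.601 weights 0.2989 / 0.5870 / 0.1140.
Writing quantizes with round-half-up, so a write/read round trip is exact
to within one quantization step.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .ci_filter import as_gray_image

__all__ = ["read_gray", "write_gray", "write_labels"]

_LUMA = np.array([0.2989, 0.5870, 0.1140])


def read_gray(path: str | Path) -> np.ndarray:
    """Read an image file as a [0, 1] float grayscale array."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise IOError(f"cannot read image {path} ({path.suffix or 'no ext'}): {exc}")
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise IOError(f"unsupported channel count {arr.shape[2]} in {path}")
        arr = arr[..., :3] @ _LUMA
        scale = _dtype_max(raw.dtype)
        return np.clip(arr / scale, 0.0, 1.0)
    if arr.ndim != 2:
        raise IOError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if np.issubdtype(arr.dtype, np.floating):
        return as_gray_image(np.clip(arr, 0.0, 1.0))
    return arr.astype(np.float64) / _dtype_max(arr.dtype)


def _dtype_max(dtype: np.dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 1.0


def write_gray(image: np.ndarray, path: str | Path, depth: int = 8) -> Path:
    """Write a [0, 1] image quantized to 8 or 16 bits (round-half-up)."""
    if depth not in (8, 16):
        raise ValueError("depth must be 8 or 16")
    arr = as_gray_image(image)
    maxval = 2**depth - 1
    q = np.floor(arr * maxval + 0.5)  # round-half-up
    out = q.astype(np.uint8 if depth == 8 else np.uint16)
    path = Path(path)
    try:
        iio.imwrite(path, out)
    except Exception as exc:  # pragma: no cover
        raise IOError(f"cannot write image {path}: {exc}")
    return path


def write_labels(
    labels: np.ndarray, path: str | Path, colormap: str | None = None
) -> Path:
    """Write a label map as an 8-bit PNG of class indices.

    With ``colormap`` set (a matplotlib colormap name) an RGB rendering is
    written instead, classes spread over the colormap range.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    if labels.max() > 255:
        raise ValueError("more than 256 classes cannot be stored as 8-bit PNG")
    path = Path(path)
    if colormap is None:
        iio.imwrite(path, labels.astype(np.uint8))
        return path
    import matplotlib

    cmap = matplotlib.colormaps[colormap]
    k = max(int(labels.max()), 1)
    rgb = (cmap(labels.astype(float) / k)[..., :3] * 255).astype(np.uint8)
    iio.imwrite(path, rgb)
    return path
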
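"""Synthetic phantoms and noise models for segmentation stress-tests.

Speckle is modelled multiplicatively, ``J = I + u * I``, with ``u`` an
i.i.d. zero-mean uniform multiplier of a chosen variance (the convention
of the classic ``imnoise``-style speckle generator); a Gaussian multiplier
is available as an option.  Additive Gaussian noise is ``J = I + g``.
Both results are clipped to [0, 1] after corruption; moment checks in the
test-suite use the pre-clip statistics.

Phantoms are piecewise-constant images: a background plus non-overlapping
rectangles and discs, one intensity level per class, levels evenly spaced
in [0.1, 0.9], with the ground-truth class map returned alongside.  They
emulate the piecewise-homogeneous structure of the infrared/medical test
scenes this kind of filter is aimed at, not their texture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ci_filter import as_gray_image

__all__ = [
    "NoiseParams",
    "PhantomTruth",
    "add_speckle",
    "add_gaussian",
    "apply_noise",
    "make_phantom",
    "DEFAULT_SPECKLE_VARIANCE",
]

# Default multiplier variance: on the default 4-class 256x256 phantom this
# produces a post-noise image standard deviation of about 0.26, within the
# 0.15-0.27 range typical of the speckle-contaminated scenes the filter
# targets.
DEFAULT_SPECKLE_VARIANCE = 0.30


@dataclass(frozen=True)
class NoiseParams:
    """Noise description: kind, variance, (Gaussian) mean and seed."""

    kind: Literal["speckle", "gaussian"]
    variance: float
    mean: float = 0.0
    seed: int | None = None
    multiplier: Literal["uniform", "gaussian"] = "uniform"

    def __post_init__(self) -> None:
        if self.kind not in ("speckle", "gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.multiplier not in ("uniform", "gaussian"):
            raise ValueError(f"unknown multiplier law {self.multiplier!r}")


def _rng(params: NoiseParams) -> np.random.Generator:
    return np.random.default_rng(params.seed)


def add_speckle(
    image: np.ndarray, params: NoiseParams, clip: bool = True
) -> np.ndarray:
    """Multiplicative speckle: ``J = I + u * I`` with Var(u) = variance.

    ``u`` is zero-mean uniform on [-sqrt(3 v), +sqrt(3 v)] by default, or
    zero-mean Gaussian when ``params.multiplier == "gaussian"``.  Output is
    clipped to [0, 1] unless ``clip=False``.  Seeded and reproducible.
    """
    if params.kind != "speckle":
        raise ValueError("params.kind must be 'speckle'")
    arr = as_gray_image(image)
    rng = _rng(params)
    if params.multiplier == "uniform":
        half = np.sqrt(3.0 * params.variance)
        u = rng.uniform(-half, half, size=arr.shape)
    else:
        u = rng.normal(0.0, np.sqrt(params.variance), size=arr.shape)
    out = arr + u * arr
    return np.clip(out, 0.0, 1.0) if clip else out


def add_gaussian(
    image: np.ndarray, params: NoiseParams, clip: bool = True
) -> np.ndarray:
    """Additive Gaussian noise ``J = I + g``, g ~ N(mean, variance)."""
    if params.kind != "gaussian":
        raise ValueError("params.kind must be 'gaussian'")
    arr = as_gray_image(image)
    g = _rng(params).normal(params.mean, np.sqrt(params.variance), size=arr.shape)
    out = arr + g
    return np.clip(out, 0.0, 1.0) if clip else out


def apply_noise(image: np.ndarray, params: NoiseParams) -> np.ndarray:
    """Dispatch on ``params.kind``."""
    if params.kind == "speckle":
        return add_speckle(image, params)
    return add_gaussian(image, params)


@dataclass(frozen=True)
class PhantomTruth:
    """A synthetic piecewise-constant image with its ground-truth labels."""

    image: np.ndarray
    labels: np.ndarray
    levels: tuple[float, ...]


def make_phantom(
    height: int = 256,
    width: int = 256,
    n_classes: int = 4,
    seed: int | None = None,
    max_tries: int = 200,
) -> PhantomTruth:
    """Piecewise-constant phantom with one shape per non-background class.

    The background carries the lowest level; classes 1..K-1 are randomly
    placed, pairwise non-overlapping rectangles or discs.  Levels are
    evenly spaced in [0.1, 0.9], so every pair of classes is separable by
    intensity.  Raises ``RuntimeError`` when a shape cannot be placed
    within ``max_tries`` attempts.
    """
    if not 2 <= n_classes <= 8:
        raise ValueError("n_classes must be in [2, 8]")
    if height < 8 or width < 8:
        raise ValueError("phantom must be at least 8x8")
    rng = np.random.default_rng(seed)
    levels = tuple(np.linspace(0.1, 0.9, n_classes))
    labels = np.zeros((height, width), dtype=np.uint8)
    occupied = np.zeros((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width]
    lo_frac, hi_frac = 0.12, 0.35
    for k in range(1, n_classes):
        placed = False
        for _ in range(max_tries):
            if rng.random() < 0.5:  # rectangle
                h = int(rng.integers(max(2, int(lo_frac * height)),
                                     max(3, int(hi_frac * height))))
                w = int(rng.integers(max(2, int(lo_frac * width)),
                                     max(3, int(hi_frac * width))))
                r0 = int(rng.integers(0, height - h + 1))
                c0 = int(rng.integers(0, width - w + 1))
                mask = np.zeros((height, width), dtype=bool)
                mask[r0 : r0 + h, c0 : c0 + w] = True
            else:  # disc
                rad = int(rng.integers(max(2, int(lo_frac * min(height, width) / 2)),
                                       max(3, int(hi_frac * min(height, width) / 2))))
                cy = int(rng.integers(rad, height - rad))
                cx = int(rng.integers(rad, width - rad))
                mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad * rad
            if not (mask & occupied).any():
                labels[mask] = k
                occupied |= mask
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place shape for class {k} in {max_tries} tries"
            )
    image = np.asarray(levels, dtype=np.float64)[labels]
    return PhantomTruth(image=image, labels=labels, levels=levels)
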
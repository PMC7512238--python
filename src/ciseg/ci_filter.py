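"""Tile-wise confidence-interval pre-filter for noisy grayscale images.

The filter treats every pixel intensity as a point-wise datum.  It computes
the population standard deviation ``sigma`` of the whole image, partitions
the image into rectangular tiles (sub-images), and inside each tile builds
the normal-theory confidence band for the population mean,

    x_bar - z * sigma / sqrt(n)  <  mu  <  x_bar + z * sigma / sqrt(n),

where ``x_bar`` is the tile sample mean, ``n`` the tile sample size and
``z`` the standard-normal critical value (1.96 at 95% confidence).  Pixels
strictly inside their tile's band are kept; pixels outside are replaced by
the tile's representative statistic (the mean by default, optionally the
tile minimum or maximum).  The filtered tiles are recomposed into an image
of the original shape.

All statistics are computed once from the *original* image; replacements
never feed back into ``sigma`` or the tile means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "TileSpec",
    "TileGrid",
    "TileStats",
    "CIBand",
    "FilterParams",
    "as_gray_image",
    "global_std",
    "make_tile_grid",
    "tile_mean",
    "ci_band",
    "apply_ci_filter",
    "pipeline_segment",
]

Rect = tuple[int, int, int, int]  # (row0, col0, height, width)


def as_gray_image(image: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D float64 intensity image in [0, 1].

    Raises ``ValueError`` for empty, non-2-D, non-finite or out-of-range
    input.  Integer arrays are *not* rescaled here; use
    :func:`ciseg.imgio.read_gray` for files.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class TileSpec:
    """Nominal tile (sub-image) shape: ``ia`` rows by ``ja`` columns."""

    ia: int = 8
    ja: int = 8

    def __post_init__(self) -> None:
        if self.ia < 1 or self.ja < 1:
            raise ValueError("tile dimensions must be >= 1")

    @property
    def n(self) -> int:
        """Nominal tile sample size ``n = ia * ja``."""
        return self.ia * self.ja


@dataclass(frozen=True)
class TileGrid:
    """Row-major partition of an image into disjoint covering rectangles."""

    height: int
    width: int
    spec: TileSpec
    tiles: tuple[Rect, ...]

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def __iter__(self) -> Iterator[Rect]:
        return iter(self.tiles)


@dataclass(frozen=True)
class TileStats:
    mean: float
    n_actual: int


@dataclass(frozen=True)
class CIBand:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("band lower edge exceeds upper edge")


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the confidence-interval filter.

    ``z`` defaults to the literal 1.96 two-sided 95% critical value.  If
    ``confidence`` is set explicitly and ``z`` is left as None, ``z`` is
    derived from the standard-normal quantile (or Student-t with
    ``tile.n - 1`` degrees of freedom when ``use_t`` is enabled — a
    small-sample extension that is off by default).

    ``band_n`` selects the sample size used in the band half-width for
    ragged edge tiles: ``"nominal"`` always uses ``ia * ja`` (the literal
    formula), ``"actual"`` uses the true pixel count of the tile.
    ``sigma_ddof`` selects population (0, default) or sample (1) standard
    deviation.
    """

    tile: TileSpec = field(default_factory=TileSpec)
    z: float | None = None
    confidence: float | None = None
    replacement: Literal["mean", "min", "max"] = "mean"
    band_n: Literal["nominal", "actual"] = "nominal"
    use_t: bool = False
    sigma_ddof: int = 0

    def __post_init__(self) -> None:
        if self.z is not None and self.z <= 0:
            raise ValueError("z must be positive")
        if self.confidence is not None and not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if self.replacement not in ("mean", "min", "max"):
            raise ValueError(f"unknown replacement policy {self.replacement!r}")
        if self.band_n not in ("nominal", "actual"):
            raise ValueError(f"unknown band_n mode {self.band_n!r}")
        if self.sigma_ddof not in (0, 1):
            raise ValueError("sigma_ddof must be 0 or 1")

    def resolve_z(self, n: int | None = None) -> float:
        """Critical-value multiplier actually used in the band."""
        if self.z is not None:
            return self.z
        if self.confidence is None:
            return 1.96
        upper = (1.0 + self.confidence) / 2.0
        if self.use_t:
            df = (n if n is not None else self.tile.n) - 1
            if df < 1:
                raise ValueError("Student-t band needs tile sample size >= 2")
            return float(_stats.t.ppf(upper, df))
        return float(_stats.norm.ppf(upper))


def global_std(image: np.ndarray, ddof: int = 0) -> float:
    """Standard deviation of the entire image population.

    Every pixel is a point-wise datum; ``ddof=0`` (the default) gives the
    population (divide-by-N) form, ``ddof=1`` the sample form.
    """
    arr = as_gray_image(image)
    return float(arr.std(ddof=ddof))


def make_tile_grid(height: int, width: int, tile: TileSpec) -> TileGrid:
    """Partition a ``height x width`` image into row-major tiles.

    Interior tiles have the nominal ``ia x ja`` shape; the last row/column
    of tiles absorbs any remainder and may be smaller.  A tile larger than
    the image yields a single whole-image tile.
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be >= 1")
    tiles: list[Rect] = []
    for r0 in range(0, height, tile.ia):
        h = min(tile.ia, height - r0)
        for c0 in range(0, width, tile.ja):
            w = min(tile.ja, width - c0)
            tiles.append((r0, c0, h, w))
    return TileGrid(height=height, width=width, spec=tile, tiles=tuple(tiles))


def tile_mean(image: np.ndarray, rect: Rect) -> TileStats:
    """Sample mean and pixel count of one tile of ``image``."""
    arr = as_gray_image(image)
    r0, c0, h, w = rect
    if r0 < 0 or c0 < 0 or h < 1 or w < 1:
        raise ValueError(f"invalid tile rectangle {rect}")
    if r0 + h > arr.shape[0] or c0 + w > arr.shape[1]:
        raise ValueError(f"tile rectangle {rect} exceeds image shape {arr.shape}")
    block = arr[r0 : r0 + h, c0 : c0 + w]
    return TileStats(mean=float(block.mean()), n_actual=block.size)


def ci_band(stats: TileStats, sigma: float, params: FilterParams) -> CIBand:
    """Normal-theory confidence band for the tile population mean.

    Half-width is ``z * sigma / sqrt(n)`` with ``n`` the nominal or actual
    tile size per ``params.band_n``; the band is symmetric about the tile
    mean.  A zero ``sigma`` degenerates to the point band (mean, mean).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    n = params.tile.n if params.band_n == "nominal" else stats.n_actual
    half = params.resolve_z(n) * sigma / math.sqrt(n)
    return CIBand(lo=stats.mean - half, hi=stats.mean + half)


def _replacement_value(block: np.ndarray, mean: float, policy: str) -> float:
    if policy == "mean":
        return mean
    if policy == "min":
        return float(block.min())
    return float(block.max())


def apply_ci_filter(
    image: np.ndarray,
    params: FilterParams | None = None,
    return_stats: bool = False,
):
    """Run the confidence-interval filter over the whole image.

    Single pass: ``sigma`` and all tile means come from the original image.
    Each pixel strictly inside its tile's band is kept; every other pixel
    becomes the tile's replacement statistic.  With ``return_stats=True``
    also returns a dict with ``sigma``, ``n_tiles`` and the fraction of
    pixels kept unchanged.
    """
    if params is None:
        params = FilterParams()
    arr = as_gray_image(image)
    sigma = global_std(arr, ddof=params.sigma_ddof)
    grid = make_tile_grid(arr.shape[0], arr.shape[1], params.tile)
    out = np.empty_like(arr)
    kept = 0
    for rect in grid:
        r0, c0, h, w = rect
        block = arr[r0 : r0 + h, c0 : c0 + w]
        st = TileStats(mean=float(block.mean()), n_actual=block.size)
        band = ci_band(st, sigma, params)
        inside = (block > band.lo) & (block < band.hi)  # strict, per the rule
        repl = _replacement_value(block, st.mean, params.replacement)
        out[r0 : r0 + h, c0 : c0 + w] = np.where(inside, block, repl)
        kept += int(inside.sum())
    if return_stats:
        info = {
            "sigma": sigma,
            "n_tiles": grid.n_tiles,
            "retention_fraction": kept / arr.size,
            "z": params.resolve_z(),
        }
        return out, info
    return out


def pipeline_segment(
    image: np.ndarray,
    params: FilterParams | None = None,
    m: int = 3,
    nbins: int = 256,
    prefilter: bool = True,
) -> np.ndarray:
    """Full segmentation chain: CI filter, then multi-level Otsu.

    With ``prefilter=False`` this degrades to the plain Otsu reference
    chain.  ``m`` thresholds produce ``m + 1`` classes (default three
    thresholds, four classes).
    """
    from . import multiotsu

    arr = as_gray_image(image)
    if prefilter:
        arr = apply_ci_filter(arr, params)
    hist = multiotsu.histogram(arr, nbins)
    ts = multiotsu.otsu_thresholds(hist, m)
    return multiotsu.apply_thresholds(arr, ts, nbins)
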
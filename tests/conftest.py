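"""Shared fixtures and independent reference implementations.

The reference (oracle) routines here are deliberately written as plain
per-pixel / per-tuple loops, independent of the vectorized library code
they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest


def bruteforce_ci_filter(image, ia, ja, z, replacement="mean",
                         band_n="nominal", ddof=0):
    """Literal per-pixel evaluation of the band-keep/replace rule.

    Loops over every pixel, recomputing its tile's mean and the band from
    first principles; no shared code with the library implementation.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    sigma = math.sqrt(
        sum((v - image.mean()) ** 2 for v in image.ravel()) / (image.size - ddof)
    )
    out = np.empty_like(image)
    for r in range(H):
        for c in range(W):
            r0 = (r // ia) * ia
            c0 = (c // ja) * ja
            block = image[r0 : min(r0 + ia, H), c0 : min(c0 + ja, W)]
            xbar = float(block.mean())
            n = ia * ja if band_n == "nominal" else block.size
            half = z * sigma / math.sqrt(n)
            v = image[r, c]
            if (v < xbar + half) and (v > xbar - half):
                out[r, c] = v
            elif replacement == "mean":
                out[r, c] = xbar
            elif replacement == "min":
                out[r, c] = float(block.min())
            else:
                out[r, c] = float(block.max())
    return out


def bruteforce_bcv(counts, ts):
    """Between-class variance by direct class-wise summation."""
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    total = counts.sum()
    centers = [(k + 0.5) / n for k in range(n)]
    mu = sum(counts[k] * centers[k] for k in range(n)) / total
    edges = [-1] + list(ts) + [n - 1]
    sb = 0.0
    for a, b in zip(edges, edges[1:]):
        w = counts[a + 1 : b + 1].sum() / total
        if w == 0:
            continue
        m = sum(counts[k] * centers[k] for k in range(a + 1, b + 1)) / (w * total)
        sb += w * (m - mu) ** 2
    return sb


def enumerate_best_thresholds(counts, m):
    """Full enumeration of all strictly increasing m-tuples; returns the
    lexicographically smallest argmax and the maximal criterion value."""
    n = len(counts)
    best_ts, best_v = None, -1.0
    for ts in itertools.combinations(range(n - 1), m):
        v = bruteforce_bcv(counts, ts)
        if v > best_v + 1e-15:
            best_ts, best_v = ts, v
    return best_ts, best_v


@pytest.fixture
def rng():
    return np.random.default_rng(20180046)


@pytest.fixture
def flat_field(rng):
    """Flat i.i.d. Gaussian field well inside [0, 1] (clipping negligible)."""
    return np.clip(rng.normal(0.5, 0.05, size=(200, 200)), 0.0, 1.0)
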
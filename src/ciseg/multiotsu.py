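"""Multi-level Otsu thresholding, implemented from scratch.

Otsu's criterion picks the threshold set that maximizes the between-class
variance

    sigma_B^2 = sum_k  omega_k * (mu_k - mu_total)^2

over the classes a threshold tuple induces on the intensity histogram,
using only the zeroth and first cumulative histogram moments.  The search
here is globally optimal: a dynamic program over class boundaries scans
every strictly increasing m-tuple of bin indices, and ties are broken by
the lexicographically smallest tuple so results are reproducible.

Conventions (fixed, documented, configurable where noted):

* ``nbins`` defaults to 256; bin ``k`` covers ``[k/nbins, (k+1)/nbins)``
  with the last bin closed at 1.0.
* Thresholds are bin indices; a pixel in bin ``b`` gets class ``k`` iff
  ``t_k < b <= t_(k+1)`` with sentinels ``t_0 = -1`` and
  ``t_(m+1) = nbins - 1``.  ``m`` thresholds give ``m + 1`` classes.
* Empty classes contribute zero to sigma_B^2.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "histogram",
    "bin_centers",
    "between_class_variance",
    "within_class_variance",
    "total_variance",
    "otsu_thresholds",
    "apply_thresholds",
]


def histogram(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Intensity histogram of a [0, 1] image with the stated bin rule.

    Returns integer counts of length ``nbins``; the total equals the pixel
    count.  Intensity 1.0 falls in the last bin (closed upper edge).
    """
    from .ci_filter import as_gray_image

    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    arr = as_gray_image(image)
    bins = np.minimum((arr * nbins).astype(np.int64), nbins - 1)
    return np.bincount(bins.ravel(), minlength=nbins)


def bin_centers(nbins: int) -> np.ndarray:
    """Representative intensity of each histogram bin (bin midpoint)."""
    return (np.arange(nbins) + 0.5) / nbins


def _moments(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative zeroth/first probability moments and the global mean.

    ``W[b]`` and ``S[b]`` are the probability mass and first moment of bins
    ``< b`` (so ``W`` has length nbins+1 and segment sums are differences).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be a 1-D array with >= 2 bins")
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = counts / total
    centers = bin_centers(counts.size)
    W = np.concatenate(([0.0], np.cumsum(p)))
    S = np.concatenate(([0.0], np.cumsum(p * centers)))
    return W, S, float(S[-1])


def _check_thresholds(ts: tuple[int, ...], nbins: int) -> tuple[int, ...]:
    ts = tuple(int(t) for t in ts)
    if len(ts) < 1:
        raise ValueError("need at least one threshold")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if ts[0] < 0 or ts[-1] > nbins - 2:
        raise ValueError(f"thresholds {ts} out of range for nbins={nbins}")
    return ts


def between_class_variance(counts: np.ndarray, ts: tuple[int, ...]) -> float:
    """sigma_B^2 for the classes a threshold tuple induces on a histogram."""
    counts = np.asarray(counts, dtype=np.float64)
    W, S, mu_total = _moments(counts)
    ts = _check_thresholds(ts, counts.size)
    edges = (-1,) + ts + (counts.size - 1,)
    sigma_b2 = 0.0
    for a, b in zip(edges, edges[1:]):
        w = W[b + 1] - W[a + 1]
        if w <= 0.0:  # empty class contributes nothing
            continue
        s = S[b + 1] - S[a + 1]
        sigma_b2 += w * (s / w - mu_total) ** 2
    return float(sigma_b2)


def total_variance(counts: np.ndarray) -> float:
    """Variance of the histogram about its mean (population form)."""
    counts = np.asarray(counts, dtype=np.float64)
    _, _, mu = _moments(counts)
    p = counts / counts.sum()
    c = bin_centers(counts.size)
    return float(np.sum(p * (c - mu) ** 2))


def within_class_variance(counts: np.ndarray, ts: tuple[int, ...]) -> float:
    """sigma_W^2; satisfies sigma_B^2 + sigma_W^2 = sigma_total^2."""
    counts = np.asarray(counts, dtype=np.float64)
    ts = _check_thresholds(ts, counts.size)
    p = counts / counts.sum()
    c = bin_centers(counts.size)
    edges = (-1,) + tuple(ts) + (counts.size - 1,)
    sw = 0.0
    for a, b in zip(edges, edges[1:]):
        w = p[a + 1 : b + 1].sum()
        if w <= 0.0:
            continue
        mu_k = float(np.sum(p[a + 1 : b + 1] * c[a + 1 : b + 1])) / w
        sw += float(np.sum(p[a + 1 : b + 1] * (c[a + 1 : b + 1] - mu_k) ** 2))
    return sw


def _segment_score(counts: np.ndarray) -> np.ndarray:
    """Matrix Q with Q[a, b] = s^2 / w for the class spanning bins a..b.

    sigma_B^2 of a full partition is the sum of its segment scores minus
    mu_total^2, so maximizing the sum maximizes sigma_B^2.  Empty segments
    score 0.
    """
    W, S, _ = _moments(counts)
    nbins = counts.size
    w = W[None, 1:] - W[: nbins, None]  # w[a, b] over bins a..b (b >= a)
    s = S[None, 1:] - S[: nbins, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(w > 0.0, s * s / np.where(w > 0.0, w, 1.0), 0.0)
    return q


def otsu_thresholds(counts: np.ndarray, m: int = 3) -> tuple[int, ...]:
    """Globally optimal m-level Otsu thresholds for a histogram.

    Scans all strictly increasing m-tuples of bin indices in
    ``[0, nbins - 2]`` via dynamic programming on the segment-score matrix
    and returns the tuple maximizing sigma_B^2; exact ties resolve to the
    lexicographically smallest tuple.
    """
    counts = np.asarray(counts, dtype=np.float64)
    nbins = counts.size
    if not 1 <= m <= nbins - 1:
        raise ValueError(f"m must be in [1, {nbins - 1}], got {m}")
    q = _segment_score(counts)

    # V[k] maps threshold t_k -> best score of classes k..m given t_k = t.
    # Class k spans bins t+1 .. t_{k+1}; class m spans t_m+1 .. nbins-1.
    idx = np.arange(nbins - 1)  # candidate threshold positions
    V = [np.empty(0)] * (m + 1)
    V[m] = q[idx + 1, nbins - 1]
    neg = -np.inf
    for k in range(m - 1, 0, -1):
        # M[t, t'] = q[t+1, t'] + V[k+1][t'] for t' > t, else -inf
        M = q[idx + 1, :][:, idx] + V[k + 1][None, :]
        M = np.where(idx[None, :] > idx[:, None], M, neg)
        V[k] = M.max(axis=1)

    first = q[0, idx] + V[1]
    t_prev = int(np.argmax(first))  # first max == lexicographically smallest
    ts = [t_prev]
    for k in range(2, m + 1):
        cand = q[t_prev + 1, :][idx] + V[k]
        cand = np.where(idx > t_prev, cand, neg)
        t_prev = int(np.argmax(cand))
        ts.append(t_prev)
    return tuple(ts)


def apply_thresholds(
    image: np.ndarray, ts: tuple[int, ...], nbins: int = 256
) -> np.ndarray:
    """Per-pixel class map: class k iff bin b satisfies t_k < b <= t_(k+1)."""
    from .ci_filter import as_gray_image

    arr = as_gray_image(image)
    ts = _check_thresholds(tuple(ts), nbins)
    bins = np.minimum((arr * nbins).astype(np.int64), nbins - 1)
    labels = np.zeros(arr.shape, dtype=np.uint8)
    for t in ts:
        labels += (bins > t).astype(np.uint8)
    return labels
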
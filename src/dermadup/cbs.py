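"""Circular binary segmentation (CBS) for ordered Log R ratio signals.

The algorithm recursively partitions an ordered signal into constant-mean
segments.  At each level the segment is treated as a circle and every arc
(i, j] is scored with the absolute two-sample t-like statistic

    T(i, j) = |mean(arc) - mean(complement)| / (sigma * sqrt(1/k + 1/(n-k)))

with sigma the segment's overall standard deviation.  Because sigma and the
total sum are permutation-invariant, maximizing T is equivalent to
minimizing the residual sum of squares of the two-level (arc mean /
complement mean) model, which is what the exhaustive changepoint oracle in
the test-suite computes.  The maximal arc is accepted as a pair of
change-points when its permutation p-value (marker shuffling within the
segment) is at or below ``alpha``; accepted sub-segments are then scanned
recursively.  For a fixed ``rng_seed`` the accepted change-points are fully
deterministic.

The permutation loop stops early once the exceedance count can no longer
reach significance; this cannot change which change-points are accepted,
only the resolution of the reported p-value on clearly non-significant
segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval


@dataclass
class CbsParams:
    n_permutations: int = 10_000
    alpha: float = 0.01
    rng_seed: int = 12_345_678
    min_markers_per_segment: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass
class SegmentCall:
    interval: GenomicInterval  # first to last marker of the segment
    first: int                 # marker indices (0-based, inclusive)
    last: int
    n_markers: int
    mean_lrr: float
    p_value: float             # p of the accepted split that isolated this segment (nan at root)


def _arc_stats_matrices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Precompute arc length matrix K[i, j] = j - i and validity mask for a
    segment of n markers (0 <= i < j <= n, 0 < K < n)."""
    idx = np.arange(n + 1)
    K = idx[None, :] - idx[:, None]
    valid = (K > 0) & (K < n)
    return K.astype(float), valid


def _max_arc_t(x: np.ndarray, K: np.ndarray, valid: np.ndarray) -> tuple[float, int, int]:
    """Maximal |t| over all arcs of x, with the arg-max (i, j)."""
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    total = S[-1]
    arc_sum = S[None, :] - S[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = arc_sum / K - (total - arc_sum) / (n - K)
        t = np.abs(diff) / np.sqrt(1.0 / K + 1.0 / (n - K))
    t[~valid] = -np.inf
    flat = int(np.argmax(t))
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), i, j


def _max_arc_t_only(x: np.ndarray, K: np.ndarray, valid: np.ndarray) -> float:
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    total = S[-1]
    arc_sum = S[None, :] - S[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = arc_sum / K - (total - arc_sum) / (n - K)
        t = np.abs(diff) / np.sqrt(1.0 / K + 1.0 / (n - K))
    return float(np.nanmax(np.where(valid, t, -np.inf)))


def _permutation_p(
    x: np.ndarray,
    t_obs: float,
    params: CbsParams,
    rng: np.random.Generator,
    K: np.ndarray,
    valid: np.ndarray,
) -> float:
    """P(max-arc statistic >= t_obs) under marker shuffling, early-stopped."""
    reject_at = int(np.floor(params.alpha * params.n_permutations))
    exceed = 0
    done = 0
    chunk = 256
    while done < params.n_permutations:
        m = min(chunk, params.n_permutations - done)
        for _ in range(m):
            xp = rng.permutation(x)
            if _max_arc_t_only(xp, K, valid) >= t_obs - 1e-12:
                exceed += 1
        done += m
        if exceed > reject_at:  # cannot reach significance any more
            return exceed / done
    return exceed / params.n_permutations


def cbs_segment(
    lrr: np.ndarray,
    positions: np.ndarray,
    params: CbsParams | None = None,
    chrom: str = "chr20",
) -> list[SegmentCall]:
    """Segment one individual's Log R ratio profile.

    ``lrr`` and ``positions`` must be equal-length with strictly increasing
    positions and no missing values (drop them upstream).
    """
    params = params or CbsParams()
    x = np.asarray(lrr, dtype=float)
    pos = np.asarray(positions)
    if x.shape != pos.shape:
        raise ValueError("lrr and positions must be equal length")
    if len(pos) >= 2 and not np.all(np.diff(pos) > 0):
        raise ValueError("positions must be strictly increasing")
    if np.isnan(x).any():
        raise ValueError("missing values must be dropped before segmentation")
    n = len(x)
    if n < 2:
        return [
            SegmentCall(
                interval=GenomicInterval(int(pos[0]), int(pos[0]), chrom) if n else GenomicInterval(1, 1, chrom),
                first=0,
                last=max(n - 1, 0),
                n_markers=n,
                mean_lrr=float(x.mean()) if n else float("nan"),
                p_value=float("nan"),
            )
        ]

    rng = np.random.default_rng(params.rng_seed)
    boundaries: list[tuple[int, int, float]] = []  # (lo, hi) exclusive hi, split p

    def recurse(lo: int, hi: int, p_inherit: float) -> None:
        seg = x[lo:hi]
        m = hi - lo
        if m < 4 or np.allclose(seg, seg[0]):
            boundaries.append((lo, hi, p_inherit))
            return
        K, valid = _arc_stats_matrices(m)
        sigma = seg.std()
        if sigma == 0:
            boundaries.append((lo, hi, p_inherit))
            return
        t_obs, i, j = _max_arc_t(seg, K, valid)
        p = _permutation_p(seg, t_obs, params, rng, K, valid)
        if p > params.alpha:
            boundaries.append((lo, hi, p_inherit))
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b > a:
                recurse(a, b, p)

    recurse(0, n, float("nan"))
    boundaries.sort()
    calls = []
    for lo, hi, p in boundaries:
        calls.append(
            SegmentCall(
                interval=GenomicInterval(int(pos[lo]), int(pos[hi - 1]), chrom),
                first=lo,
                last=hi - 1,
                n_markers=hi - lo,
                mean_lrr=float(x[lo:hi].mean()),
                p_value=p,
            )
        )
    return calls
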
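"""Interval PLS (iPLS): partition the wavenumber axis and search for the
interval combination with the lowest leave-one-out RMSECV.

The axis is split into contiguous equal-point-count intervals; a greedy
forward search starts from the single best interval and keeps adding the
interval giving the largest cross-validated error decrease, which
discards noisy, nonlinear or polymorph-irrelevant spectral regions.  For
small partitions an exhaustive search over all subsets is available and
doubles as the oracle for the greedy result.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .metrics import loo_cross_validate


@dataclass(frozen=True)
class IntervalSet:
    """A selected combination of wavenumber intervals and its CV score."""

    intervals: tuple[tuple[float, float], ...]
    n_intervals_total: int
    score: float  # response-averaged LOO RMSECV, % of CBZ mass
    n_lv: int

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.intervals))
        object.__setattr__(self, "intervals", ordered)
        for (_, hi), (lo, _) in zip(ordered, ordered[1:]):
            if lo <= hi:
                raise ValueError("intervals overlap")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    def covers(self, wavenumber: float) -> bool:
        return any(lo <= wavenumber <= hi for lo, hi in self.intervals)


def partition_axis(axis: np.ndarray, n_intervals: int) -> list[tuple[float, float]]:
    """Split the axis into contiguous equal-point-count intervals.

    Each interval gets ``n_points // n_intervals`` grid points; the
    remainder points go to the last interval.  Bounds are the wavenumbers
    of the first and last point of each block, so the intervals tile the
    axis exactly.
    """
    axis = np.asarray(axis, dtype=float)
    n = axis.size
    if not (2 <= n_intervals <= n):
        raise ValueError(f"n_intervals must be in [2, {n}], got {n_intervals}")
    size = n // n_intervals
    bounds = []
    for i in range(n_intervals):
        start = i * size
        stop = (i + 1) * size - 1 if i < n_intervals - 1 else n - 1
        bounds.append((float(axis[start]), float(axis[stop])))
    return bounds


def _interval_indices(axis: np.ndarray, intervals) -> np.ndarray:
    blocks = [
        np.flatnonzero((axis >= lo - 1e-9) & (axis <= hi + 1e-9))
        for lo, hi in sorted(intervals)
    ]
    return np.concatenate(blocks)


def score_interval_set(
    intervals,
    X: np.ndarray,
    Y: np.ndarray,
    axis: np.ndarray,
    lv_candidates=range(1, 11),
) -> tuple[float, int]:
    """Leave-one-out RMSECV of a PLS model restricted to ``intervals``.

    The LV count is re-optimized over ``lv_candidates`` for every candidate
    interval set (small intervals support fewer latent variables): the
    score is the minimum response-averaged RMSECV over the candidates,
    with ties broken toward fewer components.  Returns
    ``(score, best_n_lv)``; deterministic, so repeated evaluations agree
    exactly.
    """
    idx = _interval_indices(np.asarray(axis, dtype=float), intervals)
    if idx.size < 2:
        raise ValueError("interval set selects fewer than 2 features")
    cv, _ = loo_cross_validate(np.asarray(X, dtype=float)[:, idx], Y, list(lv_candidates))
    j = int(np.argmin(cv.rmsecv_mean))  # argmin takes the first (fewest-LV) tie
    return float(cv.rmsecv_mean[j]), cv.lv_candidates[j]


def forward_select_intervals(
    partition,
    X: np.ndarray,
    Y: np.ndarray,
    axis: np.ndarray,
    lv_candidates=range(1, 11),
    max_intervals: int = 5,
    min_improvement: float = 0.02,
) -> IntervalSet:
    """Greedy forward selection of wavenumber intervals.

    Start with the best-scoring single interval; repeatedly add the
    interval whose inclusion lowers the response-averaged RMSECV the most;
    stop when the best relative improvement falls below
    ``min_improvement`` or ``max_intervals`` is reached.  Ties are broken
    in favour of the lower wavenumber interval (the candidate list is
    scanned in axis order and a strictly better score is required to
    displace the incumbent).
    """
    partition = sorted((float(lo), float(hi)) for lo, hi in partition)
    scored = [
        (score_interval_set([iv], X, Y, axis, lv_candidates), iv) for iv in partition
    ]
    (best_score, best_lv), best_iv = min(scored, key=lambda t: (t[0][0], t[1]))
    selected = [best_iv]

    while len(selected) < max_intervals:
        remaining = [iv for iv in partition if iv not in selected]
        if not remaining:
            break
        best_cand = None
        for iv in remaining:  # axis order -> lower-wavenumber tie-break
            score, n_lv = score_interval_set(selected + [iv], X, Y, axis, lv_candidates)
            if best_cand is None or score < best_cand[0]:
                best_cand = (score, n_lv, iv)
        score, n_lv, iv = best_cand
        if best_score <= 0:
            break
        if (best_score - score) / best_score < min_improvement:
            break
        selected.append(iv)
        best_score, best_lv = score, n_lv

    return IntervalSet(
        intervals=tuple(sorted(selected)),
        n_intervals_total=len(partition),
        score=best_score,
        n_lv=best_lv,
    )


def exhaustive_select_intervals(
    partition,
    X: np.ndarray,
    Y: np.ndarray,
    axis: np.ndarray,
    lv_candidates=range(1, 11),
    max_intervals: int | None = None,
) -> IntervalSet:
    """Brute-force search over all non-empty interval subsets.

    Exponential in the partition size; intended for small partitions
    (<= ~10 intervals) and as the oracle for the greedy search.  Ties are
    broken by smaller subset size, then lexicographically smaller (lower
    wavenumber) interval list.
    """
    partition = sorted((float(lo), float(hi)) for lo, hi in partition)
    limit = len(partition) if max_intervals is None else min(max_intervals, len(partition))
    best = None
    for r in range(1, limit + 1):
        for subset in combinations(partition, r):
            score, n_lv = score_interval_set(list(subset), X, Y, axis, lv_candidates)
            key = (score, r, subset)
            if best is None or key < best[0]:
                best = (key, n_lv)
    (score, r, subset), n_lv = best
    return IntervalSet(
        intervals=tuple(subset),
        n_intervals_total=len(partition),
        score=score,
        n_lv=n_lv,
    )
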
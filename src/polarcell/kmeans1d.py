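"""Globally optimal 1D k-means for intensity binning.

One-dimensional k-means admits an exact solution: the optimal clusters
are contiguous intervals of the sorted values, so the partition can be
found by dynamic programming instead of Lloyd iterations. We compress the
input to unique values with multiplicity weights (fluorescence counts are
heavily tied), then run a divide-and-conquer DP that exploits the
monotonicity of the optimal split points — O(k * u log u) for u unique
values. The result is deterministic and globally optimal, so the
quantization of intensities into bins never depends on a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInput


@dataclass
class IntensityBins:
    """Result of 1D k-means on within-mask intensities.

    ``centers`` are the (strictly ascending, deduplicated) bin centers;
    ``assignments`` maps each input value to the index of its nearest
    center; ``sse`` is the within-cluster sum of squares. ``degenerate``
    flags inputs with fewer distinct values than requested bins.
    """

    centers: np.ndarray
    assignments: np.ndarray
    sse: float
    degenerate: bool

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    @property
    def top_bin(self) -> int:
        return len(self.centers) - 1


def _interval_cost(w: np.ndarray, ws1: np.ndarray, ws2: np.ndarray,
                   cw: np.ndarray, i: np.ndarray | int, j: int):
    """SSE of grouping unique values i..j (inclusive) into one cluster.

    Prefix arrays: cw = cumulative weight, ws1 = cumulative w*x,
    ws2 = cumulative w*x^2, each padded with a leading 0.
    """
    wsum = cw[j + 1] - cw[i]
    s1 = ws1[j + 1] - ws1[i]
    s2 = ws2[j + 1] - ws2[i]
    return s2 - np.where(wsum > 0, s1 * s1 / np.maximum(wsum, 1e-300), 0.0)


def _solve_layer(prev: np.ndarray, cost_args, lo: int, hi: int,
                 opt_lo: int, opt_hi: int, cur: np.ndarray,
                 split: np.ndarray) -> None:
    """Divide-and-conquer layer fill: cur[j] = min_i prev[i-1] + cost(i, j)."""
    if lo > hi:
        return
    mid = (lo + hi) // 2
    w, ws1, ws2, cw = cost_args
    i_max = min(mid, opt_hi)
    cand = np.arange(opt_lo, i_max + 1)
    vals = prev[cand - 1] + _interval_cost(w, ws1, ws2, cw, cand, mid)
    best = int(np.argmin(vals))
    cur[mid] = vals[best]
    split[mid] = cand[best]
    _solve_layer(prev, cost_args, lo, mid - 1, opt_lo, cand[best], cur, split)
    _solve_layer(prev, cost_args, mid + 1, hi, cand[best], opt_hi, cur, split)


def kmeans_1d(values: np.ndarray, k: int = 5) -> IntensityBins:
    """Exact 1D k-means of ``values`` into at most ``k`` bins.

    Returns bin centers in ascending order with nearest-center
    assignments. When the input has fewer than ``k`` distinct values the
    centers are exactly those values and the result is flagged degenerate
    (SSE 0).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise EmptyInput("kmeans_1d on empty input")
    if k < 1:
        raise ValueError("k must be >= 1")
    uniq, inverse, counts = np.unique(
        values, return_inverse=True, return_counts=True
    )
    u = len(uniq)
    if u <= k:
        centers = uniq
        assignments = inverse
        return IntensityBins(centers, assignments, 0.0, degenerate=u < k)

    w = counts.astype(float)
    cw = np.concatenate(([0.0], np.cumsum(w)))
    ws1 = np.concatenate(([0.0], np.cumsum(w * uniq)))
    ws2 = np.concatenate(([0.0], np.cumsum(w * uniq * uniq)))
    cost_args = (w, ws1, ws2, cw)

    # DP over layers; splits[l][j] = first unique index of the last cluster
    # when values 0..j are partitioned into l+1 clusters
    prev = ws2[1:] - ws1[1:] ** 2 / cw[1:]
    splits = [np.zeros(u, dtype=int)]
    for layer in range(1, k):
        cur = np.empty(u)
        split = np.zeros(u, dtype=int)
        # j < layer: j+1 values in >= j+1 clusters -> singletons, SSE 0
        cur[:layer] = 0.0
        split[:layer] = np.arange(layer)
        _solve_layer(prev, cost_args, layer, u - 1, 1, u - 1, cur, split)
        splits.append(split)
        prev = cur

    # backtrack cluster boundaries
    bounds = []
    j = u - 1
    for layer in range(k - 1, -1, -1):
        i = splits[layer][j] if layer > 0 else 0
        bounds.append((i, j))
        j = i - 1
    bounds.reverse()

    centers = np.array(
        [
            (ws1[j + 1] - ws1[i]) / (cw[j + 1] - cw[i])
            for i, j in bounds
        ]
    )
    sse = float(prev[u - 1])

    # nearest-center assignment (for the optimal partition this coincides
    # with the interval membership; midpoints break ties downward)
    centers = np.unique(centers)
    mids = (centers[:-1] + centers[1:]) / 2.0
    assignments = np.searchsorted(mids, values, side="right")
    return IntensityBins(centers, assignments, sse, degenerate=False)
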
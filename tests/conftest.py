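"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from polarcell import PolarityParams
from polarcell.polarity import Cluster
from polarcell.preprocess import Projection


@pytest.fixture
def params() -> PolarityParams:
    return PolarityParams()


def disk_mask(shape=(128, 128), center=(64, 64), radius=20) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def single_channel_projection(img: np.ndarray, name="ch") -> Projection:
    return Projection(img[None].astype(float), (name,))


def make_cluster(pixels: np.ndarray) -> Cluster:
    """Minimal Cluster wrapper for geometry-only tests (hull vs disk)."""
    pixels = np.asarray(pixels, dtype=int)
    return Cluster(
        pixels=pixels,
        size_px=len(pixels),
        mean_intensity=1.0,
        weighted_centroid_px=tuple(pixels.mean(axis=0)),
        direction_deg=0.0,
        angle_to_axis_deg=0.0,
        in_zone_fraction=1.0,
    )


# ---------------------------------------------------------------------------
# independent oracles


def kmeans_sse_oracle(values: np.ndarray, k: int) -> float:
    """Naive O(k n^2) dynamic program over the sorted raw values."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(i: int, j: int) -> float:
        w = j - i + 1
        s = cs[j + 1] - cs[i]
        return cs2[j + 1] - cs2[i] - s * s / w

    prev = [cost(0, j) for j in range(n)]
    for _ in range(1, k):
        cur = [0.0] * n
        for j in range(n):
            best = prev[j]
            for i in range(1, j + 1):
                c = prev[i - 1] + cost(i, j)
                if c < best:
                    best = c
            cur[j] = best
        prev = cur
    return prev[n - 1]


def points_in_hull_oracle(
    hull_points: np.ndarray, queries: np.ndarray
) -> np.ndarray:
    """Membership of query points in the closed convex hull of integer
    points, via half-plane checks (scipy ConvexHull) with exact integer
    fallbacks for degenerate (point / collinear) hulls."""
    from scipy.spatial import ConvexHull, QhullError

    pts = np.unique(np.asarray(hull_points, dtype=np.int64), axis=0)
    queries = np.asarray(queries, dtype=np.int64)
    if len(pts) == 1:
        return np.all(queries == pts[0], axis=1)
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:
        # collinear: on-segment test in exact integer arithmetic
        p0 = pts[0]
        d = pts[-1] - p0
        rel = queries - p0
        cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
        t = rel @ d
        return (cross == 0) & (t >= 0) & (t <= d @ d)
    eqs = hull.equations  # rows: (a, b, offset) with a*x + b*y + offset <= 0
    vals = queries @ eqs[:, :2].T + eqs[:, 2]
    return np.all(vals <= 1e-9, axis=1)


def fisher_p_oracle(table) -> float:
    """Exact two-sided Fisher p by rational enumeration (math.comb)."""
    from fractions import Fraction
    from math import comb

    (a, b), (c, d) = [list(map(int, row)) for row in table]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, aa) * comb(r2, c1 - aa), denom)
        if p <= p_obs:
            total += p
    return float(total)
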
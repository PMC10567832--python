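"""Knee / inflection-point detection on monotone curves.

One shared detector serves three places: the cumulative weighted
percent-of-variation curve in blast correction, the absolute
signed-significance decay curve that truncates the GSEA feature pool, and
the gain decay curve of boosted-tree mutation selection.  The rule is the
parameter-free maximum-perpendicular-distance criterion: the knee is the
point of the curve farthest from the chord joining its first and last
points.
"""

from __future__ import annotations

import numpy as np

__all__ = ["knee_index", "cumulative_knee_count"]


def knee_index(y: np.ndarray) -> tuple[int, float]:
    """Index of maximum perpendicular distance from the first-last chord.

    Returns ``(index, distance)`` with ``index`` 0-based on ``y``.  Points are
    taken at unit x spacing.  A curve lying on its chord (distance ~ 0)
    signals a degenerate, knee-less curve; callers should treat distances
    below their tolerance as "no knee".
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("need a 1-D curve with at least 2 points")
    x = np.arange(y.size, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return 0, 0.0
    # perpendicular distance of each point to the chord
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    idx = int(np.argmax(dist))
    return idx, float(dist[idx])


def cumulative_knee_count(increments: np.ndarray) -> tuple[int, float]:
    """Knee of a cumulative-sum curve, expressed as a leading-item count.

    ``increments`` are non-negative, sorted descending.  The cumulative curve
    is anchored at 0 so that a single dominant first increment is detectable
    (endpoints of a chord are otherwise at distance zero).  Returns
    ``(count, distance)`` where ``count`` is the number of leading increments
    at or before the knee.
    """
    inc = np.asarray(increments, dtype=float)
    if inc.ndim != 1 or inc.size < 1:
        raise ValueError("need at least one increment")
    curve = np.concatenate([[0.0], np.cumsum(inc)])
    idx, dist = knee_index(curve)
    return idx, dist
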
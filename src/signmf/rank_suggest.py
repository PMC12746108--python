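"""Automatic rank suggestion from rank-selection curves.

Two heuristics:

* :func:`suggest_rank_elbow` — knee/elbow of a bicrossvalidation curve
  by the Satopaa et al. "kneedle" construction (normalized difference
  curve, local maxima, sensitivity threshold).  Bicrossvalidation
  metrics rise toward a plateau, so the knee marks where adding
  signatures stops paying for itself.
* :func:`suggest_rank_stability` — for stability coefficients
  (signature similarity, cophenetic correlation, dispersion), which
  peak rather than plateau: local maxima become candidates, candidates
  within a tolerance ``t`` of the best are kept, and the one followed
  by the longest strictly monotonic decline wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RankCurve", "suggest_rank_elbow", "suggest_rank_stability"]


@dataclass(frozen=True)
class RankCurve:
    """A per-rank scalar curve (median cosine/R2 or a stability score)."""

    ranks: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        ranks = tuple(int(r) for r in self.ranks)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "ranks", ranks)
        object.__setattr__(self, "values", values)
        if len(ranks) != len(values):
            raise ValueError("ranks and values must have equal length")
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("ranks must be strictly increasing")
        if any(not np.isfinite(v) for v in values):
            raise ValueError("curve values must be finite")


def suggest_rank_elbow(
    curve: RankCurve,
    online: bool = True,
    sensitivity: float = 1.0,
    direction: str = "increasing",
    shape: str = "concave",
) -> int | None:
    """Knee of the curve per the kneedle maximum-curvature construction.

    x and y are min-max normalized; the curve is transformed so it is
    concave increasing and the difference curve d = y_n - x_n is formed.
    Local maxima of d (non-strict, endpoints included) are knee
    candidates; a candidate at index i with value d_i is confirmed when
    d later drops below d_i - sensitivity * mean x-spacing before the
    threshold is reset by a local minimum.  ``online=True`` scans the
    whole curve and keeps the last confirmed knee rather than stopping
    at the first; ``direction`` defaults to "increasing" because
    bicrossvalidation metrics rise toward a plateau (pass "auto" to
    infer it from the endpoints).  Returns None when no knee exists
    (e.g. the curve is linear).
    """
    x = np.asarray(curve.ranks, dtype=float)
    y = np.asarray(curve.values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for elbow detection")
    if direction == "auto":
        direction = "increasing" if y[-1] >= y[0] else "decreasing"
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"unknown direction: {direction!r}")
    if y.max() == y.min():
        return None
    x_n = (x - x.min()) / (x.max() - x.min())
    y_n = (y - y.min()) / (y.max() - y.min())
    # canonicalize to concave increasing: vertical mirror for convex
    # curvature, horizontal flip when the canonical form needs reversing
    if shape not in ("concave", "convex"):
        raise ValueError(f"unknown shape: {shape!r}")
    y_t = 1.0 - y_n if shape == "convex" else y_n
    h_flip = (shape == "concave") == (direction == "decreasing")
    if h_flip:
        y_t = np.flip(y_t)
    d = y_t - x_n
    n = len(d)
    # non-strict local extrema, boundaries compared to their single neighbour
    padded = np.concatenate([[d[0]], d, [d[-1]]])
    is_max = (d >= padded[:-2]) & (d >= padded[2:]) & ~((d == padded[:-2]) & (d == padded[2:]))
    is_min = (d <= padded[:-2]) & (d <= padded[2:]) & ~((d == padded[:-2]) & (d == padded[2:]))
    maxima = np.flatnonzero(is_max)
    if maxima.size == 0:
        return None
    spacing = sensitivity * float(np.mean(np.diff(x_n)))
    knee_idx: int | None = None
    threshold = -np.inf
    candidate: int | None = None
    for i in range(int(maxima[0]), n):
        if is_max[i]:
            candidate = i
            threshold = d[i] - spacing
        elif is_min[i]:
            candidate = None
            threshold = -np.inf
        if i + 1 < n and d[i + 1] < threshold and candidate is not None:
            idx = n - 1 - candidate if h_flip else candidate
            if not online:
                return int(curve.ranks[idx])
            knee_idx = idx
            candidate = None
            threshold = -np.inf
    return int(curve.ranks[knee_idx]) if knee_idx is not None else None


def _candidates(values: np.ndarray) -> list[int]:
    """Strict local maxima; endpoints qualify against their single neighbour."""
    n = len(values)
    if n == 1:
        return [0]
    cand = []
    if values[0] > values[1]:
        cand.append(0)
    cand.extend(
        i for i in range(1, n - 1) if values[i] > values[i - 1] and values[i] > values[i + 1]
    )
    if values[n - 1] > values[n - 2]:
        cand.append(n - 1)
    return cand


def _decline_run(values: np.ndarray, i: int) -> int:
    """Length of the strictly decreasing run immediately after index i."""
    run = 0
    while i + 1 < len(values) and values[i + 1] < values[i]:
        run += 1
        i += 1
    return run


def suggest_rank_stability(curve: RankCurve, t: float = 0.02) -> int:
    """Candidate-and-decline heuristic for peaked stability curves.

    Local maxima are candidates; those with value >= (1 - t) * best
    candidate are retained; among them the rank whose following values
    decline strictly for longest wins, ties going to the smallest rank.
    A curve with no strict local maximum (constant or plateau-topped)
    falls back to the global argmax.
    """
    if len(curve.ranks) == 0:
        raise ValueError("empty curve")
    values = np.asarray(curve.values, dtype=float)
    cand = _candidates(values)
    if not cand:
        return int(curve.ranks[int(np.argmax(values))])
    vmax = max(values[i] for i in cand)
    kept = [i for i in cand if values[i] >= (1.0 - t) * vmax]
    best = max(kept, key=lambda i: (_decline_run(values, i), -i))
    return int(curve.ranks[best])
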
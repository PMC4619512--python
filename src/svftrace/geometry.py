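"""Small polyline utilities shared by the phantom generator, the tracer and
the evaluation metrics."""

from __future__ import annotations

import numpy as np


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def arclengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arclength at each vertex, starting at 0."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, step: float,
                      keep_n: int | None = None) -> np.ndarray:
    """Resample at uniform arclength ``step`` (endpoints preserved).

    ``keep_n`` forces an exact vertex count instead of deriving it from the
    step."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return points.copy()
    s = arclengths(points)
    total = s[-1]
    if total == 0:
        return points[:1].copy()
    n = keep_n if keep_n is not None else max(2, int(round(total / step)) + 1)
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])
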
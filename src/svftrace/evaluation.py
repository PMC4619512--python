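"""Evaluation metrics against ground-truth centerlines.

* ``point_deviation``: mean Euclidean distance from each evaluated point to
  its nearest gold-standard point (the seeding quality measure).
* ``precision_recall``: length-based trace agreement.  Both the automated
  trace and the gold skeleton are resampled at 0.5-voxel steps; an automated
  sample is correct when it lies within ``match_tol`` of the gold skeleton,
  and precision is the correct fraction of automated length.  Recall is
  measured symmetrically from the gold side (fraction of gold length covered
  by the trace), which avoids rewarding oversampled traces.
* ``skeleton_length``: total polyline arclength of a trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import polyline_length, resample_polyline
from .tracing import NeuronTrace

RESAMPLE_STEP = 0.5


@dataclass
class TraceMatchResult:
    correct_length: float
    total_auto_length: float
    gold_length: float
    precision: float
    recall: float
    match_tol: float


def point_deviation(P_s, P_g) -> float:
    """Mean distance from each point of ``P_s`` to its nearest point in the
    gold standard ``P_g``."""
    P_s = np.atleast_2d(np.asarray(P_s, dtype=float))
    P_g = np.atleast_2d(np.asarray(P_g, dtype=float))
    if len(P_s) == 0:
        raise ValueError("evaluated point set is empty")
    if len(P_g) == 0:
        raise ValueError("gold point set is empty")
    d, _ = cKDTree(P_g).query(P_s)
    return float(np.mean(d))


def _as_polylines(obj) -> list[np.ndarray]:
    if isinstance(obj, NeuronTrace):
        return [c.nodes for c in obj.curves]
    if isinstance(obj, np.ndarray):
        return [obj]
    return [np.asarray(p, dtype=float) for p in obj]


def _dense_samples(polylines) -> np.ndarray:
    parts = [resample_polyline(p, RESAMPLE_STEP) for p in polylines if len(p) >= 2]
    if not parts:
        return np.empty((0, 3))
    return np.concatenate(parts)


def precision_recall(auto, gold, match_tol: float = 2.0) -> TraceMatchResult:
    """Length-based precision and recall of ``auto`` against ``gold``
    (a NeuronTrace, one polyline, or a list of polylines each)."""
    if match_tol <= 0:
        raise ValueError("match_tol must be positive")
    auto_lines = _as_polylines(auto)
    gold_lines = _as_polylines(gold)
    gold_pts = _dense_samples(gold_lines)
    if len(gold_pts) == 0:
        raise ValueError("gold standard is empty")
    auto_pts = _dense_samples(auto_lines)
    total_auto = sum(polyline_length(p) for p in auto_lines)
    total_gold = sum(polyline_length(p) for p in gold_lines)
    if len(auto_pts) == 0:
        return TraceMatchResult(0.0, 0.0, total_gold, 0.0, 0.0, match_tol)
    d_auto, _ = cKDTree(gold_pts).query(auto_pts)
    precision = float(np.mean(d_auto <= match_tol))
    d_gold, _ = cKDTree(auto_pts).query(gold_pts)
    recall = float(np.mean(d_gold <= match_tol))
    correct = precision * total_auto
    return TraceMatchResult(correct, total_auto, total_gold,
                            precision, recall, match_tol)


def skeleton_length(trace) -> float:
    """Total arclength (voxels) over all curves of a trace."""
    return float(sum(polyline_length(p) for p in _as_polylines(trace)))
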
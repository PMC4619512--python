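"""Cross-section boundary and radius estimation with a 2-D sliding band.

At a curve node the local frame is (v1, v2, v3): v1 the unit tangent, v2/v3
an orthonormal basis of the cross-sectional plane.  Along each of ``n``
in-plane rays the band filter finds the radius ``r`` (integer, in the open
sliding range) that maximises the band-averaged convergence index measured
toward the node — gradients at the neurite wall converge on the centerline,
so the winning band straddles the wall.  The ``n`` boundary points trace the
(generally non-circular) cross-section; their mean radius is the scalar
radius used for SWC export.

The band average here keeps the fixed ``1/(d+1)`` normalisation: unlike seed
detection, where thin tubes would drown in background samples, it is exactly
the dilution of part-empty bands that localises the wall.  Bands may need to
be thinner than the seeding band on thin neurites; ``radius_band_params``
derives a valid band width from ``R_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .filters import EPS_GRAD, FilterParams, GradientField
from .geometry import arclengths
from .tracing import NeuronTrace, SnakeCurve


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal frame at a curve node (v1 = v2 x v3)."""

    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray


@dataclass
class Contour:
    """One estimated cross-section: ``n`` boundary points
    ``B_k = center + r_k (cos(theta_k) v2 + sin(theta_k) v3)`` with
    ``theta_k = 2 pi k / n`` in plane order."""

    center: np.ndarray
    frame: LocalFrame
    boundary: np.ndarray     # (n, 3)
    radii: np.ndarray        # (n,)
    curve_id: int = 0
    node_index: int = 0

    @property
    def n(self) -> int:
        return len(self.radii)

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())


def local_frame(curve: SnakeCurve, node_index: int) -> LocalFrame:
    """Frame from the central-difference tangent (one-sided at the ends);
    v2 is the projection of the global axis least aligned with v1."""
    nodes = curve.nodes
    if len(nodes) < 3:
        raise ValueError("curve needs >= 3 nodes for a stable tangent")
    i = node_index
    if i == 0:
        t = nodes[1] - nodes[0]
    elif i == len(nodes) - 1:
        t = nodes[-1] - nodes[-2]
    else:
        t = nodes[i + 1] - nodes[i - 1]
    nt = np.linalg.norm(t)
    if nt < 1e-12:
        raise FloatingPointError("zero tangent at node")
    v1 = t / nt
    e = np.zeros(3)
    e[np.argmin(np.abs(v1))] = 1.0
    v2 = e - (e @ v1) * v1
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    return LocalFrame(v1, v2, v3)


PLATEAU_TOL = 0.01  # responses within this of the max count as tied


def _plateau_mid(responses: np.ndarray, tol: float = PLATEAU_TOL) -> int:
    """Index of the middle of the contiguous near-maximal response plateau.

    A band strictly inside the gradient-bearing shell scores the same as its
    neighbours (the convergence index ignores gradient magnitude), so on
    clean data the maximum is a plateau as wide as shell minus band; its
    midpoint is the band centered on the wall.  Degenerate all-equal
    responses yield the middle of the sliding range."""
    best = float(responses.max())
    j = int(np.argmax(responses))
    tied = responses >= best - tol
    lo = j
    while lo > 0 and tied[lo - 1]:
        lo -= 1
    hi = j
    while hi < len(responses) - 1 and tied[hi + 1]:
        hi += 1
    return (lo + hi) // 2


def sbf_boundary(grad: GradientField, center, frame: LocalFrame, n: int,
                 params: FilterParams, curve_id: int = 0,
                 node_index: int = 0) -> Contour:
    """Sliding-band boundary estimate around ``center`` in the plane of
    ``frame``; near-ties in the band response resolve to the plateau
    midpoint (see :func:`_plateau_mid`)."""
    if n < 4:
        raise ValueError("need n >= 4 boundary rays")
    center = np.asarray(center, dtype=float)
    if np.any(center < 0) or np.any(center > np.array(grad.shape) - 1):
        raise ValueError("contour center outside the volume")
    theta = 2 * np.pi * np.arange(n) / n
    dirs = (np.cos(theta)[:, None] * frame.v2[None, :]
            + np.sin(theta)[:, None] * frame.v3[None, :])      # (n, 3)
    rho = params.rho_values.astype(float)                      # (n_rho,)
    pts = center[None, None, :] + rho[None, :, None] * dirs[:, None, :]
    g = grad.sample(pts.reshape(-1, 3)).reshape(n, len(rho), 3)
    mag = np.linalg.norm(g, axis=-1)
    informative = mag >= EPS_GRAD
    dots = np.einsum("krc,kc->kr", g, dirs)
    cosphi = np.where(informative, -dots / np.maximum(mag, 1e-300), 0.0)
    d = params.d
    w = d + 1
    r_vals = params.r_values
    csum = np.concatenate([np.zeros((n, 1)), np.cumsum(cosphi, axis=1)], axis=1)
    resp = np.stack([(csum[:, k + w] - csum[:, k]) / w
                     for k in range(len(r_vals))], axis=1)     # (n, n_r)
    best = np.array([_plateau_mid(resp[k]) for k in range(n)])
    radii = r_vals[best].astype(float)
    boundary = center[None, :] + radii[:, None] * dirs
    return Contour(center, frame, boundary, radii, curve_id, node_index)


def radius_band_params(params: FilterParams, R_min: int | None = None,
                       R_max: int | None = None) -> FilterParams:
    """Band parameters for radius estimation: same geometry, but the band
    width is clipped to the largest even value that keeps the innermost band
    off the center (``d <= 2 R_min``)."""
    R_min = params.R_min if R_min is None else R_min
    R_max = params.R_max if R_max is None else R_max
    d = min(params.d, 2 * R_min)
    d -= d % 2
    d = max(d, 2)
    return replace(params, d=d, R_min=R_min, R_max=R_max, band_norm="full")


def contours_for_trace(trace: NeuronTrace, grad: GradientField, n: int = 16,
                       params: FilterParams | None = None,
                       backoff_D: float = 10.0) -> list[Contour]:
    """One contour per curve node, skipping nodes within ``backoff_D``
    polyline distance of a branch point (radius estimation is ambiguous in
    the collision region); per-curve ``mean_radius`` and per-node ``radii``
    are updated on the trace in place."""
    params = radius_band_params(params if params is not None else FilterParams())
    out: list[Contour] = []
    bps = [np.asarray(p, float) for p, _, _ in trace.branch_points]
    for curve in trace.curves:
        s = arclengths(curve.nodes)
        skip = np.zeros(len(curve.nodes), dtype=bool)
        for bp in bps:
            dist = np.linalg.norm(curve.nodes - bp[None, :], axis=1)
            j = int(np.argmin(dist))
            if dist[j] <= backoff_D:
                skip |= np.abs(s - s[j]) <= backoff_D
        node_radii = np.full(len(curve.nodes), np.nan)
        for i in range(len(curve.nodes)):
            if skip[i]:
                continue
            frame = local_frame(curve, i)
            c = sbf_boundary(grad, curve.nodes[i], frame, n, params,
                             curve_id=curve.id, node_index=i)
            node_radii[i] = c.mean_radius
            out.append(c)
        if np.any(np.isfinite(node_radii)):
            curve.mean_radius = float(np.nanmean(node_radii))
            # nodes in the skipped junction zone inherit the nearest estimate
            good = np.nonzero(np.isfinite(node_radii))[0]
            for i in np.nonzero(~np.isfinite(node_radii))[0]:
                node_radii[i] = node_radii[good[np.argmin(np.abs(good - i))]]
        curve.radii = node_radii
    return out
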
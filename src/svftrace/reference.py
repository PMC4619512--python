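"""Naive reference implementations used as independent oracles.

Each function here recomputes a quantity with direct enumeration — plain
Python loops, hand-rolled trilinear interpolation, brute-force all-pairs
distances — sharing no code path with the optimised implementations they
check.  They are intentionally slow and meant for small inputs only.
"""

from __future__ import annotations

import numpy as np

from .filters import EPS_GRAD, FilterParams, GradientField


def trilinear(field: np.ndarray, p) -> float:
    """Hand-rolled trilinear interpolation; points outside the voxel-center
    hull return 0 (the package-wide out-of-bounds convention)."""
    x, y, z = float(p[0]), float(p[1]), float(p[2])
    nx, ny, nz = field.shape
    if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1 and 0 <= z <= nz - 1):
        return 0.0
    i0, j0, k0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
    fx, fy, fz = x - i0, y - j0, z - k0
    total = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                i, j, k = i0 + di, j0 + dj, k0 + dk
                if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
                    v = field[i, j, k]
                else:
                    v = 0.0
                w = ((fx if di else 1 - fx)
                     * (fy if dj else 1 - fy)
                     * (fz if dk else 1 - fz))
                total += w * v
    return total


def vci_naive(grad: GradientField, O, P, eps_grad: float = EPS_GRAD) -> float:
    g = np.array([trilinear(grad.vectors[c], P) for c in range(3)])
    mag = float(np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2))
    if mag < eps_grad:
        return 0.0
    v = np.asarray(O, float) - np.asarray(P, float)
    nv = float(np.linalg.norm(v))
    return float((g[0] * v[0] + g[1] * v[1] + g[2] * v[2]) / (mag * nv))


def svf_at_naive(grad: GradientField, O, params: FilterParams) -> float:
    """Direct triple-loop evaluation of the sliding volume filter: for every
    grid direction, every sliding position and every band sample, one VCI."""
    O = np.asarray(O, dtype=float)
    L = params.L
    d = params.d
    half = d // 2
    total = 0.0
    wsum = 0.0
    for j in range(L):
        b = np.pi * j / L
        w = np.sin(b)
        for i in range(2 * L):
            a = 2 * np.pi * i / (2 * L)
            u = np.array([np.sin(b) * np.cos(a),
                          np.sin(b) * np.sin(a),
                          np.cos(b)])
            best = -np.inf
            for r in range(params.R_min + 1, params.R_max):
                ssum = 0.0
                count = 0
                for rho in range(r - half, r + half + 1):
                    Q = O + rho * u
                    g = np.array([trilinear(grad.vectors[c], Q) for c in range(3)])
                    mag = float(np.linalg.norm(g))
                    if mag < EPS_GRAD:
                        continue
                    v = O - Q
                    ssum += float(g @ v) / (mag * float(np.linalg.norm(v)))
                    count += 1
                if params.band_norm == "full":
                    resp = ssum / (d + 1)
                elif count == 0:
                    resp = 0.0
                else:
                    resp = ssum / max(count, (d + 2) // 2)
                best = max(best, resp)
            total += w * best
            wsum += w
    return total / wsum


def sbf_radii_naive(grad: GradientField, center, frame, n: int,
                    params: FilterParams, plateau_tol: float = 0.01) -> np.ndarray:
    """Exhaustive per-ray scan of every band position (full normalisation);
    the winning radius is the midpoint of the contiguous run of responses
    within ``plateau_tol`` of the maximum."""
    center = np.asarray(center, dtype=float)
    half = params.d // 2
    r_list = list(range(params.R_min + 1, params.R_max))
    radii = np.empty(n)
    for k in range(n):
        theta = 2 * np.pi * k / n
        u = np.cos(theta) * frame.v2 + np.sin(theta) * frame.v3
        resps = []
        for r in r_list:
            ssum = 0.0
            for rho in range(r - half, r + half + 1):
                Q = center + rho * u
                g = np.array([trilinear(grad.vectors[c], Q) for c in range(3)])
                mag = float(np.linalg.norm(g))
                if mag < EPS_GRAD:
                    continue
                v = center - Q
                ssum += float(g @ v) / (mag * float(np.linalg.norm(v)))
            resps.append(ssum / (params.d + 1))
        best = max(resps)
        j = resps.index(best)
        lo = j
        while lo > 0 and resps[lo - 1] >= best - plateau_tol:
            lo -= 1
        hi = j
        while hi < len(resps) - 1 and resps[hi + 1] >= best - plateau_tol:
            hi += 1
        radii[k] = r_list[(lo + hi) // 2]
    return radii


def point_deviation_naive(P_s, P_g) -> float:
    """All-pairs brute-force nearest-neighbour mean distance."""
    P_s = np.atleast_2d(np.asarray(P_s, dtype=float))
    P_g = np.atleast_2d(np.asarray(P_g, dtype=float))
    dmin = [float(np.min(np.linalg.norm(P_g - p[None, :], axis=1)))
            for p in P_s]
    return float(np.mean(dmin))
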
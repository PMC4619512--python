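"""Seed selection: threshold the SVF response, then keep the candidates that
sit on a genuine intensity ridge.

The ridge criterion asks that the image gradient at a seed be orthogonal to
the two Hessian eigenvectors spanning the tube cross-section (``|ev2 . grad|``
and ``|ev3 . grad|`` below a small tolerance).  At integer voxel positions of
discrete data this condition is satisfiable only *at* the sub-voxel ridge
point — any voxel a fraction off the centerline has a cross-plane gradient
orders of magnitude above the tolerance.  Following the ridge-traversal
literature the criterion is therefore evaluated at the Newton-refined in-plane
ridge point: a seed is kept when (a) the cross-sectional Hessian is negative
definite (a bright ridge), (b) Newton steps within the cross-sectional plane
converge to a point with both cross-plane gradient projections below
``ridge_tol``, and (c) that ridge point lies within ``step_limit`` voxels of
the seed.  Seed positions themselves stay on the voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .filters import EPS_GRAD, GradientField, ResponseVolume
from .volume import Volume


@dataclass
class HessianInfo:
    """Eigen-decomposition of the Gaussian-scale Hessian at one point,
    ordered by eigenvalue magnitude ``|l1| <= |l2| <= |l3|``; ``ev1`` is the
    tube's axial direction, ``ev2``/``ev3`` span the cross-section."""

    eigenvalues: np.ndarray   # (3,)
    eigenvectors: np.ndarray  # (3, 3), rows ev1, ev2, ev3
    sigma: float

    @property
    def ev1(self):
        return self.eigenvectors[0]

    @property
    def ev2(self):
        return self.eigenvectors[1]

    @property
    def ev3(self):
        return self.eigenvectors[2]


@dataclass
class SeedPoint:
    """A candidate centerline voxel with its SVF response and the id of the
    curve that owns it (0 = unclaimed)."""

    position: np.ndarray
    response: float
    label: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


_HKEYS = ("xx", "xy", "xz", "yy", "yz", "zz")


def hessian_field(volume: Volume, sigma: float) -> dict:
    """All six Gaussian second-derivative volumes at scale ``sigma`` (cached
    on the volume)."""
    key = ("hessian", float(sigma))
    if key not in volume._cache:
        orders = {"xx": (2, 0, 0), "xy": (1, 1, 0), "xz": (1, 0, 1),
                  "yy": (0, 2, 0), "yz": (0, 1, 1), "zz": (0, 0, 2)}
        volume._cache[key] = {
            k: ndimage.gaussian_filter(volume.data, sigma, order=o, mode="nearest")
            for k, o in orders.items()
        }
    return volume._cache[key]


def _hessian_matrix_at(volume: Volume, p: np.ndarray, sigma: float) -> np.ndarray:
    fields = hessian_field(volume, sigma)
    coords = np.asarray(p, dtype=float)[:, None]
    vals = {k: ndimage.map_coordinates(fields[k], coords, order=1,
                                       mode="nearest", prefilter=False)[0]
            for k in _HKEYS}
    return np.array([[vals["xx"], vals["xy"], vals["xz"]],
                     [vals["xy"], vals["yy"], vals["yz"]],
                     [vals["xz"], vals["yz"], vals["zz"]]])


def hessian_at(volume: Volume, p, sigma_h: float = 1.5) -> HessianInfo:
    """Gaussian-derivative Hessian at ``p`` (trilinear between voxels),
    eigen-ordered by magnitude with deterministic eigenvector signs (largest
    magnitude component made positive)."""
    if sigma_h <= 0:
        raise ValueError("sigma_h must be positive")
    p = np.asarray(p, dtype=float)
    if not volume.in_bounds(p):
        raise ValueError(f"point {p} outside the volume")
    H = _hessian_matrix_at(volume, p, sigma_h)
    lam, vec = np.linalg.eigh(H)         # ascending by value
    order = np.argsort(np.abs(lam), kind="stable")
    lam = lam[order]
    vec = vec[:, order].T                # rows are eigenvectors
    for i in range(3):
        j = np.argmax(np.abs(vec[i]))
        if vec[i, j] < 0:
            vec[i] = -vec[i]
    return HessianInfo(lam, vec, sigma_h)


def threshold_seeds(response: ResponseVolume, T: float) -> list[SeedPoint]:
    """All voxels with SVF response strictly above ``T``, unlabeled."""
    if not (-1.0 < T < 1.0):
        raise ValueError("threshold T must lie in (-1, 1)")
    idx = np.argwhere(response.values > T)
    vals = response.values[tuple(idx.T)]
    return [SeedPoint(pos.astype(float), float(v)) for pos, v in zip(idx, vals)]


def ridge_filter(raw: list[SeedPoint], volume: Volume, grad: GradientField,
                 sigma_h: float = 1.5, tol: float = 1e-3,
                 step_limit: float = 1.5, max_iter: int = 15) -> list[SeedPoint]:
    """Keep seeds whose cross-plane gradient projections vanish (below
    ``tol``, intensity units per voxel on the [0, 255] scale) at the
    Newton-refined ridge point within ``step_limit`` voxels of the seed."""
    if tol <= 0:
        raise ValueError("ridge tolerance must be positive")
    kept = []
    hi = np.array(volume.shape, dtype=float) - 1
    for seed in raw:
        p = seed.position
        info = hessian_at(volume, p, sigma_h)
        # bright ridge: cross-sectional curvatures both negative
        if info.eigenvalues[1] >= 0 or info.eigenvalues[2] >= 0:
            continue
        E = info.eigenvectors[1:]        # (2, 3) cross-plane basis
        q = p.copy()
        ok = False
        for _ in range(max_iter):
            g = grad.sample(q[None, :])[0]
            c = E @ g
            if np.all(np.abs(c) < tol):
                ok = True
                break
            H = _hessian_matrix_at(volume, q, sigma_h)
            Hp = E @ H @ E.T             # 2x2 in-plane Hessian
            try:
                delta = np.linalg.solve(Hp, -c)
            except np.linalg.LinAlgError:
                break
            step = np.clip(delta, -1.0, 1.0)  # guard wild steps
            q = q + step @ E
            if np.linalg.norm(q - p) > step_limit:
                break
            if np.any(q < 0) or np.any(q > hi):
                break
        if ok and np.linalg.norm(q - p) <= step_limit:
            kept.append(seed)
    return kept


@dataclass
class SeedList:
    """Seeds in descending-response order with a spatial index and mutable
    curve-ownership labels."""

    positions: np.ndarray            # (n, 3)
    responses: np.ndarray            # (n,)
    labels: np.ndarray = None        # (n,) int, 0 = unclaimed
    _tree: cKDTree = field(default=None, repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.labels is None:
            self.labels = np.zeros(len(self.positions), dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.positions):
            self._tree = cKDTree(self.positions)

    def __len__(self):
        return len(self.positions)

    def __iter__(self):
        for pos, resp, lab in zip(self.positions, self.responses, self.labels):
            yield SeedPoint(pos, float(resp), int(lab))

    def first_unlabeled(self) -> int | None:
        """Index of the strongest unclaimed seed (list is response-sorted)."""
        idx = np.nonzero(self.labels == 0)[0]
        return int(idx[0]) if len(idx) else None

    def within(self, points: np.ndarray, radius: float) -> np.ndarray:
        """Indices of seeds within ``radius`` of any of ``points``."""
        if self._tree is None:
            return np.array([], dtype=int)
        points = np.atleast_2d(points)
        hits = self._tree.query_ball_point(points, radius)
        if len(hits) == 0:
            return np.array([], dtype=int)
        flat = sorted({i for sub in hits for i in sub})
        return np.array(flat, dtype=int)

    def claim(self, indices, curve_id: int, only_unlabeled: bool = True) -> None:
        indices = np.asarray(indices, dtype=int)
        if only_unlabeled:
            indices = indices[self.labels[indices] == 0]
        self.labels[indices] = curve_id


def build_seed_list(seeds: list[SeedPoint], min_spacing: float = 2.0) -> SeedList:
    """Sort by descending response (ties broken by lexicographic position for
    determinism) and greedily drop any seed within ``min_spacing`` of an
    already accepted, stronger seed."""
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    if not seeds:
        return SeedList(np.empty((0, 3)), np.empty(0))
    pos = np.array([s.position for s in seeds], dtype=float)
    resp = np.array([s.response for s in seeds], dtype=float)
    order = np.lexsort((pos[:, 2], pos[:, 1], pos[:, 0], -resp))
    pos, resp = pos[order], resp[order]
    if min_spacing == 0:
        return SeedList(pos, resp)
    accepted: list[int] = []
    tree_pts: list[np.ndarray] = []
    for i in range(len(pos)):
        p = pos[i]
        if tree_pts:
            d = np.linalg.norm(np.asarray(tree_pts) - p[None, :], axis=1)
            if np.any(d < min_spacing):
                continue
        accepted.append(i)
        tree_pts.append(p)
    return SeedList(pos[accepted], resp[accepted])
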
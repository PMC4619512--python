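"""Open-curve-snake tracing driven by the SVF-enhanced volume.

A snake is an ordered 3-D polyline ``c(s)``, ``s`` in [0, 1], that minimises
the sum of an internal smoothness energy (elasticity ``alpha`` on ``|c_s|^2``
and stiffness ``beta`` on ``|c_ss|^2``, with ``beta = 0`` at the free end
points) and an external image energy.  The external force has two parts:

* the normalised gradient vector flow (GVF) of the enhanced volume, a
  diffusion-regularised edge force that pulls every node toward the
  centerline, and
* a stretching force applied only at the two end nodes, directed along the
  outward tangent with magnitude ``| sqrt(|l2 l3|) / (|l1| + 0.01) - 1 |``
  computed from the local Hessian eigenvalues — large inside a tube (the
  cross-sectional curvatures ``l2, l3`` dwarf the axial ``l1``) and ~0 where
  the structure becomes isotropic, so ends stop growing when the tube ends.

Nodes are updated semi-implicitly, ``x_t = (gamma I + A)^{-1} (gamma x_{t-1}
+ F(x_{t-1}))`` per coordinate, where ``A`` is the pentadiagonal internal
operator.  Curves grow from seeds, extend from both ends, claim nearby seeds
with their id, and register a branch point when a growing end reaches a seed
already claimed by another curve; the colliding end is then cut back by a
distance ``D`` (twice the running radius estimate) so that cross-section
contours from the two curves cannot intersect near the junction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .filters import GradientField
from .geometry import arclengths, polyline_length, resample_polyline
from .seeding import SeedList, SeedPoint, hessian_at
from .volume import Volume

_curve_counter = itertools.count(1)


class SnakeStateError(RuntimeError):
    pass


@dataclass
class SnakeParams:
    """Tunables of the open-curve snake (voxel units throughout).

    Defaults follow the standard parameterisation for confocal stacks:
    alpha 0.8, beta 0.2 (0 at ends), gamma 2, at most 10 deformation steps
    per extension.  ``claim_radius`` of None means ``max(2, radius
    estimate)``; the radius estimate starts at ``init_radius`` and the
    collision backoff distance is ``backoff_factor`` times it (double the
    average estimated radius by default).  ``bg_floor`` stops an end that
    keeps sampling empty background, ``stretch_eps`` is the tubeness level
    below which an end is considered converged.
    """

    alpha: float = 0.8
    beta: float = 0.2
    gamma: float = 2.0
    t_max: int = 10
    extend_step: float = 1.5
    node_spacing: float = 1.5
    stretch_eps: float = 0.2
    claim_radius: float | None = None
    backoff_factor: float = 2.0
    init_radius: float = 5.0
    stretch_cap: float = 1.0
    bg_floor: float = 1.0
    sigma_h: float = 1.5
    converge_runs: int = 3
    bg_runs: int = 2
    max_nodes: int = 400

    def __post_init__(self):
        if self.alpha <= 0 or self.gamma <= 0 or self.beta < 0:
            raise ValueError("need alpha, gamma > 0 and beta >= 0")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not (0 < self.extend_step <= 3):
            raise ValueError("extend_step must lie in (0, 3]")
        if self.backoff_factor <= 0:
            raise ValueError("backoff_factor must be positive")

    def effective_claim_radius(self, mean_radius: float) -> float:
        if self.claim_radius is not None:
            return self.claim_radius
        return max(2.0, float(mean_radius))


@dataclass
class FlowField:
    """Unit-capped external force field: the normalised GVF of the enhanced
    volume (the negative image-energy gradient)."""

    vectors: np.ndarray  # (3, nx, ny, nz)
    mu: float = 0.1
    n_iters: int = 50

    @property
    def shape(self):
        return self.vectors.shape[1:]

    def sample(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty((pts.shape[0], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.vectors[c], pts.T, order=1, mode="constant", cval=0.0,
                prefilter=False)
        return out


@dataclass
class SnakeCurve:
    """One traced open curve with per-end growth state."""

    id: int
    nodes: np.ndarray                       # (n, 3)
    state: dict = field(default_factory=lambda: {"head": "growing",
                                                 "tail": "growing"})
    branch_hits: list = field(default_factory=list)   # (position, other_id)
    mean_radius: float = 5.0
    radii: np.ndarray | None = None         # per-node, set by radius module
    _calm: dict = field(default_factory=lambda: {"head": 0, "tail": 0},
                        repr=False)
    _bg: dict = field(default_factory=lambda: {"head": 0, "tail": 0},
                      repr=False)
    _stall: dict = field(default_factory=lambda: {"head": 0, "tail": 0},
                         repr=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def end_node(self, end: str) -> np.ndarray:
        return self.nodes[0] if end == "head" else self.nodes[-1]

    def outward_tangent(self, end: str) -> np.ndarray:
        if end == "head":
            v = self.nodes[0] - self.nodes[1]
        else:
            v = self.nodes[-1] - self.nodes[-2]
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise FloatingPointError("degenerate tangent: coincident end nodes")
        return v / n

    @property
    def growing(self) -> bool:
        return "growing" in self.state.values()

    def length(self) -> float:
        return polyline_length(self.nodes)


@dataclass
class NeuronTrace:
    """The full tracing result: curves plus the branch-point registry
    (position on the parent curve, parent id, child id)."""

    curves: list = field(default_factory=list)
    branch_points: list = field(default_factory=list)

    def curve_by_id(self, cid: int) -> SnakeCurve:
        for c in self.curves:
            if c.id == cid:
                return c
        raise KeyError(f"no curve with id {cid}")

    def total_length(self) -> float:
        return sum(c.length() for c in self.curves)


# ---------------------------------------------------------------------------
# external force field


def compute_gvf(enhanced: Volume, mu: float = 0.1, n_iters: int = 50,
                dt: float | None = None) -> FlowField:
    """Gradient vector flow of the enhanced volume, unit-normalised.

    Iterates ``u <- u + dt (mu lap(u) - (u - grad f) |grad f|^2)`` on the
    unit-scaled image ``f``, starting from ``u = grad f``; ``dt`` defaults to
    ``min(1, 1/(6 mu))`` (the explicit-diffusion stability bound).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if n_iters < 0:
        raise ValueError("n_iters must be >= 0")
    fmax = enhanced.data.max()
    f = enhanced.data / fmax if fmax > 0 else enhanced.data
    g = np.stack(np.gradient(f))
    if dt is None:
        dt = min(1.0, 1.0 / (6.0 * mu))
    mag2 = np.sum(g * g, axis=0)
    u = g.copy()
    for _ in range(n_iters):
        for c in range(3):
            u[c] += dt * (mu * ndimage.laplace(u[c], mode="nearest")
                          - (u[c] - g[c]) * mag2)
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("GVF iteration diverged")
    mag = np.sqrt(np.sum(u * u, axis=0))
    scale = np.where(mag > 1e-8, 1.0 / np.maximum(mag, 1e-300), 0.0)
    return FlowField(u * scale[None], mu=mu, n_iters=n_iters)


# ---------------------------------------------------------------------------
# internal energy operator


def internal_matrix(n_nodes: int, params: SnakeParams,
                    spacing: float = 1.0) -> np.ndarray:
    """Pentadiagonal internal-energy operator for an open curve.

    Interior rows carry the elasticity term ``alpha * (-c_ss)`` (standard
    [-1, 2, -1] stencil over ``spacing**2``); the two end rows carry no
    elasticity constraint (free ends, driven purely by the external and
    stretching forces).  The stiffness term is ``beta * c_ssss`` assembled as
    ``D2^T diag(beta) D2`` with ``beta = 0`` at the end nodes.  Straight
    evenly spaced curves are exact null vectors, and every row sums to zero.
    """
    if n_nodes < 3:
        raise ValueError("an open snake needs at least 3 nodes")
    n = n_nodes
    h2 = spacing * spacing
    A = np.zeros((n, n))
    for i in range(1, n - 1):
        A[i, i - 1] -= params.alpha / h2
        A[i, i] += 2 * params.alpha / h2
        A[i, i + 1] -= params.alpha / h2
    if params.beta > 0 and n >= 4:
        D2 = np.zeros((n - 2, n))
        for i in range(n - 2):
            D2[i, i] = 1.0
            D2[i, i + 1] = -2.0
            D2[i, i + 2] = 1.0
        A += params.beta * (D2.T @ D2) / (h2 * h2)
    return A


# ---------------------------------------------------------------------------
# forces


def tubeness_magnitude(eigenvalues: np.ndarray) -> float:
    """``| sqrt(|l2 l3|) / (|l1| + 0.01) - 1 |`` for magnitude-ordered
    eigenvalues — the tube-likeness used by the stretching force."""
    l1, l2, l3 = eigenvalues
    return float(abs(np.sqrt(abs(l2 * l3)) / (abs(l1) + 0.01) - 1.0))


def _bright_ridge(eigenvalues: np.ndarray) -> bool:
    """Both cross-sectional curvatures negative: the point sits on a bright
    ridge (or blob), the only structures a snake end should stretch along."""
    return eigenvalues[1] < 0 and eigenvalues[2] < 0


def _strong_saddle(eigenvalues: np.ndarray, ratio: float = 0.25) -> bool:
    """A clearly positive cross-plane curvature against a negative one marks
    the bright wedge between two diverging branches — definitive evidence
    the end has left a tube (noise alone rarely flips a curvature this
    far)."""
    l2, l3 = eigenvalues[1], eigenvalues[2]
    a, m = max(l2, l3), min(l2, l3)
    return m < 0 and a > ratio * abs(m)


def stretch_force(curve: SnakeCurve, end: str, volume: Volume,
                  sigma_h: float = 1.5, stretch_eps: float = 0.2,
                  cap: float = 1.0) -> np.ndarray:
    """Outward tangential stretching force at one end node.

    Magnitude is the tubeness level of the local Hessian, capped at ``cap``
    so it stays commensurate with the unit-normalised flow field; below
    ``stretch_eps`` the force is zero (the end has left the tube)."""
    if curve.n_nodes < 2:
        raise ValueError("curve needs at least 2 nodes for a tangent")
    t = curve.outward_tangent(end)
    p = np.clip(curve.end_node(end), 0, np.array(volume.shape) - 1)
    info = hessian_at(volume, p, sigma_h)
    if not _bright_ridge(info.eigenvalues):
        return np.zeros(3)
    mag = tubeness_magnitude(info.eigenvalues)
    if mag < stretch_eps:
        return np.zeros(3)
    return t * min(mag, cap)


def _external_force(curve: SnakeCurve, flow: FlowField, volume: Volume,
                    params: SnakeParams) -> np.ndarray:
    F = flow.sample(curve.nodes)
    for end, idx in (("head", 0), ("tail", -1)):
        if curve.state[end] == "growing":
            F[idx] += stretch_force(curve, end, volume, params.sigma_h,
                                    params.stretch_eps, params.stretch_cap)
    return F


# ---------------------------------------------------------------------------
# deformation / extension


def deform_curve(curve: SnakeCurve, flow: FlowField, volume: Volume,
                 params: SnakeParams) -> SnakeCurve:
    """Up to ``t_max`` semi-implicit update steps followed by arclength
    resampling to ``node_spacing``; nodes are clamped to the volume."""
    hi = np.array(volume.shape, dtype=float) - 1
    n = curve.n_nodes
    A = internal_matrix(n, params, params.node_spacing)
    M = params.gamma * np.eye(n) + A
    x = curve.nodes.copy()
    for _ in range(params.t_max):
        work = SnakeCurve(curve.id, x, state=curve.state,
                          mean_radius=curve.mean_radius)
        F = _external_force(work, flow, volume, params)
        x = np.linalg.solve(M, params.gamma * x + F)
        np.clip(x, 0.0, hi, out=x)
    x = resample_polyline(x, params.node_spacing)
    if len(x) < 3:
        x = resample_polyline(x, params.node_spacing, keep_n=3)
    curve.nodes = x
    return curve


def init_curve(seed: SeedPoint, volume: Volume, sigma_h: float = 1.5,
               extend_step: float = 1.5, curve_id: int | None = None) -> SnakeCurve:
    """Three collinear nodes through the seed along the principal (axial)
    Hessian direction; the seed becomes the property of the new curve."""
    if seed.label != 0:
        raise SnakeStateError(f"seed at {seed.position} already claimed "
                              f"by curve {seed.label}")
    if curve_id is None:
        curve_id = next(_curve_counter)
    info = hessian_at(volume, seed.position, sigma_h)
    ev1 = info.ev1
    hi = np.array(volume.shape, dtype=float) - 1
    nodes = np.array([
        np.clip(seed.position - extend_step * ev1, 0, hi),
        seed.position,
        np.clip(seed.position + extend_step * ev1, 0, hi),
    ])
    seed.label = curve_id
    return SnakeCurve(curve_id, nodes)


def extend_and_label(curve: SnakeCurve, seeds: SeedList, flow: FlowField,
                     volume: Volume, params: SnakeParams) -> SnakeCurve:
    """One growth round: append a node at each growing end along the outward
    tangent, deform, update per-end convergence state, and claim all
    unclaimed seeds within the claim radius of the curve."""
    if not curve.growing:
        raise SnakeStateError("both ends of the curve have stopped")
    hi = np.array(volume.shape, dtype=float) - 1
    before = {end: curve.end_node(end).copy() for end in ("head", "tail")}
    for end in ("head", "tail"):
        if curve.state[end] != "growing":
            continue
        t = curve.outward_tangent(end)
        new = curve.end_node(end) + params.extend_step * t
        if np.any(new < 0) or np.any(new > hi):
            curve.state[end] = "converged"
            continue
        if end == "head":
            curve.nodes = np.vstack([new, curve.nodes])
        else:
            curve.nodes = np.vstack([curve.nodes, new])
    deform_curve(curve, flow, volume, params)

    for end in ("head", "tail"):
        if curve.state[end] != "growing":
            continue
        p = curve.end_node(end)
        info = hessian_at(volume, p, params.sigma_h)
        if _strong_saddle(info.eigenvalues):
            curve.state[end] = "converged"
            continue
        mag = (tubeness_magnitude(info.eigenvalues)
               if _bright_ridge(info.eigenvalues) else 0.0)
        curve._calm[end] = curve._calm[end] + 1 if mag < params.stretch_eps else 0
        intensity = ndimage.map_coordinates(
            volume.data, p[:, None], order=1, mode="constant", cval=0.0,
            prefilter=False)[0]
        curve._bg[end] = curve._bg[end] + 1 if intensity < params.bg_floor else 0
        # an end that cannot advance (image forces cancel the extension,
        # e.g. against a bright cap or the volume border) has converged too
        moved = np.linalg.norm(p - before[end])
        curve._stall[end] = (curve._stall[end] + 1
                             if moved < 0.5 * params.extend_step else 0)
        if (curve._calm[end] >= params.converge_runs
                or curve._bg[end] >= params.bg_runs
                or curve._stall[end] >= params.converge_runs):
            curve.state[end] = "converged"
    if curve.n_nodes >= params.max_nodes:
        for end in ("head", "tail"):
            if curve.state[end] == "growing":
                curve.state[end] = "converged"

    claim_r = params.effective_claim_radius(curve.mean_radius)
    idx = seeds.within(curve.nodes, claim_r)
    seeds.claim(idx, curve.id)
    return curve


def detect_collision(curve: SnakeCurve, seeds: SeedList,
                     params: SnakeParams):
    """If a growing end is within the claim radius of a seed owned by a
    *different* curve, mark that end collided and return the branch event
    ``(seed_position, other_id)``; self-owned seeds are ignored."""
    claim_r = params.effective_claim_radius(curve.mean_radius)
    event = None
    for end in ("head", "tail"):
        if curve.state[end] != "growing":
            continue
        p = curve.end_node(end)
        idx = seeds.within(p[None, :], claim_r)
        foreign = idx[(seeds.labels[idx] != 0) & (seeds.labels[idx] != curve.id)]
        if len(foreign) == 0:
            continue
        d = np.linalg.norm(seeds.positions[foreign] - p[None, :], axis=1)
        j = int(foreign[np.argmin(d)])
        hit = (seeds.positions[j].copy(), int(seeds.labels[j]))
        curve.branch_hits.append(hit)
        curve.state[end] = "collided"
        if event is None:
            event = hit
    return event


def backoff(curve: SnakeCurve, end: str, D: float) -> SnakeCurve:
    """Cut the collided end back by polyline length ``D`` (never below 3
    nodes); the branch registry is untouched."""
    if D < 0:
        raise ValueError("backoff distance must be >= 0")
    if D == 0:
        return curve
    removed = 0.0
    while curve.n_nodes > 3 and removed < D:
        if end == "head":
            removed += np.linalg.norm(curve.nodes[0] - curve.nodes[1])
            curve.nodes = curve.nodes[1:]
        else:
            removed += np.linalg.norm(curve.nodes[-1] - curve.nodes[-2])
            curve.nodes = curve.nodes[:-1]
    return curve


# ---------------------------------------------------------------------------
# driver


def trace_all(volume: Volume, seeds: SeedList, flow: FlowField,
              params: SnakeParams | None = None) -> NeuronTrace:
    """Trace every structure the seed list supports.

    Repeatedly pops the strongest unclaimed seed, initialises a snake there,
    grows it until both ends stop (converged or collided), applies the
    collision backoff, and accepts the curve if it still has >= 3 nodes.
    Branch events are registered at the node of the *other* curve nearest to
    the collision seed — the best available estimate of the junction.
    Deterministic for identical inputs.
    """
    if params is None:
        params = SnakeParams()
    trace = NeuronTrace()
    next_id = 1
    while True:
        i = seeds.first_unlabeled()
        if i is None:
            break
        seed = SeedPoint(seeds.positions[i], float(seeds.responses[i]))
        curve = init_curve(seed, volume, params.sigma_h, params.extend_step,
                           curve_id=next_id)
        next_id += 1
        seeds.claim(np.array([i]), curve.id)
        curve.mean_radius = params.init_radius
        rounds = 0
        while curve.growing and rounds < 4 * params.max_nodes:
            extend_and_label(curve, seeds, flow, volume, params)
            if curve.growing:
                detect_collision(curve, seeds, params)
            rounds += 1
        # junction estimate per hit: the node of the other curve nearest to
        # the collision seed
        events = []
        for hit_pos, other_id in curve.branch_hits:
            try:
                other = trace.curve_by_id(other_id)
            except KeyError:
                continue
            j = int(np.argmin(np.linalg.norm(other.nodes - hit_pos[None, :],
                                             axis=1)))
            events.append((other.nodes[j].copy(), other_id))
        # cut a collided end back to distance D from the junction it reached
        # (the end usually stops short of the junction already, so only the
        # missing length is trimmed)
        D = params.backoff_factor * curve.mean_radius
        for end, st in list(curve.state.items()):
            if st != "collided":
                continue
            p = curve.end_node(end)
            gap = min((float(np.linalg.norm(p - bp)) for bp, _ in events),
                      default=0.0)
            backoff(curve, end, max(0.0, D - gap))
        if curve.n_nodes >= 3:
            trace.curves.append(curve)
            for bp, other_id in events:
                trace.branch_points.append((bp, other_id, curve.id))
    return trace
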
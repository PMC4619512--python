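"""Synthetic tubular phantoms with known centerlines.

Generates tube, helix and Y-branch volumes whose analytic skeletons serve as
gold standards for the seeding, tracing and radius-estimation stages.  Tubes
are rendered with 3x-per-axis supersampling followed by box averaging so that
thin structures are anti-aliased, with one of two radial intensity profiles:

``cosine``
    ``I(rho) = peak * cos^2(pi * rho / (2 r))`` for ``rho <= r``, else 0 —
    bright on the centerline, smoothly falling to zero at the wall, which is
    the tube-like convex region the sliding filter is designed around.
``hard``
    a binary disk of value ``peak`` — all intensity gradient concentrated at
    the wall, useful for edge-localisation (radius recovery) experiments.

Signal attenuation and additive Gaussian noise reproduce the robustness
protocol conditions (signal reduced by 10-40 %, noise variances 0.01-0.04 on
the unit intensity scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .volume import Volume

SUPERSAMPLE = 3  # sub-samples per axis when rasterising tubes


class PhantomDomainError(ValueError):
    """Raised when requested geometry does not fit the volume."""


@dataclass
class Phantom:
    """A synthetic volume plus its ground truth.

    ``centerlines`` holds one densely sampled (<= 0.5 voxel steps) polyline
    per tube segment; ``radius_profiles`` the matching per-sample radii.
    """

    volume: Volume
    centerlines: list = field(default_factory=list)
    radius_profiles: list = field(default_factory=list)
    branch_points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        hi = np.array(self.volume.shape, dtype=float) - 1
        for pts, rads in zip(self.centerlines, self.radius_profiles):
            pts = np.asarray(pts, float)
            if np.any(pts < 0) or np.any(pts > hi):
                raise PhantomDomainError("centerline exits the volume bounds")
            rads = np.asarray(rads, float)
            if np.any(rads <= 0) or np.any(rads >= min(self.volume.shape) / 2):
                raise PhantomDomainError("radius profile out of sensible range")

    @property
    def centerline(self) -> np.ndarray:
        """All ground-truth centerline samples, concatenated."""
        return np.concatenate([np.asarray(c, float) for c in self.centerlines])

    @property
    def radius_profile(self) -> np.ndarray:
        return np.concatenate([np.asarray(r, float) for r in self.radius_profiles])


# ---------------------------------------------------------------------------
# curve sampling helpers


def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arclength ``step``; returns (points, s)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1], np.zeros(1)
    n = max(2, int(np.ceil(total / step)) + 1)
    si = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])
    return out, si


def _sample_curve(curve, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Sample a parametric curve (callable on [0,1]) or polyline at ``step``."""
    if callable(curve):
        t = np.linspace(0.0, 1.0, 512)
        pts = np.asarray([curve(ti) for ti in t], dtype=float)
    else:
        pts = np.asarray(curve, dtype=float)
        if pts.ndim == 1:
            pts = pts[None, :]
    if len(pts) < 2:
        raise PhantomDomainError("curve must contain at least two points")
    return _resample_polyline(pts, step)


# ---------------------------------------------------------------------------
# rasterisation


def _profile(rho: np.ndarray, r: np.ndarray, peak: float, falloff: str) -> np.ndarray:
    inside = rho <= r
    if falloff == "cosine":
        out = np.where(inside, peak * np.cos(np.pi * rho / (2.0 * np.maximum(r, 1e-9))) ** 2, 0.0)
    elif falloff == "hard":
        out = np.where(inside, float(peak), 0.0)
    else:
        raise ValueError(f"unknown falloff profile {falloff!r}")
    return out


def render_tubes(segments, peak, falloff, shape) -> Volume:
    """Rasterise tube fields around sampled centerlines; voxel value is the
    max over tubes (branches overlap additively nowhere, they just merge).

    ``segments`` is a list of ``(points, radii)`` pairs with per-sample radii.
    """
    nx, ny, nz = shape
    trees = []
    rmax_all = 0.0
    for pts, rads in segments:
        trees.append((cKDTree(pts), np.asarray(rads, float)))
        rmax_all = max(rmax_all, float(np.max(rads)))

    ss = SUPERSAMPLE
    off = (np.arange(ss) - (ss - 1) / 2.0) / ss  # sub-voxel offsets
    xs = (np.arange(nx)[:, None] + off[None, :]).ravel()
    ys = (np.arange(ny)[:, None] + off[None, :]).ravel()
    data = np.zeros((nx, ny, nz), dtype=np.float64)

    # process z-slabs to bound memory
    slab = max(1, int(2e6 // (nx * ny * ss * ss)))
    for z0 in range(0, nz, slab):
        z1 = min(nz, z0 + slab)
        zs = (np.arange(z0, z1)[:, None] + off[None, :]).ravel()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        acc = np.zeros(len(pts), dtype=np.float64)
        for tree, rads in trees:
            dist, idx = tree.query(pts, k=1, distance_upper_bound=rmax_all + 0.75)
            hit = np.isfinite(dist)
            if np.any(hit):
                vals = _profile(dist[hit], rads[np.minimum(idx[hit], len(rads) - 1)],
                                peak, falloff)
                field = np.zeros_like(acc)
                field[hit] = vals
                np.maximum(acc, field, out=acc)
        acc = acc.reshape(nx, ss, ny, ss, z1 - z0, ss)
        data[:, :, z0:z1] = acc.mean(axis=(1, 3, 5))
    return Volume(np.clip(data, 0.0, 255.0))


# ---------------------------------------------------------------------------
# phantom constructors


def make_tube(centerline, radius, peak_intensity: float = 200.0,
              falloff: str = "cosine", shape=(64, 64, 64)) -> Phantom:
    """A single tube around an arbitrary curve.

    ``radius`` is a scalar or a function of arclength (voxels); it must be
    >= 2 voxels everywhere (thinner tubes alias even with supersampling).
    """
    pts, s = _sample_curve(centerline)
    if callable(radius):
        rads = np.asarray([radius(si) for si in s], dtype=float)
    else:
        rads = np.full(len(pts), float(radius))
    if np.any(rads < 2):
        raise PhantomDomainError("tube radius must be >= 2 voxels")
    hi = np.array(shape, dtype=float) - 1
    if np.any(pts < 0) or np.any(pts > hi):
        raise PhantomDomainError("centerline curve exits the volume bounds")
    vol = render_tubes([(pts, rads)], peak_intensity, falloff, shape)
    return Phantom(vol, [pts], [rads])


def helix_centerline(helix_radius: float, pitch: float, turns: float,
                     shape, step: float = 0.25) -> np.ndarray:
    """Analytic helix centered in the x-y plane of ``shape``, sampled at
    <= ``step`` voxel arc increments."""
    if turns <= 0:
        raise PhantomDomainError("helix needs a positive number of turns")
    cx, cy = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    height = pitch * turns
    z0 = (shape[2] - 1 - height) / 2.0
    arclen = turns * 2 * np.pi * np.hypot(helix_radius, pitch / (2 * np.pi))
    n = max(8, int(np.ceil(arclen / step)) + 1)
    theta = np.linspace(0.0, 2 * np.pi * turns, n)
    return np.column_stack([
        cx + helix_radius * np.cos(theta),
        cy + helix_radius * np.sin(theta),
        z0 + pitch * theta / (2 * np.pi),
    ])


def make_helix(helix_radius: float = 18.0, pitch: float = 20.0, turns: float = 2.0,
               tube_radius: float = 4.0, shape=(64, 64, 64),
               peak_intensity: float = 200.0, falloff: str = "cosine") -> Phantom:
    """The reference helix phantom.

    Defaults (64^3, helix radius 18, pitch 20, 2 turns, tube radius 4,
    peak 200, cosine falloff) are the repository's fixed reference conditions
    for the seeding and tracing experiments.
    """
    pts = helix_centerline(helix_radius, pitch, turns, shape)
    margin = tube_radius
    hi = np.array(shape, dtype=float) - 1
    if np.any(pts - margin < 0) or np.any(pts + margin > hi):
        raise PhantomDomainError("helix plus tube radius exceeds the volume bounds")
    return make_tube(pts, tube_radius, peak_intensity, falloff, shape)


def make_y_branch(trunk_dir=(0.0, 0.0, 1.0), branch_angle: float = 60.0,
                  radii=(5.0, 4.0, 4.0), shape=(64, 64, 64),
                  peak_intensity: float = 200.0, falloff: str = "cosine") -> Phantom:
    """A symmetric Y: one trunk splitting into two branches at the volume
    center.  ``branch_angle`` is the full angle between the two branches."""
    if not (0.0 < branch_angle < 180.0):
        raise PhantomDomainError("branch angle must lie strictly in (0, 180) degrees")
    if min(radii) < 2:
        raise PhantomDomainError("all radii must be >= 2 voxels")
    t = np.asarray(trunk_dir, dtype=float)
    t /= np.linalg.norm(t)
    center = (np.array(shape, dtype=float) - 1) / 2.0
    rmax = float(max(radii))

    # in-plane axis perpendicular to the trunk, for splitting the branches
    e = np.zeros(3)
    e[np.argmin(np.abs(t))] = 1.0
    u = e - (e @ t) * t
    u /= np.linalg.norm(u)
    half = np.deg2rad(branch_angle) / 2.0
    d1 = np.cos(half) * t + np.sin(half) * u
    d2 = np.cos(half) * t - np.sin(half) * u

    def ray_length(origin, direction, margin):
        """Largest L so origin + L*direction stays ``margin`` inside bounds."""
        hi = np.array(shape, dtype=float) - 1
        L = np.inf
        for k in range(3):
            if direction[k] > 1e-12:
                L = min(L, (hi[k] - margin - origin[k]) / direction[k])
            elif direction[k] < -1e-12:
                L = min(L, (margin - origin[k]) / direction[k])
        return max(L, 0.0)

    margin = rmax + 1.0
    segs, rads_list = [], []
    for direction, r in (( -t, radii[0]), (d1, radii[1]), (d2, radii[2])):
        L = ray_length(center, direction, margin)
        if L < 3 * r:
            raise PhantomDomainError("volume too small for the requested Y geometry")
        pts, s = _resample_polyline(np.array([center, center + L * direction]), 0.25)
        segs.append(pts)
        rads_list.append(np.full(len(pts), float(r)))

    vol = render_tubes(list(zip(segs, rads_list)), peak_intensity, falloff, shape)
    return Phantom(vol, segs, rads_list, branch_points=[center.copy()])


def make_elliptic_tube(semi_axes=(4.0, 8.0), shape=(48, 48, 48),
                       peak_intensity: float = 200.0,
                       falloff: str = "hard") -> Phantom:
    """A straight x-axis tube with an elliptical cross-section
    ``(y/a)^2 + (z/b)^2 <= 1`` — the non-circular case the sliding-band
    boundary estimator exists for.  The recorded radius profile carries the
    mean semi-axis."""
    a, b = float(semi_axes[0]), float(semi_axes[1])
    if min(a, b) < 2:
        raise PhantomDomainError("semi-axes must be >= 2 voxels")
    nx, ny, nz = shape
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    if a + 2 > cy or b + 2 > cz:
        raise PhantomDomainError("ellipse does not fit the volume")
    ss = SUPERSAMPLE
    off = (np.arange(ss) - (ss - 1) / 2.0) / ss
    ys = (np.arange(ny)[:, None] + off[None, :]).ravel()
    zs = (np.arange(nz)[:, None] + off[None, :]).ravel()
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    q = np.sqrt(((yy - cy) / a) ** 2 + ((zz - cz) / b) ** 2)
    if falloff == "hard":
        plane = np.where(q <= 1.0, float(peak_intensity), 0.0)
    elif falloff == "cosine":
        plane = np.where(q <= 1.0,
                         peak_intensity * np.cos(np.pi * q / 2.0) ** 2, 0.0)
    else:
        raise ValueError(f"unknown falloff profile {falloff!r}")
    plane = plane.reshape(ny, ss, nz, ss).mean(axis=(1, 3))
    data = np.broadcast_to(plane[None, :, :], (nx, ny, nz)).copy()
    vol = Volume(np.clip(data, 0.0, 255.0))
    line = np.column_stack([np.arange(0, nx - 1 + 0.25, 0.25),
                            np.full(int((nx - 1) / 0.25) + 1, cy),
                            np.full(int((nx - 1) / 0.25) + 1, cz)])
    rads = np.full(len(line), (a + b) / 2.0)
    return Phantom(vol, [line], [rads])


# ---------------------------------------------------------------------------
# degradations


def attenuate_signal(volume: Volume, fraction: float) -> Volume:
    """Scale all intensities by ``1 - fraction`` (signal reduction)."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("attenuation fraction must lie in [0, 1)")
    return Volume(np.clip(volume.data * (1.0 - fraction), 0.0, 255.0), volume.spacing)


def add_gaussian_noise(volume: Volume, variance: float, seed=0) -> Volume:
    """Additive i.i.d. Gaussian noise with the stated ``variance`` on the
    unit intensity scale, i.e. std = sqrt(variance)*255 on the 8-bit scale,
    clamped to [0, 255].  Deterministic under a fixed ``seed``."""
    if variance < 0:
        raise ValueError("noise variance must be non-negative")
    if variance == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(variance) * 255.0, size=volume.shape)
    return Volume(np.clip(volume.data + noise, 0.0, 255.0), volume.spacing)


def reference_helix(noise_variance: float = 0.0, attenuation: float = 0.0,
                    seed: int = 0) -> Phantom:
    """The fixed reference helix, optionally degraded."""
    ph = make_helix()
    vol = ph.volume
    if attenuation > 0:
        vol = attenuate_signal(vol, attenuation)
    if noise_variance > 0:
        vol = add_gaussian_noise(vol, noise_variance, seed=seed)
    return Phantom(vol, ph.centerlines, ph.radius_profiles, ph.branch_points)
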
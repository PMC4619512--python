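"""SWC morphology export and simple contour-lofted mesh output.

Each traced curve becomes a chain of SWC nodes; a curve that registered a
branch hit is parented at the node of the other curve nearest to the hit.
Type codes are 0 (undefined) for regular nodes and 5 at branch nodes.  The
mesh writer lofts consecutive cross-section contours of a curve into a
triangle strip with fanned end caps (a deliberately simple surface; branch
junctions are left open, matching the tracer's backoff which removes
contours from the collision region).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .tracing import NeuronTrace


@dataclass
class SwcNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


def build_tree(trace: NeuronTrace, default_radius: float = 1.0) -> list[SwcNode]:
    """Flatten a trace into SWC nodes with contiguous 1-based ids.

    Curves are emitted in id order; collisions always reference an
    earlier curve, so parents exist by construction.  A curve with a branch
    hit is oriented so its connecting end comes first and is parented at the
    nearest node of the other curve; hit-free curves become roots.
    """
    nodes: list[SwcNode] = []
    curve_ids: dict[int, list[int]] = {}   # curve id -> SWC ids of its nodes
    next_id = 1
    for curve in sorted(trace.curves, key=lambda c: c.id):
        pts = curve.nodes
        radii = curve.radii
        if radii is None or not np.any(np.isfinite(radii)):
            radii = np.full(len(pts), curve.mean_radius
                            if np.isfinite(curve.mean_radius) else default_radius)
        parent_swc = -1
        if curve.branch_hits:
            hit_pos, other_id = curve.branch_hits[0]
            if other_id in curve_ids:
                other_curve = trace.curve_by_id(other_id)
                j = int(np.argmin(np.linalg.norm(
                    other_curve.nodes - np.asarray(hit_pos)[None, :], axis=1)))
                parent_swc = curve_ids[other_id][j]
                # orient the chain so the colliding end attaches to the parent
                d_head = np.linalg.norm(pts[0] - np.asarray(hit_pos))
                d_tail = np.linalg.norm(pts[-1] - np.asarray(hit_pos))
                if d_tail < d_head:
                    pts = pts[::-1]
                    radii = radii[::-1]
        ids_here = []
        for k, (p, r) in enumerate(zip(pts, radii)):
            parent = parent_swc if k == 0 else ids_here[-1]
            nodes.append(SwcNode(next_id, 0, float(p[0]), float(p[1]),
                                 float(p[2]),
                                 float(r) if np.isfinite(r) else default_radius,
                                 parent))
            ids_here.append(next_id)
            next_id += 1
        curve_ids[curve.id] = ids_here
    # mark branch nodes (a parent referenced by a non-consecutive child)
    child_count: dict[int, int] = {}
    for nd in nodes:
        if nd.parent != -1:
            child_count[nd.parent] = child_count.get(nd.parent, 0) + 1
    for nd in nodes:
        if child_count.get(nd.id, 0) >= 2:
            nd.type_code = 5
    return nodes


def write_swc(nodes: list[SwcNode], path, spacing=(1.0, 1.0, 1.0),
              header: str = "") -> None:
    """Standard 7-column whitespace-delimited SWC; coordinates and radii are
    scaled by the voxel spacing (radius by the mean spacing)."""
    sx, sy, sz = spacing
    rs = (sx + sy + sz) / 3.0
    with open(os.fspath(path), "w") as fh:
        fh.write("# generated by svftrace\n")
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write("# id type x y z radius parent\n")
        for nd in nodes:
            fh.write(f"{nd.id} {nd.type_code} {nd.x * sx:.4f} {nd.y * sy:.4f} "
                     f"{nd.z * sz:.4f} {nd.radius * rs:.4f} {nd.parent}\n")


def read_swc(path) -> list[SwcNode]:
    nodes = []
    with open(os.fspath(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            nodes.append(SwcNode(int(f[0]), int(f[1]), float(f[2]), float(f[3]),
                                 float(f[4]), float(f[5]), int(f[6])))
    return nodes


def validate_swc(nodes: list[SwcNode]) -> None:
    """Assert the structural SWC invariants (parent precedes child; one root
    per connected component by construction)."""
    seen = set()
    for nd in nodes:
        if nd.parent != -1 and nd.parent not in seen:
            raise ValueError(f"node {nd.id} references unseen parent {nd.parent}")
        if nd.id in seen:
            raise ValueError(f"duplicate node id {nd.id}")
        seen.add(nd.id)


def loft_mesh(contours, path) -> None:
    """Join consecutive contours of each curve into a triangle mesh (OBJ).

    Adjacent rings are connected with 2n triangles (quads split); ring index
    alignment minimises twist; both open ends are capped with a fan around
    the ring center.  All contours of a curve must share ``n``.
    """
    by_curve: dict[int, list] = {}
    for c in contours:
        by_curve.setdefault(c.curve_id, []).append(c)
    vertices: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    for cid, group in sorted(by_curve.items()):
        group = sorted(group, key=lambda c: c.node_index)
        if len(group) < 2:
            raise ValueError(f"curve {cid}: need >= 2 contours to loft")
        n = group[0].n
        if any(c.n != n for c in group):
            raise ValueError(f"curve {cid}: contours disagree on n")
        ring_start = []
        prev_ring = None
        for c in group:
            ring = np.asarray(c.boundary, dtype=float)
            if prev_ring is not None:
                # rotate ring indexing to minimise twist against previous ring
                costs = [np.linalg.norm(np.roll(ring, -k, axis=0) - prev_ring,
                                        axis=1).sum() for k in range(n)]
                ring = np.roll(ring, -int(np.argmin(costs)), axis=0)
            ring_start.append(len(vertices))
            vertices.extend(ring)
            prev_ring = ring
        for a, b in zip(ring_start[:-1], ring_start[1:]):
            for k in range(n):
                k2 = (k + 1) % n
                faces.append((a + k, b + k2, b + k))
                faces.append((a + k, a + k2, b + k2))
        for start, contour, flip in ((ring_start[0], group[0], True),
                                     (ring_start[-1], group[-1], False)):
            ci = len(vertices)
            vertices.append(np.asarray(contour.center, dtype=float))
            for k in range(n):
                k2 = (k + 1) % n
                tri = (ci, start + k, start + k2)
                faces.append((tri[0], tri[2], tri[1]) if flip else tri)
    with open(os.fspath(path), "w") as fh:
        fh.write("# svftrace lofted contour mesh\n")
        for v in vertices:
            fh.write(f"v {v[0]:.5f} {v[1]:.5f} {v[2]:.5f}\n")
        for f in faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
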
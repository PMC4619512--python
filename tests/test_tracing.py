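"""Open-curve snake: GVF, internal operator, forces, growth, collisions."""

import numpy as np
import pytest

from svftrace import (SeedPoint, SnakeParams, Volume, backoff, compute_gvf,
                      deform_curve, detect_collision, init_curve,
                      internal_matrix, stretch_force, trace_all,
                      tubeness_magnitude)
from svftrace.seeding import SeedList
from svftrace.tracing import FlowField, SnakeCurve, SnakeStateError, extend_and_label


@pytest.fixture(scope="module")
def xtube_flow(xtube):
    from svftrace import compute_gradient, enhance_volume, svf_volume
    from svftrace.filters import FilterParams

    grad = compute_gradient(xtube.volume, 1.0)
    resp = svf_volume(xtube.volume, FilterParams(), mask_floor=1.0, grad=grad)
    enhanced = enhance_volume(xtube.volume, resp)
    return compute_gvf(enhanced)


# ---------------------------------------------------------------------------
# GVF


def test_gvf_constant_volume_is_zero():
    flow = compute_gvf(Volume(np.full((10, 10, 10), 50.0)))
    assert np.all(flow.vectors == 0)


def test_gvf_zero_iterations_equals_normalised_gradient(xtube):
    flow = compute_gvf(xtube.volume, n_iters=0)
    f = xtube.volume.data / xtube.volume.data.max()
    g = np.stack(np.gradient(f))
    mag = np.sqrt((g * g).sum(axis=0))
    inside = mag > 1e-8
    expect = g[:, inside] / mag[inside]
    assert np.allclose(flow.vectors[:, inside], expect, atol=1e-12)
    assert np.all(np.linalg.norm(flow.vectors, axis=0) <= 1.0 + 1e-12)


def test_gvf_wall_flow_points_toward_axis(xtube, xtube_flow):
    """At wall voxels the external force pulls toward the centerline."""
    theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    pts = np.column_stack([np.full(24, 24.0),
                           16 + 3.0 * np.cos(theta),
                           16 + 3.0 * np.sin(theta)])
    F = xtube_flow.sample(pts)
    inward = np.column_stack([np.zeros(24), 16 - pts[:, 1], 16 - pts[:, 2]])
    inward /= np.linalg.norm(inward, axis=1, keepdims=True)
    frac = np.mean(np.sum(F * inward, axis=1) > 0)
    assert frac >= 0.95


# ---------------------------------------------------------------------------
# internal operator


def test_internal_matrix_n3_is_second_difference_stencil():
    A = internal_matrix(3, SnakeParams(alpha=0.8, beta=0.0), spacing=1.0)
    expect = 0.8 * np.array([[0, 0, 0], [-1, 2, -1], [0, 0, 0.0]])
    assert np.allclose(A, expect)
    assert np.allclose(A.sum(axis=1), 0.0)


def test_internal_matrix_annihilates_straight_lines():
    params = SnakeParams(alpha=0.8, beta=0.2)
    A = internal_matrix(12, params, spacing=1.5)
    t = np.arange(12)[:, None]
    line = np.array([[0.3, -1.0, 2.0]]) * t + np.array([[5.0, 6.0, 7.0]])
    assert np.max(np.abs(A @ line)) < 1e-12


def test_internal_matrix_nonnegative_spectrum():
    A = internal_matrix(20, SnakeParams(alpha=0.8, beta=0.2), spacing=1.0)
    eig = np.linalg.eigvals(A)
    assert np.all(eig.real >= -1e-10)
    assert np.max(np.abs(eig.imag)) < 1e-8


# ---------------------------------------------------------------------------
# stretch force


def test_tubeness_magnitude_at_zero_eigenvalues_is_one():
    assert tubeness_magnitude(np.zeros(3)) == pytest.approx(1.0)


def test_stretch_forces_antiparallel_on_straight_curve(xtube):
    curve = SnakeCurve(1, np.array([[18.0, 16, 16], [24, 16, 16], [30, 16, 16]]))
    fh = stretch_force(curve, "head", xtube.volume)
    ft = stretch_force(curve, "tail", xtube.volume)
    assert np.linalg.norm(fh) > 0 and np.linalg.norm(ft) > 0
    cosang = fh @ ft / (np.linalg.norm(fh) * np.linalg.norm(ft))
    assert cosang < -np.cos(np.deg2rad(1))


def test_stretch_force_large_tubeness_mid_tube(xtube):
    from svftrace import hessian_at

    info = hessian_at(xtube.volume, (24.0, 16.0, 16.0), 1.5)
    assert tubeness_magnitude(info.eigenvalues) > 10  # l2 l3 >> l1
    curve = SnakeCurve(1, np.array([[18.0, 16, 16], [24, 16, 16], [30, 16, 16]]))
    f = stretch_force(curve, "tail", xtube.volume)
    assert np.linalg.norm(f) == pytest.approx(1.0)  # capped, along tangent
    assert abs(f @ np.array([1.0, 0, 0])) > 0.99


# ---------------------------------------------------------------------------
# deformation


def test_deform_on_axis_is_fixed_point(xtube, xtube_flow):
    nodes = np.column_stack([np.linspace(14, 34, 14),
                             np.full(14, 16.0), np.full(14, 16.0)])
    curve = SnakeCurve(1, nodes.copy(),
                       state={"head": "converged", "tail": "converged"})
    deform_curve(curve, xtube_flow, xtube.volume, SnakeParams(node_spacing=1.54))
    d = np.abs(curve.nodes[1:-1, 1:] - 16.0)
    assert d.max() < 0.1


def test_deform_pulls_offset_curve_to_axis(xtube, xtube_flow):
    nodes = np.column_stack([np.linspace(16, 32, 11),
                             np.full(11, 18.0), np.full(11, 16.0)])
    curve = SnakeCurve(1, nodes.copy(),
                       state={"head": "converged", "tail": "converged"})
    params = SnakeParams()
    prev = 2.0
    for _ in range(3):
        deform_curve(curve, xtube_flow, xtube.volume, params)
        now = np.mean(np.abs(curve.nodes[:, 1] - 16.0))
        assert now < prev + 1e-9
        prev = now
    assert prev < 0.5


def test_deform_large_gamma_freezes_curve(xtube, xtube_flow):
    nodes = np.column_stack([np.linspace(16, 32, 11),
                             np.full(11, 18.0), np.full(11, 16.0)])
    curve = SnakeCurve(1, nodes.copy(),
                       state={"head": "converged", "tail": "converged"})
    deform_curve(curve, xtube_flow, xtube.volume,
                 SnakeParams(gamma=1e6, t_max=1, node_spacing=1.6))
    assert np.max(np.abs(curve.nodes[:, 1] - 18.0)) < 1e-3


# ---------------------------------------------------------------------------
# initialisation, growth, collision, backoff


def test_init_curve_axis_aligned_and_labeled(xtube):
    seed = SeedPoint((24.0, 16.0, 16.0), 0.8)
    curve = init_curve(seed, xtube.volume, extend_step=1.5, curve_id=7)
    assert curve.n_nodes == 3
    assert seed.label == 7
    chords = np.diff(curve.nodes, axis=0)
    for c in chords:
        assert abs(c[0]) / np.linalg.norm(c) > np.cos(np.deg2rad(5))
    with pytest.raises(SnakeStateError):
        init_curve(seed, xtube.volume)


def test_init_curve_ids_distinct(xtube):
    a = init_curve(SeedPoint((20.0, 16, 16), 0.8), xtube.volume)
    b = init_curve(SeedPoint((28.0, 16, 16), 0.8), xtube.volume)
    assert a.id != b.id


def test_backoff_identity_and_trim_arithmetic():
    nodes = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
    curve = SnakeCurve(1, nodes.copy())
    assert np.array_equal(backoff(curve, "tail", 0.0).nodes, nodes)
    curve.state["tail"] = "collided"
    backoff(curve, "tail", 5.0)
    trimmed = 19.0 - curve.nodes[-1, 0]
    assert 5.0 <= trimmed <= 6.0


def test_backoff_never_below_three_nodes():
    nodes = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    curve = SnakeCurve(1, nodes)
    backoff(curve, "head", 100.0)
    assert curve.n_nodes == 3


def test_extend_labels_seeds_near_curve(xtube, xtube_flow):
    sl = SeedList(np.array([[20.0, 16, 16], [24, 16, 16], [28, 16, 16],
                            [24.0, 28, 28]]),
                  np.array([0.9, 0.85, 0.8, 0.75]))
    seed = SeedPoint(sl.positions[1], 0.85)
    curve = init_curve(seed, xtube.volume, curve_id=1)
    extend_and_label(curve, sl, xtube_flow, xtube.volume, SnakeParams())
    assert sl.labels[0] == sl.labels[2] == 1     # on-curve seeds claimed
    assert sl.labels[3] == 0                     # far corner untouched
    claim_r = SnakeParams().effective_claim_radius(curve.mean_radius)
    for i in np.nonzero(sl.labels == 1)[0]:
        d = np.min(np.linalg.norm(curve.nodes - sl.positions[i][None], axis=1))
        assert d <= claim_r + 1e-9


def test_collision_requires_foreign_label(xtube):
    sl = SeedList(np.array([[24.0, 16, 16], [26.0, 16, 16]]),
                  np.array([0.9, 0.8]), labels=np.array([1, 1]))
    curve = SnakeCurve(1, np.array([[20.0, 16, 16], [22, 16, 16], [24, 16, 16]]))
    assert detect_collision(curve, sl, SnakeParams()) is None  # own label
    sl.labels[:] = 2
    event = detect_collision(curve, sl, SnakeParams())
    assert event is not None and event[1] == 2
    assert curve.state["tail"] == "collided" or curve.state["head"] == "collided"


def test_trace_all_empty_seed_list_gives_empty_trace(xtube, xtube_flow):
    sl = SeedList(np.empty((0, 3)), np.empty(0))
    trace = trace_all(xtube.volume, sl, xtube_flow, SnakeParams())
    assert trace.curves == [] and trace.branch_points == []


def test_flat_volume_curve_stops_quickly():
    """With no tube-like signal anywhere, both ends give up within a few
    extensions and the stub stays short."""
    vol = Volume(np.zeros((32, 32, 32)))
    flow = FlowField(np.zeros((3, 32, 32, 32)))
    sl = SeedList(np.array([[16.0, 16, 16]]), np.array([0.9]))
    trace = trace_all(vol, sl, flow, SnakeParams())
    assert len(trace.curves) <= 1
    if trace.curves:
        assert trace.curves[0].length() < 8 * SnakeParams().extend_step


def test_trace_all_recovers_straight_tube(xtube, xtube_flow):
    sl = SeedList(np.array([[24.0, 16, 16]]), np.array([0.9]))
    trace = trace_all(xtube.volume, sl, xtube_flow, SnakeParams())
    assert len(trace.curves) == 1
    curve = trace.curves[0]
    assert curve.length() >= 0.9 * 39.0          # tube spans x in [4, 43]
    assert np.max(np.abs(curve.nodes[:, 1:] - 16.0)) < 1.5
    spacing = np.linalg.norm(np.diff(curve.nodes, axis=0), axis=1)
    ns = SnakeParams().node_spacing
    assert np.all(spacing >= 0.5 * ns - 1e-6)
    assert np.all(spacing <= 2.0 * ns + 1e-6)


def test_trace_all_deterministic(xtube, xtube_flow):
    def run():
        sl = SeedList(np.array([[24.0, 16, 16], [30.0, 16, 16]]),
                      np.array([0.9, 0.8]))
        return trace_all(xtube.volume, sl, xtube_flow, SnakeParams())

    a, b = run(), run()
    assert len(a.curves) == len(b.curves)
    for ca, cb in zip(a.curves, b.curves):
        assert np.array_equal(ca.nodes, cb.nodes)
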
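"""Convergence-index machinery and the sliding volume filter."""

import numpy as np
import pytest

from svftrace import (DirectionGrid, FilterParams, Volume, band_response,
                      compute_gradient, enhance_volume, svf_at, svf_volume,
                      vci)
from svftrace.filters import FilterParamError, _svf_points
from svftrace.reference import svf_at_naive

SMALL = FilterParams(rad=7, d=2, L=6, R_min=2, R_max=6, T=0.5)


# ---------------------------------------------------------------------------
# parameters and direction grid


@pytest.mark.parametrize("kwargs", [
    dict(d=7),                       # odd band width
    dict(R_min=3, d=8),              # band would cross the center
    dict(R_min=16, R_max=16),        # empty sliding range
    dict(R_max=17),                  # band leaves the support region
    dict(L=3),
    dict(T=1.0),
])
def test_filter_params_validation(kwargs):
    with pytest.raises(FilterParamError):
        FilterParams(**{**dict(rad=20, d=8, L=20, R_min=5, R_max=16, T=0.7),
                        **kwargs})


def test_direction_grid_counts_and_norms():
    g = DirectionGrid(L=20)
    assert len(g.vectors) == g.M == 2 * 20 * 20
    assert np.max(np.abs(np.linalg.norm(g.vectors, axis=1) - 1.0)) < 1e-12
    assert np.all(g.weights >= 0)


# ---------------------------------------------------------------------------
# gradients and the pointwise index


def test_gradient_flat_and_ramp():
    flat = compute_gradient(Volume(np.zeros((8, 8, 8))), 1.0)
    assert np.all(flat.vectors == 0)
    x = np.arange(12, dtype=float)
    ramp = Volume(np.broadcast_to(x[:, None, None], (12, 12, 12)).copy())
    g = compute_gradient(ramp, 0.0)
    interior = g.vectors[:, 3:-3, 3:-3, 3:-3]
    assert np.allclose(interior[0], 1.0) and np.allclose(interior[1:], 0.0)


def test_gradient_radial_blob_points_inward():
    n = 25
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n), dtype=float)
    rho = np.sqrt(((idx - c) ** 2).sum(axis=0))
    vol = Volume(200.0 * np.exp(-(rho ** 2) / 30.0))
    grad = compute_gradient(vol, 1.0)
    rng = np.random.default_rng(0)
    pts = c + rng.uniform(-1, 1, size=(50, 3)) * 4
    g = grad.sample(pts)
    inward = c - pts
    cosang = np.sum(g * inward, axis=1) / (
        np.linalg.norm(g, axis=1) * np.linalg.norm(inward, axis=1))
    assert np.all(cosang > np.cos(np.deg2rad(5)))


def test_vci_cardinal_angles():
    """Gradient toward / perpendicular to / away from the center."""
    n = 12
    x = np.arange(n, dtype=float)
    ramp = Volume(np.broadcast_to(x[:, None, None], (n, n, n)).copy() * 10)
    grad = compute_gradient(ramp, 0.0)  # gradient = +x everywhere
    P = np.array([5.0, 5.0, 5.0])
    assert vci(grad, P + np.array([3, 0, 0]), P) == pytest.approx(1.0)
    assert vci(grad, P + np.array([0, 3, 0]), P) == pytest.approx(0.0, abs=1e-12)
    assert vci(grad, P - np.array([3, 0, 0]), P) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        vci(grad, P, P)


def test_band_response_flat_and_constant():
    flat = compute_gradient(Volume(np.zeros((16, 16, 16))), 0.0)
    assert band_response(flat, (8, 8, 8), (1, 0, 0), r=3, d=2) == 0.0
    x = np.arange(16, dtype=float)
    ramp = Volume(np.broadcast_to(x[:, None, None], (16, 16, 16)).copy() * 10)
    grad = compute_gradient(ramp, 0.0)
    # band along -x from a center: every sample's gradient (+x) points at O
    val = band_response(grad, (10.0, 8, 8), (-1, 0, 0), r=3, d=2)
    assert val == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# the sliding volume filter


def test_svf_zero_gradient_is_zero():
    grad = compute_gradient(Volume(np.zeros((16, 16, 16))), 1.0)
    assert svf_at(grad, (8.0, 8.0, 8.0), SMALL) == 0.0


def test_svf_tube_axis_beats_outside(xtube, xtube_grad):
    params = FilterParams()  # rad=20, d=8, L=20, R_min=5, R_max=16
    axis = svf_at(xtube_grad, (24.0, 16.0, 16.0), params)
    outside = svf_at(xtube_grad, (24.0, 30.0, 16.0), params)
    assert axis > 0.7 > outside


def test_svf_intensity_scale_invariance(xtube):
    """Cosines only: doubling all intensities leaves the response alone."""
    half = Volume(xtube.volume.data / 2.0)
    full = xtube.volume
    O = np.array([24.0, 17.0, 16.0])
    a = svf_at(compute_gradient(half, 1.0), O, SMALL)
    b = svf_at(compute_gradient(full, 1.0), O, SMALL)
    assert abs(a - b) < 1e-9


def test_svf_equivariant_under_axis_rotation(xtube):
    """Rotating the tube from x to y moves the response with it (within the
    angular discretisation tolerance)."""
    params = FilterParams(rad=10, d=4, L=10, R_min=2, R_max=8, T=0.5)
    rot = Volume(np.rot90(xtube.volume.data, axes=(0, 1)).copy())
    a = svf_at(compute_gradient(xtube.volume, 1.0), (24.0, 16.0, 16.0), params)
    # rot90 maps old (x, y, z) -> new (ny-1-y, x, z)
    b = svf_at(compute_gradient(rot, 1.0), (16.0, 24.0, 16.0), params)
    assert abs(a - b) < 0.02


def test_svf_matches_naive_enumeration():
    """Optimised implementation vs direct triple-loop oracle, 5 points."""
    rng = np.random.default_rng(42)
    vol = Volume(rng.uniform(0, 255, size=(16, 16, 16)))
    grad = compute_gradient(vol, 1.0)
    for _ in range(5):
        O = rng.uniform(3, 12, size=3)
        assert svf_at(grad, O, SMALL) == pytest.approx(
            svf_at_naive(grad, O, SMALL), abs=1e-9)


def test_svf_volume_range_and_pointwise_consistency():
    rng = np.random.default_rng(1)
    vol = Volume(rng.uniform(0, 255, size=(12, 12, 12)))
    grad = compute_gradient(vol, 1.0)
    resp = svf_volume(vol, SMALL, mask_floor=0.0, grad=grad)
    assert resp.values.min() >= -1.0 and resp.values.max() <= 1.0
    for p in [(2, 3, 4), (6, 6, 6), (9, 2, 10)]:
        assert resp.values[p] == pytest.approx(
            svf_at(grad, np.array(p, dtype=float), SMALL), abs=1e-12)


def test_svf_volume_mask_floor_marks_background():
    vol = Volume(np.zeros((10, 10, 10)))
    vol.data[5, 5, 5] = 200.0
    resp = svf_volume(vol, SMALL, mask_floor=100.0)
    assert resp.values[0, 0, 0] == -1.0
    assert resp.values[5, 5, 5] > -1.0


# ---------------------------------------------------------------------------
# enhancement


def test_enhance_volume_formula_spot_checks():
    resp_vals = np.array([[[0.0, 0.0, 0.5]]])
    vol = Volume(np.array([[[255.0, 0.0, 100.0]]]))
    from svftrace.filters import ResponseVolume

    out = enhance_volume(vol, ResponseVolume(resp_vals, SMALL))
    assert out.data[0, 0, 0] == pytest.approx(15 * np.sqrt(255), abs=1e-9)  # 239.53
    assert out.data[0, 0, 1] == 0.0
    assert out.data[0, 0, 2] == pytest.approx(15 * np.sqrt(150), abs=1e-9)  # 183.71


def test_saved_and_reloaded_volume_reproduces_responses(tmp_path, xtube):
    """Lossless save -> load -> recompute leaves the SVF responses (and
    hence any seed list) bit-identical."""
    from svftrace import load_stack, save_stack

    path = tmp_path / "t.tif"
    save_stack(xtube.volume, path, dtype=np.float32)
    back = load_stack(path)
    ga = compute_gradient(xtube.volume, 1.0)
    gb = compute_gradient(back, 1.0)
    for p in [(24.0, 16.0, 16.0), (20.0, 18.0, 15.0), (30.0, 14.0, 17.0)]:
        a = svf_at(ga, np.array(p), SMALL)
        b = svf_at(gb, np.array(p), SMALL)
        assert abs(a - b) < 1e-6  # float32 storage of intensities


def test_enhance_volume_bounded_and_clamped():
    rng = np.random.default_rng(2)
    vol = Volume(rng.uniform(0, 255, size=(8, 8, 8)))
    from svftrace.filters import ResponseVolume

    resp = ResponseVolume(rng.uniform(-1, 1, size=(8, 8, 8)), SMALL)
    out = enhance_volume(vol, resp)
    assert out.data.min() >= 0.0
    assert out.data.max() <= 15 * np.sqrt(255) + 1e-9
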
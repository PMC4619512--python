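"""End-to-end driver: volume -> seeds -> trace -> contours -> SWC.

Stages can be run individually (each returns its intermediate product) or
through :func:`run_pipeline`, which wires them with the standard parameters
(support radius 20, band width 8, angular resolution L = 20, sliding range
(5, 16), seed threshold 0.7; snake alpha 0.8, beta 0.2, gamma 2, 10
deformation steps)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .filters import (FilterParams, GradientField, ResponseVolume,
                      compute_gradient, enhance_volume, svf_volume)
from .radius import contours_for_trace
from .seeding import SeedList, build_seed_list, ridge_filter, threshold_seeds
from .tracing import FlowField, NeuronTrace, SnakeParams, compute_gvf, trace_all
from .volume import Volume


@dataclass
class PipelineConfig:
    filter_params: FilterParams = field(default_factory=FilterParams)
    snake_params: SnakeParams = field(default_factory=SnakeParams)
    sigma_g: float | str = "auto"  # gradient smoothing scale (voxels)
    sigma_g_base: float = 1.0      # scale used when the volume is clean
    grad_noise_cap: float = 0.5    # tolerated gradient noise (intensity/voxel)
    sigma_h: float = 1.5          # Hessian scale (voxels)
    ridge_tol: float = 1e-3
    min_spacing: float = 2.0
    mask_floor: float | str = "auto"
    gvf_mu: float = 0.1
    gvf_iters: int = 50
    n_contour: int = 16


@dataclass
class PipelineResult:
    volume: Volume
    grad: GradientField
    response: ResponseVolume
    seeds: SeedList
    enhanced: Volume
    flow: FlowField
    trace: NeuronTrace
    contours: list


def resolve_mask_floor(volume: Volume, mask_floor: float | str = "auto") -> float:
    """Intensity floor below which SVF responses are not evaluated.

    ``"auto"`` applies Otsu's threshold to a lightly smoothed copy, so that
    noisy background (which a fixed floor of 1 would admit wholesale) is
    still skipped.  Any voxel above the floor is evaluated exactly as
    without a mask; the floor only bounds where responses are computed.
    """
    if mask_floor != "auto":
        return float(mask_floor)
    from skimage.filters import threshold_otsu

    data = ndimage.gaussian_filter(volume.data, 1.5, mode="nearest")
    lo, hi = float(data.min()), float(data.max())
    if hi - lo < 1.0:
        return 1.0
    return max(1.0, float(threshold_otsu(data)))


def _gradient_noise_factor(sigma: float) -> float:
    """L2 norm of the discrete smoothed-central-difference kernel: the
    factor by which i.i.d. voxel noise propagates into one gradient
    component at smoothing scale ``sigma``."""
    radius = int(4 * sigma + 0.5) + 1
    x = np.arange(-radius, radius + 1, dtype=float)
    s = np.exp(-x * x / (2 * sigma * sigma))
    s /= s.sum()
    cd = np.convolve(s, [0.5, 0.0, -0.5])
    return float(np.sqrt((cd @ cd) * (s @ s) ** 2))


def resolve_sigma_g(volume: Volume, sigma_g: float | str = "auto",
                    base: float = 1.0, cap: float = 0.5) -> float:
    """Gradient smoothing scale, adapted to the measured noise level.

    The convergence index uses gradient *orientations* only, and the filter
    already treats gradients below ``EPS_GRAD`` (half an 8-bit quantisation
    step) as orientation-free.  For that convention to remain meaningful on
    noisy data, the noise itself must be smoothed below the same level:
    ``"auto"`` estimates the noise standard deviation (wavelet-MAD) and
    picks the smallest scale >= ``base`` at which the propagated
    per-component gradient noise stays below ``cap`` (default
    ``EPS_GRAD``).  Clean volumes therefore keep the base scale unchanged.
    """
    if sigma_g != "auto":
        return float(sigma_g)
    from skimage.restoration import estimate_sigma

    noise = float(estimate_sigma(volume.data))
    for sig in np.arange(base, 3.01, 0.25):
        if noise * _gradient_noise_factor(float(sig)) <= cap:
            return float(sig)
    return 3.0


def detect_seeds(volume: Volume, config: PipelineConfig | None = None):
    """SVF response -> threshold -> ridge refinement -> sorted seed list.

    Returns ``(grad, response, seed_list)``."""
    cfg = config or PipelineConfig()
    grad = compute_gradient(volume, resolve_sigma_g(
        volume, cfg.sigma_g, cfg.sigma_g_base, cfg.grad_noise_cap))
    response = svf_volume(volume, cfg.filter_params,
                          mask_floor=resolve_mask_floor(volume, cfg.mask_floor),
                          grad=grad)
    raw = threshold_seeds(response, cfg.filter_params.T)
    kept = ridge_filter(raw, volume, grad, cfg.sigma_h, cfg.ridge_tol)
    seeds = build_seed_list(kept, cfg.min_spacing)
    return grad, response, seeds


def run_pipeline(volume: Volume, config: PipelineConfig | None = None,
                 with_contours: bool = True) -> PipelineResult:
    cfg = config or PipelineConfig()
    cfg.snake_params.sigma_h = cfg.sigma_h
    cfg.snake_params.init_radius = float(cfg.filter_params.R_min)
    grad, response, seeds = detect_seeds(volume, cfg)
    enhanced = enhance_volume(volume, response)
    flow = compute_gvf(enhanced, cfg.gvf_mu, cfg.gvf_iters)
    trace = trace_all(volume, seeds, flow, cfg.snake_params)
    contours = []
    if with_contours and trace.curves:
        backoff_D = cfg.snake_params.backoff_factor * np.mean(
            [c.mean_radius for c in trace.curves])
        contours = contours_for_trace(trace, grad, cfg.n_contour,
                                      cfg.filter_params, backoff_D)
    return PipelineResult(volume, grad, response, seeds, enhanced, flow,
                          trace, contours)
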
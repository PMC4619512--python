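"""Shared fixtures.

The reference phantoms and their full pipeline runs are expensive (tens of
seconds to minutes), so they are session-scoped and shared between the unit
tests and the acceptance suite.
"""

import numpy as np
import pytest

from svftrace import (FilterParams, compute_gradient, make_helix, make_tube,
                      make_y_branch, reference_helix)
from svftrace.phantoms import helix_centerline
from svftrace.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def helix_phantom():
    return make_helix()


@pytest.fixture(scope="session")
def helix_gold():
    """Analytic helix centerline sampled at 0.5-voxel steps."""
    return helix_centerline(18.0, 20.0, 2.0, (64, 64, 64), step=0.5)


@pytest.fixture(scope="session")
def helix_result(helix_phantom):
    """Full pipeline on the clean reference helix."""
    return run_pipeline(helix_phantom.volume, with_contours=False)


@pytest.fixture(scope="session")
def ybranch_phantom():
    return make_y_branch()


@pytest.fixture(scope="session")
def ybranch_result(ybranch_phantom):
    return run_pipeline(ybranch_phantom.volume, with_contours=False)


@pytest.fixture(scope="session")
def atten_result():
    """Pipeline on the reference helix with 40 % signal attenuation."""
    ph = reference_helix(attenuation=0.4)
    return run_pipeline(ph.volume, with_contours=False)


@pytest.fixture(scope="session")
def noisy_result():
    """Pipeline on the reference helix with variance-0.04 Gaussian noise."""
    ph = reference_helix(noise_variance=0.04, seed=0)
    return run_pipeline(ph.volume, with_contours=False)


@pytest.fixture(scope="session")
def xtube():
    """Straight x-axis tube, radius 4, cosine falloff, 48x33x33."""
    shape = (48, 33, 33)
    c = (np.array(shape) - 1) / 2.0
    line = np.array([[4.0, c[1], c[2]], [43.0, c[1], c[2]]])
    return make_tube(line, 4.0, 200.0, "cosine", shape)


@pytest.fixture(scope="session")
def xtube_grad(xtube):
    return compute_gradient(xtube.volume, 1.0)


@pytest.fixture(scope="session")
def hard_tubes():
    """Straight hard-profile tubes of radius 3, 5 and 8 with gradients."""
    out = {}
    for r in (3, 5, 8):
        shape = (40, int(4 * r + 17) | 1, int(4 * r + 17) | 1)
        c = (np.array(shape) - 1) / 2.0
        line = np.array([[2.0, c[1], c[2]], [shape[0] - 3.0, c[1], c[2]]])
        ph = make_tube(line, float(r), 200.0, "hard", shape)
        out[r] = (ph, compute_gradient(ph.volume, 1.0), c)
    return out
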
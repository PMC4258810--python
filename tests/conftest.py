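"""Shared fixtures: phantoms and their extracted contours.

The full-size phantom extractions are session-scoped — the 3-D median and
per-frame edge detection on a 140x200x576 cube take several seconds, and
many tests interrogate the same two sequences (one noise-free, one with the
default noise model).
"""

import numpy as np
import pytest

from corneodeform import (PhantomConfig, PipelineConfig, decompose_contour,
                          detect_outer_contour, extract_contours,
                          generate_phantom)
from corneodeform.phantom import true_contour


@pytest.fixture(scope="session")
def noise_free_phantom():
    cfg = PhantomConfig(seed=1, noise_sd=0.0, contour_jitter_sd=0.0)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def noise_free_contours(noise_free_phantom):
    seq, _truth = noise_free_phantom
    return extract_contours(seq)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def default_contours(default_phantom):
    seq, _truth = default_phantom
    return extract_contours(seq)


@pytest.fixture
def small_config():
    """A reduced-geometry phantom for fast end-to-end runs."""
    return PhantomConfig(M=144, N=288, I=60, envelope_on=8, envelope_off=52,
                         eye_displacement_delay=10, indent_sigma=55.0,
                         peak_amplitude=30.0, seed=7)


def analytic_contours(config: PhantomConfig):
    """Decomposition input built from the phantom's exact contour model,
    bypassing rendering and edge detection."""
    return decompose_contour(true_contour(config), PipelineConfig())


@pytest.fixture
def make_analytic_contours():
    return analytic_contours
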
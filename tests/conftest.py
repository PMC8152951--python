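"""Shared fixtures: windows, annotations, non-overlapping patterns, scenes."""

import pytest
from hypothesis import HealthCheck, settings

from neuromosaic import (
    RenderSpec,
    dart_throw_pattern,
    make_layered_annotation,
    rectangle_window,
    render_scene,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def window_1mm():
    return rectangle_window(1000.0, 1000.0)


@pytest.fixture(scope="session")
def straight_annotation():
    """Four straight layers of 300/200/300/200 μm over a 1-mm-wide ROI."""
    return make_layered_annotation([300.0, 200.0, 300.0, 200.0], width=1000.0, waviness=0.0)


@pytest.fixture(scope="session")
def soma_pattern_50():
    return dart_throw_pattern(
        50, rectangle_window(500.0, 500.0), min_separation=24.0, margin=15.0, seed=1
    )


@pytest.fixture(scope="session")
def clean_scene(soma_pattern_50):
    """50 well-separated somata, SNR 10, with neurite clutter."""
    spec = RenderSpec(
        soma_radius=6.0,
        psf_sigma=1.0,
        peak_intensity=1000.0,
        background_level=100.0,
        noise_sd=90.0,
        clutter_density=800.0,
        pixel_size=1.0,
        z_slices=4,
        seed=7,
    )
    return render_scene(soma_pattern_50, spec)
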
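"""Shared fixtures: phantoms are generated once per session where several
tests can share them."""

import numpy as np
import pytest

from cortiquant import phantom


@pytest.fixture(scope="session")
def sphere_spec():
    """Spherical 0.5 mm-radius lesion sampled by 8 sections across its AP
    window, default noise."""
    return phantom.PhantomSpec(
        rng_seed=11,
        lesion_shape=phantom.LesionShape(semi_axes_mm=(0.5, 0.5, 0.5)),
        slice_positions_mm=tuple(np.linspace(1.3, 0.2, 8)))


@pytest.fixture(scope="session")
def sphere_stack(sphere_spec):
    return phantom.generate_slice_stack(sphere_spec)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-footprint phantom for fast per-slice tests."""
    return phantom.PhantomSpec(
        rng_seed=23,
        footprint_semiaxes_mm=(1.2, 1.0),
        lesion_shape=phantom.LesionShape(
            semi_axes_mm=(0.8, 0.35, 0.35), center_ap_mm=0.75,
            center_ml_mm=0.5, center_dv_mm=-0.2),
        slice_positions_mm=(1.0, 0.75, 0.5),
        margin_mm=0.2)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return phantom.generate_slice_stack(small_spec)


@pytest.fixture(scope="session")
def small_stack_clean(small_spec):
    """Noise-free variant of the small phantom (exact-count oracles)."""
    from dataclasses import replace
    return phantom.generate_slice_stack(replace(small_spec, noise_sd=0.0))
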
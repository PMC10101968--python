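"""Shared fixtures: small deterministic phantoms used across the suite."""

import pytest

from cytotomo.phantom import (
    ClassDistributions,
    PhantomParams,
    generate_phantom,
    sample_class_params,
)

SMALL_GRID = (100, 100, 100)
SMALL_DIST = ClassDistributions(radius_scale=0.5)


@pytest.fixture(scope="session")
def homogeneous_sphere():
    """Digital sphere: R = 4.5 µm, Δn = 0.02, no nucleus/texture, 201³ grid."""
    params = PhantomParams(
        class_label="MC",
        equiv_radius=4.5,
        axis_ratios=(1.0, 1.0, 1.0),
        mean_delta_n=0.02,
        nucleus_fraction=0.5,
        nucleus_delta_n_offset=0.0,
        n_inclusions=0,
        inclusion_radius=0.5,
        inclusion_delta_n_offset=0.0,
        texture_amplitude=0.0,
        texture_correlation_length=1.0,
        seed=1,
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def small_sphere():
    """Same degenerate sphere at benchmark scale (R = 2.5 µm, 96³ grid)."""
    params = PhantomParams(
        class_label="MC",
        equiv_radius=2.5,
        axis_ratios=(1.0, 1.0, 1.0),
        mean_delta_n=0.02,
        nucleus_fraction=0.5,
        nucleus_delta_n_offset=0.0,
        n_inclusions=0,
        inclusion_radius=0.3,
        inclusion_delta_n_offset=0.0,
        texture_amplitude=0.0,
        texture_correlation_length=1.0,
        seed=1,
        shape=SMALL_GRID,
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def textured_cell():
    """One representative textured tumor-like phantom at benchmark scale."""
    params = sample_class_params("NB", 42, SMALL_DIST, shape=SMALL_GRID)
    return generate_phantom(params)


def make_cell(label: str, seed: int):
    params = sample_class_params(label, seed, SMALL_DIST, shape=SMALL_GRID)
    return generate_phantom(params)
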
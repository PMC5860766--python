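"""Shared small-scale fixtures: a coarse pupil, a compact mirror, a fast system."""

import numpy as np
import pytest

from aosim import (
    MicroscopeSystem,
    OpticalConfig,
    build_G,
    flag_displacement_modes,
    make_pupil,
    orthogonalize,
    synth_influence_functions,
)
from aosim.pupil_optics import symmetric_z_planes


@pytest.fixture(scope="session")
def cfg64():
    return OpticalConfig(grid_n=64, pupil_fill=0.5)


@pytest.fixture(scope="session")
def mask64(cfg64):
    return make_pupil(cfg64)


@pytest.fixture(scope="session")
def cfg128():
    return OpticalConfig(grid_n=128, pupil_fill=0.5)


@pytest.fixture(scope="session")
def mask128(cfg128):
    return make_pupil(cfg128)


@pytest.fixture(scope="session")
def small_dm(mask64):
    return synth_influence_functions("square", 16, 0.3, mask64, seed=7)


@pytest.fixture(scope="session")
def small_basis(small_dm, mask64):
    G = build_G(small_dm, mask64, method="direct")
    basis = orthogonalize(G, influence=small_dm, mask=mask64)
    return flag_displacement_modes(basis, small_dm, mask64)


@pytest.fixture()
def small_system(cfg64, small_basis, mask64):
    """Fast single-plane system on the coarse grid (fresh state per test)."""
    cfg = cfg64.with_z_planes(symmetric_z_planes(1.0, 3))
    return MicroscopeSystem(
        config=cfg, basis=small_basis, mask=mask64, window=32, min_separation=4
    )


@pytest.fixture(scope="session")
def rad_per_um(cfg64):
    return 2.0 * np.pi / cfg64.wavelength_um
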
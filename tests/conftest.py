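"""Shared phantom fixtures (session-scoped: generation is deterministic)."""

import numpy as np
import pytest

from dermoct.phantom import PhantomSpec, generate_volume

# geometry chosen so the band centres fall exactly on the axial grid:
# surface at pixel 40 (101.2 um), membrane at pixel 76 (thickness 91.08 um)
FLAT_KW = dict(
    nx=48,
    ny=48,
    nz=256,
    dz=2.53,
    surface_depth=101.2,
    mean_thickness=91.08,
    mean_cuticle=22.0,
    roughness_amplitude=0.0,
    mu_s=2.16,
    seed=1,
)


@pytest.fixture(scope="session")
def flat_phantom():
    spec = PhantomSpec(**FLAT_KW)
    vol, truth = generate_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def rough_phantom():
    spec = PhantomSpec(**{**FLAT_KW, "nx": 96, "ny": 96,
                          "roughness_amplitude": 0.5, "seed": 3})
    vol, truth = generate_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def speckled_phantom():
    spec = PhantomSpec(**{**FLAT_KW, "nx": 64, "ny": 64,
                          "roughness_amplitude": 0.5,
                          "speckle_on": True, "seed": 7})
    vol, truth = generate_volume(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
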
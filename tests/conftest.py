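import numpy as np
import pytest

from atriaquant.phantom import PhantomSpec, generate_phantom

# A compact phantom configuration used across the suite: same topology as
# the default (4 veins, appendage, valve orifice) at roughly 60% scale so a
# generation takes ~2 s instead of ~16 s.
SMALL = dict(
    body_semiaxes=(18.0, 15.0, 12.0),
    wall_thickness=2.5,
    vein_radius=3.5,
    vein_length=14.0,
    mv_orifice_radius=8.0,
    grid_shape=(96, 96, 96),
)


def small_spec(**overrides) -> PhantomSpec:
    kw = dict(SMALL)
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    """Aligned (zero rigid offset) small phantom with 30% fibrosis."""
    spec = small_spec(seed=13, fibrosis_fraction=0.3, rigid_offset=(0, 0, 0, 0, 0, 0))
    mra, lge, truth = generate_phantom(spec)
    return spec, mra, lge, truth


@pytest.fixture(scope="session")
def offset_phantom():
    """Small phantom with the default rigid misalignment between channels."""
    spec = small_spec(seed=21, fibrosis_fraction=0.3)
    mra, lge, truth = generate_phantom(spec)
    return spec, mra, lge, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Deterministic-intensity phantom (no noise, no blood texture)."""
    spec = small_spec(seed=3, noise_sd=0.0, blood_sd=0.0, rigid_offset=(0, 0, 0, 0, 0, 0))
    mra, lge, truth = generate_phantom(spec)
    return spec, mra, lge, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
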
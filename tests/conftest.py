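import numpy as np
import pytest

from ocuvol import PhantomSpec, VoxelGeometry, generate_stack


@pytest.fixture(scope="session")
def sphere_stack():
    """Noiseless digitized sphere, r=12 mm, pixel 0.5 mm, gap 1 mm, no exclusion."""
    spec = PhantomSpec(radii=(12.0, 12.0, 12.0), p_w=0.5, p_h=0.5, gap=1.0)
    return generate_stack(spec)


@pytest.fixture(scope="session")
def excluded_sphere_stack():
    """Same sphere with the terminal-slice exclusion rule at fraction 0.35."""
    spec = PhantomSpec(radii=(12.0, 12.0, 12.0), p_w=0.5, p_h=0.5, gap=1.0,
                       exclusion_fraction=0.35)
    return generate_stack(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240702)


@pytest.fixture
def unit_geometry():
    return VoxelGeometry.uniform(p_w=1.0, p_h=1.0, gap=1.0, n_slices=3)
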
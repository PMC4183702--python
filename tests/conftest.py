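import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fewviewct as fv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_system():
    """A small but realistic fan-beam system on an 8x8 grid (dense-oracle scale)."""
    grid = fv.ImageGrid(np.zeros((8, 8)), 1.0)
    # angles offset from the symmetry axes so no ray runs exactly along a
    # pixel-boundary plane (where intersection lengths are ambiguous)
    geom = fv.FanBeamGeometry(
        source_to_axis=40.0, detector_bins=11, bin_aperture=1.0,
        angles=fv.view_angles(6) + 0.123,
    )
    return fv.build_system_matrix(geom, grid), grid, geom


@pytest.fixture(scope="session")
def disc_system():
    """Uniform disc phantom with a consistent noise-free sinogram, 32x32."""
    phantom = fv.make_test_phantom("uniform-disc", 32)
    geom = fv.FanBeamGeometry(
        source_to_axis=120.0, detector_bins=49, bin_aperture=32.0 / 48,
        angles=fv.view_angles(12),
    )
    A = fv.build_system_matrix(geom, phantom)
    sino = fv.simulate_projections(phantom, A)
    return A, phantom, sino
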
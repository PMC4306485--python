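import numpy as np
import pytest
from hypothesis import settings

from octgland import GlandSpec, PhantomConfig, ScanGeometry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """Down-sampled raster that keeps the physical field and depth range."""
    return ScanGeometry(n_fast=96, n_slow=96, n_depth=192)


@pytest.fixture(scope="session")
def clean_config(small_geometry) -> PhantomConfig:
    """Speckle- and noise-free phantom with a flat, untilted surface."""
    return PhantomConfig(
        geometry=small_geometry,
        surface_tilt=(400.0, 0.0, 0.0),
        bulge_amp_um=0.0,
        speckle=False,
        noise_floor_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def three_gland_specs() -> tuple[GlandSpec, ...]:
    """Two duct-bearing glands and one duct-free gland, all interior."""
    return (
        GlandSpec((0.60, 0.60), 750.0, (600.0, 500.0, 400.0), has_duct=True),
        GlandSpec((1.10, 0.90), 750.0, (500.0, 600.0, 350.0), has_duct=True),
        GlandSpec((0.85, 1.30), 750.0, (450.0, 450.0, 300.0), has_duct=False),
    )


@pytest.fixture(scope="session")
def surface_truth_index():
    """Exact first-crossing depth index of the generator's surface model."""

    def _truth(config: PhantomConfig) -> np.ndarray:
        from octgland.simulate import _surface_um

        g = config.geometry
        x = (np.arange(g.n_fast) + 0.5) * g.fov_lateral_cm / g.n_fast
        y = (np.arange(g.n_slow) + 0.5) * g.fov_lateral_cm / g.n_slow
        zs = _surface_um(config, x[None, :], y[:, None])
        # voxel k samples depth (k + 0.5) dz; first voxel at/below the interface
        return np.ceil(zs / g.dz_um - 0.5).astype(int)

    return _truth
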
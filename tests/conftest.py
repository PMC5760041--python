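import numpy as np
import pytest

from seapatch import (DensityRaster, GaussianPatch, PatchSpec,
                      generate_patchy_raster, reference_fixture)


@pytest.fixture(scope="session")
def fixture_bundle():
    """Packaged survey levels, day-0 state and default config."""
    return reference_fixture()


@pytest.fixture()
def two_bump_raster() -> DensityRaster:
    """Two well-separated smooth bumps, peaks 0.4, background 0."""
    spec = PatchSpec(patches=(
        GaussianPatch(center=(5000.0, 15000.0), peak=0.40, sigma=(900.0, 700.0)),
        GaussianPatch(center=(15000.0, 5000.0), peak=0.40, sigma=(700.0, 1100.0)),
    ), extent=(20000.0, 20000.0), cell_size=100.0)
    return generate_patchy_raster(spec)


@pytest.fixture()
def random_raster() -> DensityRaster:
    """A rough random field (not smooth) for oracle-equivalence checks."""
    rng = np.random.default_rng(42)
    values = np.clip(rng.normal(0.06, 0.08, size=(60, 80)), 0.0, None)
    return DensityRaster(values=values, cell_size=50.0)
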
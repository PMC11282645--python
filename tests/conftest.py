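import numpy as np
import pytest

from csfdispersion.geometry import (
    PhantomConfig,
    RegionMap,
    VolumeProfile,
    build_synthetic_geometry,
)
from csfdispersion.waveform import WaveformConfig, combined_waveform


@pytest.fixture(scope="session")
def default_geometry() -> VolumeProfile:
    return build_synthetic_geometry(PhantomConfig())


@pytest.fixture(scope="session")
def default_waveform():
    return combined_waveform(WaveformConfig())


@pytest.fixture(scope="session")
def regions() -> RegionMap:
    return RegionMap()


@pytest.fixture()
def uniform_canal() -> VolumeProfile:
    """Constant-area canal: 100 slices of 0.05 ml spanning z in [-80, 20)."""
    n = 100
    z = np.arange(n) + 0.5 - 80.0
    return VolumeProfile(z_centers=z, volumes=np.full(n, 0.05))
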
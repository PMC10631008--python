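import numpy as np
import pytest

from skygreen.skyproj import BandSpec, EquirectangularMask, SkyMapGeometry


@pytest.fixture
def default_bands() -> BandSpec:
    return BandSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_mask(width: int = 256, fill: int = 2,
              vegetation_ids=frozenset({8})) -> EquirectangularMask:
    labels = np.full((width // 2, width), fill, dtype=np.uint8)
    return EquirectangularMask(labels=labels, vegetation_ids=vegetation_ids)


@pytest.fixture
def small_geometry() -> SkyMapGeometry:
    return SkyMapGeometry(radius_R=256 / (2 * np.pi), map_resolution_px=256)
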
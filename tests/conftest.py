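import numpy as np
import pytest

from landfrag import CategoricalRaster

NODATA = -9999


def random_binary_raster(
    rng: np.random.Generator,
    shape: tuple[int, int] = (20, 20),
    p_forest: float = 0.5,
    p_nodata: float = 0.0,
    cell_size_m: float = 30.0,
) -> CategoricalRaster:
    codes = (rng.random(shape) < p_forest).astype(np.int32)
    if p_nodata > 0:
        codes[rng.random(shape) < p_nodata] = NODATA
    return CategoricalRaster.from_codes(codes, cell_size_m, nodata_code=NODATA)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def two_block_raster() -> CategoricalRaster:
    """6x6, 30 m cells: a 2x2 block and a 3x3 block, well separated.

    Patch areas 3,600 m2 and 8,100 m2 on a 32,400 m2 landscape.
    """
    codes = np.zeros((6, 6), dtype=np.int32)
    codes[0:2, 0:2] = 1
    codes[3:6, 3:6] = 1
    return CategoricalRaster.from_codes(codes, 30.0, nodata_code=NODATA)
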
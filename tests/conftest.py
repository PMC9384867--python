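import numpy as np
import pytest

from parasdm import pipeline, synth
from parasdm.occurrences import concat_samples, extract_values, sample_background
from parasdm.raster import Grid, RasterStack


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)


@pytest.fixture
def tiny_grid():
    """2x2 grid, cellsize 0.5, NW..SE values 1 2 / 3 4."""
    return Grid(nrows=2, ncols=2, xll=10.0, yll=40.0, cellsize=0.5,
                values=np.array([[1.0, 2.0], [3.0, 4.0]]))


@pytest.fixture(scope="session")
def small_stack():
    return synth.gen_climate_stack((40, 40), K=4, range_len=4.0, seed=77)


@pytest.fixture(scope="session")
def small_study():
    """In-memory synthetic study reused by slow-ish tests."""
    data, truths = pipeline.synthetic_study(
        nrows=40, ncols=40, K=4, n_presence=80, pairs=1,
        offset_delta=1.0, seed=11,
    )
    return data, truths


@pytest.fixture(scope="session")
def small_samples(small_study):
    """Presence + full-background SampleTable for the synthetic parasite."""
    data, _ = small_study
    pres = extract_values(data.current, data.occurrences["parasite1"])
    bg = sample_background(data.current, data.mask, 40 * 40, 5)
    return concat_samples([pres, bg])
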
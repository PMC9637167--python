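import numpy as np
import pytest

from nirtransfer.spectra_io import SpectraSet, WavelengthGrid


@pytest.fixture
def small_grid() -> WavelengthGrid:
    return WavelengthGrid(start_nm=400.0, step_nm=2.0, n_channels=20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_spectra(small_grid, rng) -> SpectraSet:
    X = rng.normal(0.5, 0.1, (10, small_grid.n_channels))
    return SpectraSet(
        grid=small_grid,
        absorbance=X,
        sample_ids=[f"s{i}" for i in range(10)],
        state="powder",
    )


def make_spectra(X, step=2.0, start=400.0, state="powder", ids=None, tags=()):
    X = np.atleast_2d(np.asarray(X, float))
    grid = WavelengthGrid(start_nm=start, step_nm=step, n_channels=X.shape[1])
    return SpectraSet(
        grid=grid,
        absorbance=X,
        sample_ids=ids or [f"s{i}" for i in range(X.shape[0])],
        state=state,
        pretreatment=list(tags),
    )
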
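import numpy as np
import pandas as pd
import pytest

from ovofresh import SpectraSet, make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """A 40-point uniform nm grid."""
    return make_grid(600.0, 800.0, 5.0, unit="nm", dialect="inclusive_points")


def build_spectra_set(absorbance, grid, days=None, group="25C"):
    """Assemble a SpectraSet with generated metadata."""
    n = absorbance.shape[0]
    days = days if days is not None else [1] * n
    meta = pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "storage_day": days,
        "temp_group": [group] * n,
        "replicate": list(range(1, n + 1)),
    })
    return SpectraSet(absorbance=absorbance, grid=grid, metadata=meta)


@pytest.fixture
def small_set(rng, small_grid):
    """Nine random-but-smooth spectra on the small grid."""
    w = small_grid.values
    base = 0.5 + 0.3 * np.exp(-0.5 * ((w - 700) / 40) ** 2)
    X = base + 0.05 * rng.normal(size=(9, len(small_grid))).cumsum(axis=1) / 6
    days = [1, 1, 1, 3, 3, 3, 5, 5, 5]
    return build_spectra_set(X, small_grid, days=days)


@pytest.fixture
def thin_study_grid():
    """The study's 550-985 nm axis thinned to ~400 variables."""
    return make_grid(550.0, 985.0, 1.05, unit="nm",
                     dialect="count_floor_steps")
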
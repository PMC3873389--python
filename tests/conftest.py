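import numpy as np
import pytest

from chronophase import (
    LD12_12,
    ActivitySeries,
    GenotypePreset,
    ld_then_dd,
    preset,
)

ZT_TIMES = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0]


@pytest.fixture(scope="session")
def wt():
    return preset("wt")


@pytest.fixture(scope="session")
def cry1():
    return preset("cry1")


@pytest.fixture(scope="session")
def cry2():
    return preset("cry2")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(counts, bin_width_min=15, schedule=LD12_12, modality="locomotor"):
    """Wrap a raw counts vector in an ActivitySeries for unit tests."""
    return ActivitySeries(
        subject_id="test",
        genotype="wt",
        modality=modality,
        bin_width_min=bin_width_min,
        counts=np.asarray(counts),
        schedule=schedule,
    )


@pytest.fixture(scope="session")
def dd_schedule():
    return ld_then_dd(0)
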
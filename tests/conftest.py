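import numpy as np
import pytest

from mieinvert import (
    OscillatorBand,
    OscillatorSet,
    SpectralGrid,
    SphereModel,
)


@pytest.fixture
def midir_grid():
    """Default 600-point mid-IR grid."""
    return SpectralGrid.uniform(500.0, 4000.0, 600)


@pytest.fixture
def coarse_grid():
    return SpectralGrid.uniform(500.0, 4000.0, 200)


@pytest.fixture
def sphere():
    return SphereModel(radius_um=5.0, medium_index=1.0)


@pytest.fixture
def one_band_set():
    return OscillatorSet([OscillatorBand(1730.0, 200.0, 20.0)], eps_inf=2.25)


@pytest.fixture
def three_band_set():
    return OscillatorSet(
        [
            OscillatorBand(1100.0, 250.0, 35.0),
            OscillatorBand(1730.0, 200.0, 25.0),
            OscillatorBand(2900.0, 150.0, 30.0),
        ],
        eps_inf=2.3,
    )


def random_oscillator_set(rng, n_bands=None):
    """Draw a valid random oscillator set for property tests."""
    m = int(n_bands if n_bands is not None else rng.integers(1, 12))
    bands = [
        OscillatorBand(
            rng.uniform(500.0, 3500.0),
            rng.uniform(50.0, 300.0),
            rng.uniform(10.0, 50.0),
        )
        for _ in range(m)
    ]
    return OscillatorSet(bands=bands, eps_inf=rng.uniform(1.5, 4.0))
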
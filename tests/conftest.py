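import numpy as np
import pytest

from helixcd import (
    ChainSpec,
    SpectroParams,
    ThermoParams,
    default_spectro,
    default_thermo,
)


@pytest.fixture(scope="session")
def alanine_thermo() -> ThermoParams:
    """Helix–coil block of the alanine-peptide calibration."""
    return default_thermo()


@pytest.fixture(scope="session")
def alanine_spectro() -> SpectroParams:
    """Spectroscopic block of the alanine-peptide calibration."""
    return default_spectro()


@pytest.fixture(scope="session")
def figure_spectro() -> SpectroParams:
    """Round-number baseline used for the model-comparison scans
    (infinite-helix ellipticity −40,000, k = 4, no coil contribution)."""
    return SpectroParams(theta_H_inf=-40_000.0, k=4.0)


@pytest.fixture(scope="session")
def chain33() -> ChainSpec:
    """The 33-peptide-unit blocked chain (n_res = 32)."""
    return ChainSpec(32)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240222)
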
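import numpy as np
import pytest

from serpinscope.spectra import EmissionSpectrum
from serpinscope.synthetic_data import (
    EMISSION_GRID_NM,
    SpectrumRecipe,
    ToyStructureRecipe,
    make_conformer_presets,
    make_spectrum_pair,
    make_toy_system,
)


@pytest.fixture(scope="session")
def grid():
    return EMISSION_GRID_NM.copy()


@pytest.fixture
def flat_spectrum(grid):
    return EmissionSpectrum(
        lambda_nm=grid, intensity=np.ones_like(grid), lambda_ex_nm=275.0, label="flat"
    )


@pytest.fixture(scope="session")
def noiseless_presets():
    return make_conformer_presets(noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def native_pair(noiseless_presets):
    return make_spectrum_pair(noiseless_presets["native"])


@pytest.fixture
def single_band_spectrum(grid):
    """One Gaussian: center 331 nm, sigma 12 nm, unit area."""
    sigma, area = 12.0, 1.0
    amp = area / (sigma * np.sqrt(2 * np.pi))
    y = amp * np.exp(-0.5 * ((grid - 331.0) / sigma) ** 2)
    return EmissionSpectrum(grid, y, lambda_ex_nm=275.0, label="single")


@pytest.fixture
def carbon_atom_system():
    system, traj, truth = make_toy_system(
        ToyStructureRecipe(kind="isolated_atoms", n_res=1)
    )
    return system, traj, truth


@pytest.fixture
def dimer_system():
    system, traj, _ = make_toy_system(
        ToyStructureRecipe(kind="dimer", distance_A=2.0)
    )
    return system, traj
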
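import numpy as np
import pytest

from ctfm import lattice_sim as sim
from ctfm.lattice_sim import ImagingSpec, LatticeSpec


@pytest.fixture(scope="session")
def perfect_lattice():
    return sim.make_lattice(LatticeSpec(L0=1.5, rows=12, cols=12))


@pytest.fixture(scope="session")
def jittered_dipole():
    """Standard-conditions array: printing jitter + contractile dipole."""
    arr = sim.make_lattice(LatticeSpec(L0=1.5, rows=24, cols=24,
                                       jitter_sd=0.0247, seed=42))
    cen = tuple(arr.xy.mean(axis=0))
    fn = sim.contractile_dipole(centre=cen, separation=8.0, sigma=3.0,
                                peak=1.5)
    return sim.apply_deformation(arr, fn)


@pytest.fixture(scope="session")
def noisefree_image(perfect_lattice):
    return sim.render_image(perfect_lattice, ImagingSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_image(perfect_lattice):
    return sim.render_image(perfect_lattice, ImagingSpec(noise_sd=10.0),
                            seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
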
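import numpy as np
import pytest

from driftscan import simulate, synth


@pytest.fixture(scope="session")
def gmap_small():
    return synth.make_genome_map(2, 5_000_000, 0.5)


@pytest.fixture(scope="session")
def panel_small(gmap_small):
    return synth.make_founder_panel(
        gmap_small, n_founders=8, snp_density=1 / 10_000, ancestral_pool=6, seed=11
    )


@pytest.fixture(scope="session")
def ped_small():
    return synth.make_pedigree(4, 3, 6, seed=21)


@pytest.fixture(scope="session")
def model_default():
    return simulate.TraitModel()


@pytest.fixture(scope="session")
def sim_small(ped_small, panel_small, gmap_small, model_default):
    return simulate.run_experiment(
        ped_small, panel_small, gmap_small, model_default, rng=np.random.default_rng(31)
    )
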
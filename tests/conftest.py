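import numpy as np
import pandas as pd
import pytest

import heatnorm as hn


@pytest.fixture(scope="session")
def small_sim():
    """A compact dataset: ~60 sows, 2 sire generations, 400 SNPs."""
    cfg = hn.SimConfig(
        seed=42,
        n_founders=40,
        n_generations=3,
        n_sires_per_gen=5,
        n_daughters_per_sire=6,
        n_snps=400,
        n_chromosomes=4,
        parities_range=(4, 6),
    )
    return hn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_model(small_sim):
    from heatnorm.model import ReactionNormModel

    return ReactionNormModel.from_simulation(small_sim)


@pytest.fixture(scope="session")
def small_fit(small_model):
    return small_model.fit(iterations=3000, burn_in=600, thin=8, seed=5)


@pytest.fixture()
def toy_pedigree():
    """Founders 1-4; full sibs 5,6 from (1,2); 7 = offspring of full sibs."""
    return pd.DataFrame(
        {
            "animal": [1, 2, 3, 4, 5, 6, 7],
            "sire": [0, 0, 0, 0, 1, 1, 5],
            "dam": [0, 0, 0, 0, 2, 2, 6],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
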
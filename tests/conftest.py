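import numpy as np
import pandas as pd
import pytest

from rewirenet import synthgen


@pytest.fixture
def small_config():
    return synthgen.SimConfig(
        n_genes=300,
        n_samples_per_group=20,
        n_batches=4,
        n_modules=2,
        module_size=30,
        module_cor=0.8,
        n_degs=6,
        deg_effect=2.0,
        n_rewired=1,
        rewired_partners=10,
        rewired_cor=0.8,
        n_tfs=4,
        targets_per_tf=10,
        tf_effect=1.0,
        noise_sd=1.0,
        batch_sd=0.5,
        seed=7,
    )


@pytest.fixture
def sim_data(small_config):
    return synthgen.simulate_expression(small_config)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(11)
    genes = [f"G{i:03d}" for i in range(40)]
    samples = [f"S{i:02d}" for i in range(15)]
    return pd.DataFrame(rng.normal(8, 1, size=(40, 15)),
                        index=genes, columns=samples)
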
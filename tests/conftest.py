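import numpy as np
import pytest

from netconverge import SimConfig, gen_expression_panel


@pytest.fixture(scope="session")
def small_study():
    """600-gene, 3-condition panel with three planted modules (one differential)."""
    config = SimConfig(
        n_genes=600,
        n_conditions=3,
        n_samples_per_condition=50,
        module_sizes=[100, 80, 60],
        n_differential_modules=1,
        n_hidden_factors=0,  # raw-panel tests; batch removal is preprocess's job
        seed=1,
    )
    return gen_expression_panel(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
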
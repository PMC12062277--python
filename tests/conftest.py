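import numpy as np
import pytest

from graphomix.encoder import EncoderConfig
from graphomix.integration import IntegratorConfig
from graphomix.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted-signal two-modality cohort for pipeline tests."""
    cfg = SimulationConfig(n_samples_complete=48, n_samples_mod1_only=12,
                           n_samples_mod2_only=12,
                           n_nodes_per_modality=(20, 20), n_informative=4,
                           effect_size=2.0, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_encoder_cfg():
    return EncoderConfig(n_communities=2, n_conv_blocks=1, channels=3,
                         n_clusters=2, features_per_cluster=2,
                         embedding_dim=8, node_cap=300)


@pytest.fixture(scope="session")
def small_integrator_cfg():
    return IntegratorConfig(n_blocks=1, n_heads=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
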
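import numpy as np
import pytest

from tsclust import MockConfig, generate_library


@pytest.fixture(scope="session")
def mock_small():
    """A small 8-template mock library with default noise settings."""
    cfg = MockConfig(n_templates=8, template_length=80, n_reads=3000, seed=7)
    reads, truth = generate_library(cfg)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def mock_small_indel():
    """A 454-flavoured mock with indel noise for screen/validator checks."""
    cfg = MockConfig(n_templates=5, template_length=80, n_reads=1200,
                     sub_rate=1e-3, ins_rate=4e-4, del_rate=4e-4, seed=13)
    reads, truth = generate_library(cfg)
    return cfg, reads, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
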
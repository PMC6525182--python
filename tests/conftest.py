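import numpy as np
import pandas as pd
import pytest

from rootallometry.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast, fully-featured config: every species carries anatomy."""
    cfg = GeneratorConfig(seed=42, n_studies=6)
    cfg.woody.n = 120
    cfg.woody.anatomy_n = None
    cfg.nonwoody.n = 80
    cfg.nonwoody.anatomy_n = None
    return cfg


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 505 woody + 361 non-woody species."""
    return generate_dataset(GeneratorConfig(seed=7))
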
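import numpy as np
import pytest

import lymphrisk as lr


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale cohort: 3x3 patch grid slides, ~8 tissue patches."""
    return lr.SyntheticConfig(
        n_patients=24,
        slide_width=1536,
        slide_height=1536,
        n_blobs=2,
        blob_cells=4,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return lr.build_feature_cohort(tiny_config)


@pytest.fixture(scope="session")
def one_slide(tiny_config):
    rng = np.random.default_rng(5)
    image, signal, tissue = lr.generate_slide(1, tiny_config, rng)
    return image, signal, tissue


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
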
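import numpy as np
import pytest

from amisquant import SceneParams, generate_doublet_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def null_doublet():
    """Noiseless unpolarized doublet (E = 1) with its truth."""
    return generate_doublet_scene(SceneParams(par3_enrichment=1.0, seed=7))


@pytest.fixture(scope="session")
def polarized_doublet():
    """Noiseless polarized doublet (E = 4) with its truth."""
    return generate_doublet_scene(SceneParams(par3_enrichment=4.0, seed=7))
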
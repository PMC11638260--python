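import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def source_pheno(rng):
    """A generic non-normal-ish source phenotype, n=400."""
    from reliattn.noise import PhenotypeVector

    ids = np.array([f"sub-{i:04d}" for i in range(400)])
    return PhenotypeVector(ids, rng.normal(100.0, 15.0, 400), name="score")
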
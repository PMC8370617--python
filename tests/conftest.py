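import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from landracekit import SampleMetadata, SimulationConfig, simulate_population

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_default():
    """One simulated collection under the default study-like configuration."""
    return simulate_population(SimulationConfig(seed=1))


@pytest.fixture()
def toy_meta():
    """Five collected samples in two zones plus one reference landrace."""
    t = pd.DataFrame(
        {
            "given_name": ["n1", "n2", "n3", "n4", "n5", "Kiroba"],
            "zone": ["Central", "Central", "Coastal", "Coastal", "Central", None],
            "category": ["collected"] * 5 + ["reference_landrace"],
            "replicate_group": [None] * 6,
            "replicate_type": [None] * 6,
        },
        index=pd.Index(["S1", "S2", "S3", "S4", "S5", "REF1"], name="sample_id"),
    )
    return SampleMetadata(t)


def random_dosage(rng, n, m, missing=0.1):
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    X[rng.random((n, m)) < missing] = np.nan
    return X
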
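import numpy as np
import pytest

from compslide.semantics import EmbeddingTable
from compslide.simulate import make_participant


@pytest.fixture(scope="session")
def toy_table_2d() -> EmbeddingTable:
    """Hand-checkable 2-D embeddings: dog=(1,0), cat=(0.8,0.6), rain=(0,1)."""
    return EmbeddingTable(
        {
            "dog": np.array([1.0, 0.0]),
            "cat": np.array([0.8, 0.6]),
            "rain": np.array([0.0, 1.0]),
        }
    )


@pytest.fixture(scope="session")
def quiet_profile():
    """A participant with no motor noise and no clock drift."""
    return make_participant(7, overrides={"motor_noise_sd": 0.0, "drift_ppm": 0.0})
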
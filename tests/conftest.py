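import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_genotypes():
    """Deterministic 6-line, 4-marker dosage matrix."""
    from gsmodels import GenotypeMatrix

    dosages = np.array(
        [
            [0, 1, 2, 1],
            [1, 0, 2, 2],
            [2, 1, 0, 0],
            [1, 2, 1, 0],
            [0, 0, 1, 2],
            [2, 2, 0, 1],
        ]
    )
    return GenotypeMatrix(
        [f"L{i}" for i in range(6)], [f"m{j}" for j in range(4)], dosages
    )
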
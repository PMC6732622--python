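import numpy as np
import pytest

import repolink as rl


@pytest.fixture
def toy_assoc():
    """4 drugs x 3 diseases with a mix of shared and private associations."""
    A = np.array(
        [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
        ]
    )
    return rl.AssociationMatrix(
        [f"u{i}" for i in range(4)], [f"d{j}" for j in range(3)], A
    )


@pytest.fixture(scope="session")
def fixture_triple():
    """The standard planted-module synthetic triple (100 drugs x 60 diseases)."""
    return rl.default_fixture()


@pytest.fixture(scope="session")
def small_triple():
    """A smaller planted-module triple for fast end-to-end unit tests."""
    spec = rl.SynthSpec(
        n_drugs=40, n_diseases=24, n_modules=3, fp_bits=32, seed=7
    )
    return rl.generate(spec)
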